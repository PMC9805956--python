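"""Repertoire comparison with Maximum Mean Discrepancy (MMD).

MMD is a nonparametric distance between two sample distributions: the
distance between their mean embeddings in the reproducing kernel Hilbert
space of a kernel k.  With an RBF kernel and samples X = {x_i}_m,
Y = {y_j}_n, the unbiased (U-statistic) estimate of squared MMD is

    MMD^2 = 1/(m(m-1)) sum_{i != i'} k(x_i, x_i')
          + 1/(n(n-1)) sum_{j != j'} k(y_j, y_j')
          - 2/(mn)     sum_{i,j}     k(x_i, y_j).

The biased (V-statistic) variant keeps the diagonal terms and is exactly
zero for identical multisets.  Because a raw MMD value has no absolute
scale, each between-group contrast is interpreted against a within-group
baseline: the distribution of MMDs obtained by randomly bipartitioning
one group's *pups* (splits are at the pup level, never the syllable
level, so pup identity is not leaked across the split).

The default embedding is the standardized eight-feature vector per
syllable; externally computed latent embeddings (e.g., from a
vocalization autoencoder) can be supplied instead, making the comparison
protocol embedding-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist


@dataclass(frozen=True)
class EmbeddingSet:
    """Per-syllable embedding vectors with metadata labels."""

    vectors: np.ndarray  # (n_syllables, d)
    labels: pd.DataFrame  # columns such as pup, age, session, behavior

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or not np.all(np.isfinite(v)):
            raise ValueError("vectors must be a finite (n, d) array")
        if len(self.labels) != v.shape[0]:
            raise ValueError("labels must have one row per vector")
        object.__setattr__(self, "vectors", v)

    def select(self, column: str, value) -> np.ndarray:
        if column not in self.labels.columns:
            raise KeyError(f"no label column {column!r}; have {list(self.labels.columns)}")
        mask = (self.labels[column] == value).to_numpy()
        if not mask.any():
            raise ValueError(
                f"label {value!r} absent in column {column!r}; "
                f"available: {sorted(self.labels[column].unique().tolist())}"
            )
        return self.vectors[mask]


@dataclass(frozen=True)
class MmdComparison:
    value: float
    comparison_kind: str  # within_baseline | between_groups
    kernel: str
    bandwidth: float
    group_sizes: tuple[int, int]
    groups: tuple[str, str] = ("", "")
    split_seed: int | None = None


def standardize(X: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Z-score columns using the pooled reference set (X itself by default),
    so no single feature's units dominate the kernel."""
    ref = X if reference is None else reference
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def median_heuristic_bandwidth(Z: np.ndarray, max_points: int = 2000,
                               rng: np.random.Generator | None = None) -> float:
    """Median pairwise Euclidean distance of the pooled sample — the
    standard parameter-free RBF bandwidth choice."""
    Z = np.asarray(Z, dtype=float)
    if len(Z) > max_points:
        rng = rng or np.random.default_rng(0)
        Z = Z[rng.choice(len(Z), size=max_points, replace=False)]
    med = float(np.median(pdist(Z)))
    return med if med > 0 else 1.0


def mmd2(X: np.ndarray, Y: np.ndarray, bandwidth: float | None = None,
         unbiased: bool = True) -> float:
    """Squared-MMD estimate with an RBF kernel exp(-||x-y||^2 / (2 h^2)).

    Unbiased (default) excludes diagonal terms and can be slightly
    negative under the null; the biased variant is >= 0 and exactly 0 for
    X == Y.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    m, n = len(X), len(Y)
    if m < 2 or n < 2:
        raise ValueError("need at least 2 samples per side")
    if bandwidth is None:
        bandwidth = median_heuristic_bandwidth(np.vstack([X, Y]))
    g = 1.0 / (2.0 * bandwidth ** 2)
    kxx = np.exp(-g * cdist(X, X, "sqeuclidean"))
    kyy = np.exp(-g * cdist(Y, Y, "sqeuclidean"))
    kxy = np.exp(-g * cdist(X, Y, "sqeuclidean"))
    if unbiased:
        xx = (kxx.sum() - np.trace(kxx)) / (m * (m - 1))
        yy = (kyy.sum() - np.trace(kyy)) / (n * (n - 1))
    else:
        xx = kxx.mean()
        yy = kyy.mean()
    return float(xx + yy - 2.0 * kxy.mean())


def within_baseline(embeddings: EmbeddingSet, group_column: str, group_value,
                    n_splits: int = 10, seed: int = 0,
                    pup_column: str = "pup", bandwidth: float | None = None,
                    unbiased: bool = True) -> list[MmdComparison]:
    """Within-group baseline MMDs from random pup-level bipartitions.

    Pups of the group are shuffled and split in half; MMD is computed
    between the two halves' pooled syllables.  One comparison per split,
    reproducible from the seed.
    """
    mask = (embeddings.labels[group_column] == group_value).to_numpy()
    sub_vec = embeddings.vectors[mask]
    sub_lab = embeddings.labels.loc[mask].reset_index(drop=True)
    pups = sorted(sub_lab[pup_column].unique().tolist())
    if len(pups) < 2:
        raise ValueError(f"group {group_value!r} has {len(pups)} pup(s); need >= 2 for splits")
    if bandwidth is None:
        bandwidth = median_heuristic_bandwidth(sub_vec)
    rng = np.random.default_rng(seed)
    out = []
    for split in range(n_splits):
        for _ in range(100):
            perm = rng.permutation(pups)
            half_a = set(perm[: len(pups) // 2])
            in_a = sub_lab[pup_column].isin(half_a).to_numpy()
            if 2 <= in_a.sum() <= len(in_a) - 2:
                break
        else:  # pragma: no cover - requires pathological pup sizes
            raise ValueError("could not form a split with >= 2 syllables per side")
        val = mmd2(sub_vec[in_a], sub_vec[~in_a], bandwidth=bandwidth, unbiased=unbiased)
        out.append(MmdComparison(
            value=val, comparison_kind="within_baseline", kernel="rbf",
            bandwidth=bandwidth, group_sizes=(int(in_a.sum()), int((~in_a).sum())),
            groups=(str(group_value), str(group_value)), split_seed=split,
        ))
    return out


def between_groups(embeddings: EmbeddingSet, column: str, label_a, label_b,
                   bandwidth: float | None = None,
                   unbiased: bool = True) -> MmdComparison:
    """MMD between two labeled groups (age x age, behavior x behavior, ...).

    Symmetric in the two labels.  Interpret against the matching
    within-group baseline distribution from :func:`within_baseline`.
    """
    X = embeddings.select(column, label_a)
    Y = embeddings.select(column, label_b)
    if bandwidth is None:
        bandwidth = median_heuristic_bandwidth(np.vstack([X, Y]))
    val = mmd2(X, Y, bandwidth=bandwidth, unbiased=unbiased)
    return MmdComparison(
        value=val, comparison_kind="between_groups", kernel="rbf",
        bandwidth=bandwidth, group_sizes=(len(X), len(Y)),
        groups=(str(label_a), str(label_b)),
    )


def permutation_pvalue(X: np.ndarray, Y: np.ndarray, n_permutations: int = 200,
                       seed: int = 0, bandwidth: float | None = None) -> float:
    """Optional permutation test: fraction of label permutations whose MMD
    meets or exceeds the observed one (with add-one smoothing)."""
    pool = np.vstack([np.atleast_2d(X), np.atleast_2d(Y)])
    if bandwidth is None:
        bandwidth = median_heuristic_bandwidth(pool)
    obs = mmd2(X, Y, bandwidth=bandwidth)
    m = len(np.atleast_2d(X))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(pool))
        v = mmd2(pool[perm[:m]], pool[perm[m:]], bandwidth=bandwidth)
        hits += v >= obs
    return (hits + 1) / (n_permutations + 1)
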