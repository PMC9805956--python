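"""Alignment of USV syllables with behavior ethograms.

An ethogram is a time-tiled record of mutually exclusive behavior
categories scored over a session.  Pups in isolation are scored as one of
four behaviors: locomotion, wriggling, lying still, or grooming.  This
module joins detected syllables to the ethogram (each syllable gets the
behavior code active at its onset), and computes time-in-behavior
proportions and time-normalized USV rates per behavior.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BEHAVIORS = ("locomotion", "wriggling", "lying_still", "grooming")


class EthogramError(ValueError):
    """Raised when an interval table does not tile the session."""


@dataclass(frozen=True)
class Ethogram:
    """Ordered, non-overlapping behavior intervals tiling ``[0, session_length_s)``.

    Intervals are half-open ``[start, end)``: a time exactly on a boundary
    belongs to the interval that begins there.
    """

    intervals: tuple[tuple[float, float, str], ...]
    session_length_s: float
    _starts: tuple[float, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ivs = tuple((float(a), float(b), str(c)) for a, b, c in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        bad = []
        prev_end = 0.0
        for i, (a, b, beh) in enumerate(ivs):
            if b <= a or beh not in BEHAVIORS or not np.isclose(a, prev_end, atol=1e-9):
                bad.append((i, a, b, beh))
            prev_end = b
        if not ivs or not np.isclose(prev_end, self.session_length_s, atol=1e-9):
            bad.append(("coverage", 0.0, prev_end if ivs else 0.0, "session"))
        if bad:
            raise EthogramError(
                f"ethogram must tile [0, {self.session_length_s}) with known behaviors; "
                f"offending intervals: {bad}"
            )
        object.__setattr__(self, "_starts", tuple(a for a, _, _ in ivs))

    def behavior_at(self, t_s: float) -> str:
        """Behavior of the interval containing ``t_s`` (half-open convention)."""
        if t_s < 0 or t_s >= self.session_length_s:
            raise EthogramError(
                f"time {t_s} s outside ethogram coverage [0, {self.session_length_s})"
            )
        idx = bisect.bisect_right(self._starts, t_s) - 1
        return self.intervals[idx][2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals, columns=["start_s", "end_s", "behavior"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, session_length_s: float | None = None) -> "Ethogram":
        ivs = [tuple(r) for r in df[["start_s", "end_s", "behavior"]].itertuples(index=False)]
        if session_length_s is None:
            session_length_s = float(df["end_s"].max())
        return cls(tuple(ivs), session_length_s)


def behavior_proportions(ethogram: Ethogram) -> dict[str, float]:
    """Proportion of session time spent in each behavior (sums to 1)."""
    time = {b: 0.0 for b in BEHAVIORS}
    for a, b, beh in ethogram.intervals:
        time[beh] += b - a
    return {b: t / ethogram.session_length_s for b, t in time.items()}


def assign_behavior(onset_s: float, ethogram: Ethogram) -> str:
    """Behavior code for a syllable: the behavior active at its onset.

    Syllables spanning a behavior transition are coded by the behavior at
    onset; a majority-overlap rule is deliberately not the default (the
    onset marks the motor decision to vocalize).
    """
    return ethogram.behavior_at(onset_s)


@dataclass(frozen=True)
class BehaviorRates:
    """Per-behavior occupancy time, USV counts and time-normalized rates.

    ``usvs_per_second[b]`` is ``None`` when the pup never performed
    behavior ``b`` (zero occupancy time).
    """

    time_s: dict[str, float]
    usv_count: dict[str, int]
    usvs_per_second: dict[str, float | None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "behavior": list(BEHAVIORS),
                "time_s": [self.time_s[b] for b in BEHAVIORS],
                "usv_count": [self.usv_count[b] for b in BEHAVIORS],
                "usvs_per_second": [self.usvs_per_second[b] for b in BEHAVIORS],
            }
        )


def usv_rate_per_behavior(onsets_s, ethogram: Ethogram) -> BehaviorRates:
    """USVs per second of each behavior: count in behavior / time in behavior."""
    time = {b: 0.0 for b in BEHAVIORS}
    for a, b, beh in ethogram.intervals:
        time[beh] += b - a
    count = {b: 0 for b in BEHAVIORS}
    for t in onsets_s:
        count[assign_behavior(float(t), ethogram)] += 1
    rate: dict[str, float | None] = {}
    for b in BEHAVIORS:
        rate[b] = count[b] / time[b] if time[b] > 0 else None
    return BehaviorRates(time_s=time, usv_count=count, usvs_per_second=rate)


def normalized_behavior_shares(rates: BehaviorRates) -> dict[str, float]:
    """Rate shares: each behavior's USV rate renormalized to sum to 1.

    This normalization removes the influence of how long the pup spent in
    each behavior, so it reflects the propensity to vocalize *during* a
    behavior rather than the behavior's prevalence.
    """
    nonnull = {b: r for b, r in rates.usvs_per_second.items() if r is not None}
    total = sum(nonnull.values())
    if not nonnull or total == 0:
        raise ValueError("all behavior rates are zero or undefined; shares undefined")
    return {b: (rates.usvs_per_second[b] or 0.0) / total if rates.usvs_per_second[b] is not None else 0.0
            for b in BEHAVIORS}
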