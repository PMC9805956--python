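"""End-to-end orchestration: simulate -> detect -> features -> align ->
cross-covariance -> MMD, writing tidy CSV artifacts plus a manifest.

Each simulated trial comprises two 5-min sessions (isolation and
re-isolation).  Feature and repertoire analyses pool the two sessions;
the movement/rate cross-covariance keeps them separate to form matched
and shuffled comparisons.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import behavior_proportions, usv_rate_per_behavior
from .config import PipelineConfig
from .detection import DetectionThresholds, StftParams, compute_spectrogram, detect_usvs
from .features import FEATURE_COLUMNS, features_table
from .mmd import EmbeddingSet, between_groups, standardize, within_baseline
from .movement import (MovementTrace, bin_usv_rate, matched_shuffled, pooled_cc,
                       resample_to_rate_base, smooth_trace)
from .synthetic import DEFAULT_AGE_PROFILES, TrialSpec, synth_trial

log = logging.getLogger("pupcall")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full synthetic pipeline; returns the manifest dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        manifest = _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()
    return manifest


def _run(config: PipelineConfig, out: Path) -> dict:
    sim = config.simulate
    stft = StftParams(nperseg=config.stft.nperseg, noverlap=config.stft.noverlap,
                      window=config.stft.window, sample_rate_hz=config.stft.sample_rate_hz)
    thresholds = DetectionThresholds(**config.thresholds.model_dump())
    root = np.random.default_rng(config.seed)

    feat_rows: list[pd.DataFrame] = []
    rate_rows: list[dict] = []
    curves: dict[str, list[np.ndarray]] = {}
    lags_s = None
    counts = {"trials": 0, "segments": 0, "zero_usv_trials": 0}

    for age in sim.ages:
        profile = DEFAULT_AGE_PROFILES[age]
        for pup in range(sim.n_pups):
            counts["trials"] += 1
            trial_id = f"{age}_pup{pup}"
            sessions = {}
            for session in ("isolation", "re-isolation"):
                seed = int(root.integers(0, 2**31 - 1))
                spec = TrialSpec(
                    session_length_s=sim.session_length_s,
                    sample_rate_hz=stft.sample_rate_hz,
                    noise_floor=sim.noise_floor, frame_rate_hz=sim.frame_rate_hz,
                    coupling_gain=sim.coupling_gain, coupling_lag_s=sim.coupling_lag_s,
                    baseline_rate_hz=sim.baseline_rate_hz,
                    behavior_mix=dict(sim.behavior_mix), seed=seed, age_profile=profile,
                )
                audio, truth = synth_trial(spec)
                sgram = compute_spectrogram(audio, stft)
                segments = detect_usvs(sgram, thresholds, trial_id=trial_id, session=session)
                counts["segments"] += len(segments)
                log.info("trial %s %s: %d syllables detected (%d programmed)",
                         trial_id, session, len(segments), len(truth.segments))

                feats = features_table(segments, sgram, pup=trial_id, age=age,
                                       session=session)
                if len(feats):
                    feats["behavior"] = [truth.ethogram.behavior_at(t)
                                         for t in feats["onset_s"]]
                feat_rows.append(feats)

                rates = usv_rate_per_behavior([s.onset_s for s in segments], truth.ethogram)
                props = behavior_proportions(truth.ethogram)
                for b in rates.time_s:
                    rate_rows.append({"trial_id": trial_id, "age": age, "session": session,
                                      "behavior": b, "time_s": rates.time_s[b],
                                      "usv_count": rates.usv_count[b],
                                      "usvs_per_second": rates.usvs_per_second[b],
                                      "time_proportion": props[b]})

                trace = smooth_trace(MovementTrace(truth.movement, sim.frame_rate_hz),
                                     span_frames=config.xcov.span_frames)
                rate_vec = bin_usv_rate([s.onset_s for s in segments],
                                        sim.session_length_s, config.xcov.bin_width_s)
                sessions[session] = (resample_to_rate_base(trace, rate_vec),
                                     rate_vec.counts.astype(float))
            res = matched_shuffled(*sessions["isolation"], *sessions["re-isolation"],
                                   max_lag_s=config.xcov.max_lag_s,
                                   bin_width_s=config.xcov.bin_width_s, trial_id=trial_id)
            if res is None:
                counts["zero_usv_trials"] += 1
                log.info("trial %s excluded from xcov (zero-USV session)", trial_id)
                continue
            lags_s = res.lags_s
            curves.setdefault(age, []).append(("matched", trial_id, res.matched_curve))
            curves[age].append(("shuffled", trial_id, res.shuffled_curve))

    feat_rows = [df for df in feat_rows if len(df)]
    features_df = (pd.concat(feat_rows, ignore_index=True) if feat_rows
                   else pd.DataFrame(columns=FEATURE_COLUMNS))
    features_df.to_csv(out / "features.csv", index=False)
    pd.DataFrame(rate_rows).to_csv(out / "behavior_rates.csv", index=False)

    xcov_summary = _xcov_stage(curves, lags_s, config, out)
    mmd_df = _mmd_stage(features_df, config)
    mmd_df.to_csv(out / "mmd.csv", index=False)

    manifest = {
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(config.model_dump(), sort_keys=True).encode()).hexdigest(),
        "counts": counts,
        "n_feature_rows": int(len(features_df)),
        "n_mmd_comparisons": int(len(mmd_df)),
        "xcov": xcov_summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _xcov_stage(curves, lags_s, config: PipelineConfig, out: Path) -> dict:
    rows, summary = [], {}
    for age, entries in curves.items():
        matched = [c for kind, _, c in entries if kind == "matched"]
        shuffled = [c for kind, _, c in entries if kind == "shuffled"]
        trial_ids = [tid for kind, tid, _ in entries if kind == "matched"]
        pm = pooled_cc(matched, lags_s, window_s=config.xcov.cc_window_s)
        # shuffled per-trial CCs are read at the matched pooled lag
        col = int(np.flatnonzero(np.isclose(lags_s, pm.pooled_lag_s))[0])
        shuf_ccs = np.vstack(shuffled)[:, col]
        summary[age] = {"pooled_lag_s": pm.pooled_lag_s, "pooled_cc": pm.pooled_cc,
                        "mean_matched_cc": float(np.mean(pm.per_trial_ccs)),
                        "mean_shuffled_cc": float(np.mean(shuf_ccs))}
        for tid, mc, sc in zip(trial_ids, pm.per_trial_ccs, shuf_ccs):
            rows.append({"age": age, "trial_id": tid, "matched_cc": float(mc),
                         "shuffled_cc": float(sc), "pooled_lag_s": pm.pooled_lag_s})
    pd.DataFrame(rows).to_csv(out / "xcov_summary.csv", index=False)
    long = []
    for age, entries in curves.items():
        for kind, tid, curve in entries:
            long.extend({"age": age, "trial_id": tid, "kind": kind,
                         "lag_s": float(l), "xcov": float(v)}
                        for l, v in zip(lags_s, curve))
    pd.DataFrame(long).to_csv(out / "xcov_curves.csv", index=False)
    return summary


def _mmd_stage(features_df: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    usable = features_df.dropna(subset=[c for c in FEATURE_COLUMNS if c != "isi_ms"])
    if usable.empty or usable["age"].nunique() < 2:
        return pd.DataFrame(columns=["kind", "group_a", "group_b", "value",
                                     "bandwidth", "n_a", "n_b"])
    # null ISIs (> 400 ms, bout boundaries) carry no finer information than
    # "long"; impute at the exclusion cap so the embedding stays finite
    X = usable[FEATURE_COLUMNS].fillna({"isi_ms": 400.0}).to_numpy()
    emb = EmbeddingSet(standardize(X), usable[["pup", "age", "session"]]
                       .reset_index(drop=True))
    rows = []
    ages = sorted(usable["age"].unique().tolist())
    for age in ages:
        try:
            baselines = within_baseline(emb, "age", age,
                                        n_splits=config.mmd.n_baseline_splits,
                                        seed=config.seed, unbiased=config.mmd.unbiased,
                                        bandwidth=config.mmd.bandwidth)
        except ValueError as exc:
            log.info("skipping within baseline for %s: %s", age, exc)
            continue
        rows.extend({"kind": c.comparison_kind, "group_a": c.groups[0],
                     "group_b": c.groups[1], "value": c.value,
                     "bandwidth": c.bandwidth, "n_a": c.group_sizes[0],
                     "n_b": c.group_sizes[1]} for c in baselines)
    for i, a in enumerate(ages):
        for b in ages[i + 1:]:
            c = between_groups(emb, "age", a, b, bandwidth=config.mmd.bandwidth,
                               unbiased=config.mmd.unbiased)
            rows.append({"kind": c.comparison_kind, "group_a": a, "group_b": b,
                         "value": c.value, "bandwidth": c.bandwidth,
                         "n_a": c.group_sizes[0], "n_b": c.group_sizes[1]})
    return pd.DataFrame(rows)
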