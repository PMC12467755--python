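"""Cohort assembly, filtering, correlation reporting and the run pipeline.

A cohort table has one row per run carrying identity and timing columns
(end_time, tr, tj, tm, validity) plus per-limb coordination metrics (R^2,
mean peak distance, dominant frequency) and the feet phase-synchronicity
index mu_pi.  Reporting filters the table (sex, start technique, end-time
cap), correlates end time against each coordination metric with Pearson's
r and its two-sided p-value, and summarises foot cadence distributions per
end-time interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as sc_io
from .end_time import estimate_and_validate
from .exceptions import (
    EmptyInputError,
    SampleSizeError,
    SpeedClimbError,
    UndefinedCorrelationError,
)
from .kinematics import HoldMap, compute_cog, interpolate_gaps
from .phase import limb_phase_sync
from .sinusoid import SinusoidModel
from .splits import (
    compute_profile,
    movement_initiation,
    section_statistics_from_tidy,
)

logger = logging.getLogger("speedclimb")

LIMB_JOINTS = {
    "left_foot": "left_ankle", "right_foot": "right_ankle",
    "left_hand": "left_wrist", "right_hand": "right_wrist",
}
METRIC_SUFFIXES = ("r2", "peak_distance", "dominant_freq")

#: Default cohort filter mirroring the male-elite analysis subset.
DEFAULT_FILTER = {"sex": "male", "technique": "Tomoa Skip", "max_end_time": 6.0}


@dataclass
class AnalysisConfig:
    """Tunable knobs of the per-run analysis pipeline."""

    cog_model: str = "midhip"        # synthetic skeletons carry COG at midhip
    cog_smoothing: dict = None       # e.g. {"window": 7, "order": 3}
    limb_signal: str = "speed"       # "speed" (2-D magnitude) or "vertical"
    init_strategy: str = "fft"
    t0_threshold: float = 0.2
    t0_hold_frames: int = 2
    roi_descent_frames: int = 2
    end_time_source: str = "tgt"     # correlate against "tgt" or "tm"
    holm_adjust: bool = False


def limb_velocity(track, kind: str = "speed") -> np.ndarray:
    """Velocity signal of a limb keypoint track.

    ``speed`` is the 2-D magnitude of the finite-difference velocity (the
    default); ``vertical`` the signed y-component.
    """
    vx = np.gradient(track.x, track.times)
    vy = np.gradient(track.y, track.times)
    return np.hypot(vx, vy) if kind == "speed" else vy


def analyze_run(tracks: dict, meta, hold_map: HoldMap,
                config: AnalysisConfig = None):
    """Run every per-run stage; returns (row dict, SplitTimeProfile)."""
    config = config or AnalysisConfig()
    tracks = {name: interpolate_gaps(t) for name, t in tracks.items()}
    trace = compute_cog(tracks, model=config.cog_model,
                        smoothing=config.cog_smoothing)
    est = estimate_and_validate(trace, hold_map, meta.tgt,
                                k=config.roi_descent_frames)
    t0, h0 = movement_initiation(trace, config.t0_threshold,
                                 config.t0_hold_frames)
    profile = compute_profile(trace, hold_map, meta, t0, h0)
    row = {
        "run_id": meta.run_id, "athlete_id": meta.athlete_id,
        "sex": meta.sex, "technique": meta.technique,
        "end_time": meta.tgt if config.end_time_source == "tgt" else est.tm,
        "tgt": meta.tgt, "tm": est.tm, "valid": est.valid,
        "relative_error": est.relative_error,
        "tr": profile.tr, "tj": profile.tj,
    }
    for limb, joint in LIMB_JOINTS.items():
        v = limb_velocity(tracks[joint], config.limb_signal)
        try:
            res = SinusoidModel(v, times=tracks[joint].times).fit(
                strategy=config.init_strategy)
            row[f"{limb}_r2"] = res.r2
            row[f"{limb}_peak_distance"] = res.peak_distance
            row[f"{limb}_dominant_freq"] = res.dominant_freq
        except SpeedClimbError as exc:   # failed fits become missing cells
            logger.warning("run %s %s fit failed: %s", meta.run_id, limb, exc)
            for suffix in METRIC_SUFFIXES:
                row[f"{limb}_{suffix}"] = np.nan
    try:
        vl = limb_velocity(tracks["left_ankle"], config.limb_signal)
        vr = limb_velocity(tracks["right_ankle"], config.limb_signal)
        row["mu_pi_feet"] = limb_phase_sync(
            vl, vr, rate=meta.frame_rate).mu_pi
    except SpeedClimbError as exc:
        logger.warning("run %s phase sync failed: %s", meta.run_id, exc)
        row["mu_pi_feet"] = np.nan
    return row, profile


def analyze_cohort(runs, hold_map: HoldMap, config: AnalysisConfig = None):
    """Per-run stages for a whole cohort.

    ``runs`` yields (tracks, metadata) pairs.  Per-run failures are logged
    and the run is marked failed; they never abort the cohort.  Returns a
    dict of DataFrames: ``cohort`` (valid runs only), ``validity`` (all
    runs), ``splits`` (tidy per-hold table of valid runs).
    """
    config = config or AnalysisConfig()
    rows, validity, split_frames = [], [], []
    for tracks, meta in runs:
        try:
            row, profile = analyze_run(tracks, meta, hold_map, config)
        except SpeedClimbError as exc:
            logger.warning("run %s failed: %s", meta.run_id, exc)
            validity.append({"run_id": meta.run_id, "tm": np.nan,
                             "tgt": meta.tgt, "relative_error": np.nan,
                             "valid": False, "failed": True})
            continue
        validity.append({"run_id": meta.run_id, "tm": row["tm"],
                         "tgt": row["tgt"],
                         "relative_error": row["relative_error"],
                         "valid": row["valid"], "failed": False})
        if row["valid"]:
            rows.append(row)
            split_frames.append(profile.to_frame())
    cohort = pd.DataFrame(rows)
    if not cohort.empty and cohort["run_id"].duplicated().any():
        raise ValueError("duplicate run_id in cohort")
    return {
        "cohort": cohort,
        "validity": pd.DataFrame(validity),
        "splits": (pd.concat(split_frames, ignore_index=True)
                   if split_frames else pd.DataFrame()),
    }


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def filter_cohort(table: pd.DataFrame, sex: str = "male",
                  technique: str = "Tomoa Skip",
                  max_end_time: float = 6.0) -> pd.DataFrame:
    """Subset the cohort: sex and technique match, end time strictly below.

    Pass ``None`` for any predicate to leave it out.  An empty result is a
    warning, not an error.
    """
    if table.empty:
        raise EmptyInputError("empty cohort table")
    mask = pd.Series(True, index=table.index)
    if sex is not None:
        mask &= table["sex"] == sex
    if technique is not None:
        mask &= table["technique"] == technique
    if max_end_time is not None and np.isfinite(max_end_time):
        mask &= table["end_time"] < max_end_time
    out = table[mask].reset_index(drop=True)
    if out.empty:
        logger.warning("cohort filter matched no runs")
    return out


def pearson_with_p(x, y):
    """Pearson's r with the two-sided p-value from the t(n-2) distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise SampleSizeError("need n >= 3 for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlation_matrix(table: pd.DataFrame, target: str = "end_time",
                       features=None, holm_adjust: bool = False) -> pd.DataFrame:
    """Pearson r / p / n of the target against each feature column.

    Missing values are dropped pairwise per feature; features that are
    entirely missing are skipped with a logged warning.  ``holm_adjust``
    optionally applies a Holm step-down correction to the p-values (off by
    default; raw p-values are the primary report).
    """
    if len(table) < 10:
        raise SampleSizeError("need >= 10 runs for the correlation report")
    if features is None:
        features = [c for c in table.columns
                    if any(c.endswith(s) for s in METRIC_SUFFIXES)
                    or c.startswith("mu_pi")]
    rows = []
    for feat in features:
        pair = table[[target, feat]].dropna()
        if pair.empty or pair[feat].isna().all():
            logger.warning("feature %s entirely missing; skipped", feat)
            continue
        try:
            r, p = pearson_with_p(pair[target], pair[feat])
        except (SampleSizeError, UndefinedCorrelationError) as exc:
            logger.warning("feature %s: %s", feat, exc)
            continue
        rows.append({"feature": feat, "r": r, "p": p, "n": len(pair)})
    out = pd.DataFrame(rows)
    if holm_adjust and not out.empty:
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_holm"] = adj
    return out


def frequency_by_endtime(table: pd.DataFrame, bins) -> pd.DataFrame:
    """Foot dominant-frequency summaries per end-time interval.

    ``bins`` are end-time bin edges.  Per bin and per foot the mean, sd and
    quartiles of the dominant frequency are reported; empty bins appear
    with n = 0.
    """
    edges = np.asarray(bins, dtype=float)
    if len(edges) < 3:
        raise ValueError("need at least 2 bins")
    labels = pd.cut(table["end_time"], edges)
    rows = []
    for interval in labels.cat.categories:
        sub = table[labels == interval]
        for foot in ("left_foot", "right_foot"):
            x = sub[f"{foot}_dominant_freq"].dropna().to_numpy()
            row = {"bin_low": interval.left, "bin_high": interval.right,
                   "foot": foot, "n": len(x)}
            if len(x):
                q1, med, q3 = np.percentile(x, [25, 50, 75])
                row.update(mean=x.mean(),
                           sd=x.std(ddof=1) if len(x) > 1 else 0.0,
                           q1=q1, median=med, q3=q3)
            else:
                row.update(mean=np.nan, sd=np.nan, q1=np.nan,
                           median=np.nan, q3=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(manifest, hold_map=None, config: AnalysisConfig = None,
                 out_dir=None, cohort_filter: dict = None,
                 endtime_bins=(4.7, 5.0, 5.4, 5.7, 6.0)) -> dict:
    """Manifest -> per-run stages -> cohort filtering and reports.

    ``manifest`` is a manifest CSV path (hold map defaults to ``holds.csv``
    next to it) or an iterable of (tracks, metadata) pairs with an explicit
    ``hold_map``.  When ``out_dir`` is given all tables are written there
    as CSV; outputs are deterministic for identical inputs.
    """
    config = config or AnalysisConfig()
    if isinstance(manifest, (str, Path)):
        manifest = Path(manifest)
        if hold_map is None:
            hold_map = sc_io.read_hold_map(manifest.parent / "holds.csv")
        runs = sc_io.read_manifest(manifest)
    else:
        if hold_map is None:
            raise ValueError("hold_map required for in-memory runs")
        runs = manifest
    results = analyze_cohort(runs, hold_map, config)
    filt = dict(DEFAULT_FILTER, **(cohort_filter or {}))
    if not results["cohort"].empty:
        filtered = filter_cohort(results["cohort"], **filt)
    else:
        filtered = results["cohort"]
    results["filtered"] = filtered
    if not results["splits"].empty:
        stats_ = section_statistics_from_tidy(results["splits"])
        results["section_per_hold"] = stats_.per_hold
        results["section_summary"] = stats_.per_section
    else:
        results["section_per_hold"] = pd.DataFrame()
        results["section_summary"] = pd.DataFrame()
    if len(filtered) >= 10:
        results["correlations"] = correlation_matrix(
            filtered, holm_adjust=config.holm_adjust)
        results["freq_by_endtime"] = frequency_by_endtime(filtered, endtime_bins)
    else:
        results["correlations"] = pd.DataFrame()
        results["freq_by_endtime"] = pd.DataFrame()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in results.items():
            df.to_csv(out_dir / f"{name}.csv", index=False)
    return results
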