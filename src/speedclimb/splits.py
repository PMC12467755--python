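"""Split-time (pacing) analysis.

For each run the absolute crossing times t1..t20 of the 20 hand-hold heights
are extracted from the COG trace and converted to per-hold split times

    dt_i = t_i - t_{i-1},    dh_i = h_i - h_{i-1},    dt_norm_i = dt_i / dh_i,

where (t0, h0) — the movement-initiation time and the COG height at that
instant — anchor the first gap.  Two non-normalised scalars complete the
profile: the reaction time tr = t0 - ts (start signal to first movement) and
the jump time tj = tgt - t20 (last hold to buzzer).  Cohort-level summaries
aggregate dt_norm per hold and per wall section (start / middle / end).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    CannotAnchorError,
    EmptyInputError,
    HoldNotReachedError,
    IncompleteRunError,
    MetadataError,
)
from .kinematics import COGTrace, HoldMap, RunMetadata, crossing_time

#: Default wall-section partition by hold index (1-based, inclusive).
DEFAULT_SECTIONS = {"start": (1, 5), "middle": (6, 13), "end": (14, 20)}

#: Default movement-initiation detection: vertical velocity threshold (m/s)
#: and the number of consecutive frames it must be exceeded.
T0_THRESHOLD = 0.2
T0_HOLD_FRAMES = 2


@dataclass
class SplitTimeProfile:
    """Per-hold split times and scalar timing metrics for one run."""

    run_id: str
    t: np.ndarray          # absolute crossing times t1..t20 (s)
    t0: float              # movement initiation (s)
    h0: float              # COG height at t0 (m)
    dt: np.ndarray         # split times (s)
    dh: np.ndarray         # vertical gaps (m)
    dt_norm: np.ndarray    # normalised split times (s/m)
    tr: float              # reaction time (s)
    tj: float              # jump time (s)

    def __post_init__(self):
        for name in ("t", "dt", "dh", "dt_norm"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("crossing times must be strictly increasing")
        if np.any(self.dh <= 0):
            raise ValueError("vertical gaps must be positive")
        if self.tr < 0:
            raise ValueError("reaction time must be non-negative")
        if self.tj <= 0:
            raise ValueError("jump time must be positive")

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-hold table (run_id, hold_index, t, dt, dh, dt_norm)."""
        return pd.DataFrame({
            "run_id": self.run_id,
            "hold_index": np.arange(1, 21),
            "t": self.t,
            "dt": self.dt,
            "dh": self.dh,
            "dt_norm": self.dt_norm,
        })


@dataclass
class SectionStats:
    """Per-hold and per-section summaries of normalised split times."""

    per_hold: pd.DataFrame    # hold_index, n, mean, median, sd, q1, q3, fences
    per_section: pd.DataFrame  # section, n, mean, median, sd
    outliers: pd.DataFrame     # run_id, hold_index, dt_norm


def movement_initiation(trace: COGTrace, threshold: float = T0_THRESHOLD,
                        hold_frames: int = T0_HOLD_FRAMES):
    """Detect movement initiation (t0, h0) from the vertical COG velocity.

    t0 is the first time velocity exceeds ``threshold`` and stays above it
    for ``hold_frames`` consecutive frames; h0 the COG height then.  The
    trace must begin in quasi-rest (|v| < threshold for at least
    ``hold_frames`` frames).
    """
    v = trace.velocity
    n = len(v)
    if hold_frames < 1:
        raise ValueError("hold_frames must be >= 1")
    if n < 2 * hold_frames:
        raise CannotAnchorError("trace too short to anchor t0")
    if np.any(np.abs(v[:hold_frames]) >= max(threshold, 1e-12)):
        raise CannotAnchorError("no quasi-rest period at the start of the trace")
    above = v > threshold
    for i in range(n - hold_frames + 1):
        if above[i:i + hold_frames].all():
            t = trace.times
            if threshold > 0 and i > 0 and v[i - 1] < threshold:
                # sub-frame refinement: interpolate the threshold crossing
                frac = (threshold - v[i - 1]) / (v[i] - v[i - 1])
                t0 = t[i - 1] + frac * (t[i] - t[i - 1])
                h0 = np.interp(t0, t, trace.position_y)
                return float(t0), float(h0)
            return float(t[i]), float(trace.position_y[i])
    raise CannotAnchorError("velocity never exceeds the initiation threshold")


def compute_profile(trace: COGTrace, hold_map: HoldMap, meta: RunMetadata,
                    t0: float, h0: float) -> SplitTimeProfile:
    """Per-hold split times, reaction time and jump time for one run."""
    try:
        t = np.array([crossing_time(trace, h) for h in hold_map.heights])
    except HoldNotReachedError as exc:
        raise IncompleteRunError(str(exc)) from exc
    if t0 >= t[0]:
        raise IncompleteRunError("t0 is not before the first hold crossing")
    if meta.tgt <= t[-1]:
        raise MetadataError("tgt is not after the last hold crossing")
    anchors_t = np.concatenate(([t0], t))
    anchors_h = np.concatenate(([h0], hold_map.heights))
    dt = np.diff(anchors_t)
    dh = np.diff(anchors_h)
    return SplitTimeProfile(
        run_id=meta.run_id, t=t, t0=t0, h0=h0, dt=dt, dh=dh,
        dt_norm=dt / dh, tr=t0 - meta.ts, tj=meta.tgt - t[-1],
    )


def section_statistics(profiles, sections=None) -> SectionStats:
    """Distribution summaries of dt_norm per hold and per wall section.

    Quartiles use linear interpolation (type-7); outlier fences sit at
    Q1 − 1.5·IQR and Q3 + 1.5·IQR (standard boxplot convention).  Section
    aggregates pool the member-hold values, i.e. hold means enter the
    section mean weighted by their observation counts.
    """
    profiles = list(profiles)
    if not profiles:
        raise EmptyInputError("no profiles supplied")
    tidy = pd.concat([p.to_frame() for p in profiles], ignore_index=True)
    return section_statistics_from_tidy(tidy, sections)


def section_statistics_from_tidy(tidy: pd.DataFrame, sections=None) -> SectionStats:
    """Same as :func:`section_statistics`, from a tidy per-hold table
    (columns run_id, hold_index, dt_norm)."""
    if tidy.empty:
        raise EmptyInputError("no split rows supplied")
    sections = sections or DEFAULT_SECTIONS

    def one_hold(g):
        x = g["dt_norm"].to_numpy()
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        return pd.Series({
            "n": len(x), "mean": x.mean(), "median": med,
            "sd": x.std(ddof=1) if len(x) > 1 else 0.0,
            "q1": q1, "q3": q3,
            "fence_low": q1 - 1.5 * iqr, "fence_high": q3 + 1.5 * iqr,
        })

    per_hold = (tidy.groupby("hold_index").apply(one_hold, include_groups=False)
                .reset_index())
    fences = per_hold.set_index("hold_index")[["fence_low", "fence_high"]]
    merged = tidy.join(fences, on="hold_index")
    mask = ((merged["dt_norm"] < merged["fence_low"])
            | (merged["dt_norm"] > merged["fence_high"]))
    outliers = merged.loc[mask, ["run_id", "hold_index", "dt_norm"]].reset_index(drop=True)

    section_rows = []
    for name, (lo, hi) in sections.items():
        x = tidy.loc[tidy["hold_index"].between(lo, hi), "dt_norm"].to_numpy()
        section_rows.append({
            "section": name, "first_hold": lo, "last_hold": hi, "n": len(x),
            "mean": x.mean() if len(x) else np.nan,
            "median": float(np.median(x)) if len(x) else np.nan,
            "sd": x.std(ddof=1) if len(x) > 1 else 0.0,
        })
    return SectionStats(per_hold=per_hold,
                        per_section=pd.DataFrame(section_rows),
                        outliers=outliers)


def velocity_by_height(traces, bin_width: float = 0.05, h_max: float = None,
                       ddof: int = 1) -> pd.DataFrame:
    """Mean/sd of vertical COG velocity in height bins pooled across runs.

    Bins of ``bin_width`` metres span [0, h_max] (default: the highest
    position observed).  Each run contributes its own per-bin mean velocity;
    the reported mean and sd are taken across runs, so runs of different
    speed are weighted equally regardless of how many frames they spend in
    a bin.  Empty bins are reported with n = 0, not an error.
    """
    traces = list(traces)
    if not traces:
        raise EmptyInputError("no traces supplied")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if h_max is None:
        h_max = float(max(tr.position_y.max() for tr in traces))
    edges = np.arange(0.0, h_max + bin_width, bin_width)
    n_bins = len(edges) - 1
    per_trace = np.full((len(traces), n_bins), np.nan)
    for k, tr in enumerate(traces):
        idx = np.digitize(tr.position_y, edges) - 1
        for b in range(n_bins):
            sel = tr.velocity[idx == b]
            if len(sel):
                per_trace[k, b] = sel.mean()
    rows = []
    for b in range(n_bins):
        col = per_trace[:, b]
        col = col[~np.isnan(col)]
        rows.append({
            "h_low": edges[b], "h_high": edges[b + 1], "n": len(col),
            "mean": col.mean() if len(col) else np.nan,
            "sd": (col.std(ddof=ddof) if len(col) > ddof else
                   (0.0 if len(col) else np.nan)),
        })
    return pd.DataFrame(rows)
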