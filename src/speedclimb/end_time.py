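"""Buzzer-touch (end-time) estimation from the COG velocity profile.

The finishing touch is not directly observable in keypoint data.  Within a
region of interest — from the COG crossing the height of the last hand hold
(t1) to the onset of downward body movement (t2) — the touch time tm is
identified as the inflection point of the last decay phase of the vertical
COG velocity: the sub-frame instant where the second derivative of velocity
crosses zero.  A run is kept for cohort analysis only when tm agrees with
the scoreboard time tgt to within 5 % (boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import (
    IncompleteRunError,
    MetadataError,
    NoDecayError,
    NoInflectionError,
    TruncatedRecordingError,
    HoldNotReachedError,
)
from .kinematics import COGTrace, HoldMap, crossing_time

#: Relative deviation from the documented finishing time tolerated by the
#: dataset validity filter.
VALIDITY_THRESHOLD = 0.05

#: Minimum length (samples) of a decreasing-velocity run counted as a decay
#: phase.
MIN_DECAY_SAMPLES = 3


@dataclass
class EndTimeEstimate:
    """Result of end-time estimation and the 5 % validity check."""

    t1: float
    t2: float
    tm: float
    valid: bool
    relative_error: float
    tgt: float = None

    def __post_init__(self):
        if self.t1 is not None and self.t2 is not None:
            if not (self.t1 < self.tm < self.t2):
                raise ValueError("tm must lie strictly inside (t1, t2)")


def detect_roi(trace: COGTrace, hold_map: HoldMap, k: int = 2):
    """Locate the end-time region of interest (t1, t2).

    t1 is the upward crossing of the last hold's height; t2 the first time
    after t1 at which vertical velocity is negative for ``k`` consecutive
    frames (the initiation of downward body movement).
    """
    try:
        t1 = crossing_time(trace, hold_map.top)
    except HoldNotReachedError as exc:
        raise IncompleteRunError("COG never crosses the last hold") from exc
    after = trace.times > t1
    idx = np.flatnonzero(after)
    v = trace.velocity
    neg = v < 0
    count = 0
    for i in idx:
        count = count + 1 if neg[i] else 0
        if count >= k:
            return t1, float(trace.times[i - k + 1])
    raise TruncatedRecordingError(
        "no sustained downward movement after the last hold crossing"
    )


def _decreasing_runs(v: np.ndarray):
    """Maximal runs (start, stop inclusive) of strictly decreasing samples."""
    runs = []
    start = None
    for i in range(len(v) - 1):
        if v[i + 1] < v[i]:
            if start is None:
                start = i
        else:
            if start is not None:
                runs.append((start, i))
                start = None
    if start is not None:
        runs.append((start, len(v) - 1))
    return runs


def estimate_end_time(trace: COGTrace, roi, smoothing=None) -> float:
    """Inflection of the last velocity decay phase inside the ROI.

    The last maximal run of strictly decreasing velocity samples (minimum
    :data:`MIN_DECAY_SAMPLES` long) is selected; within it the second
    derivative of velocity — double central differencing of the optionally
    smoothed velocity — is scanned for sign changes, and the sub-frame time
    of the LAST zero crossing is returned.
    """
    t1, t2 = roi
    sel = (trace.times >= t1) & (trace.times <= t2)
    t = trace.times[sel]
    v = trace.velocity[sel]
    if len(t) < 5:
        raise NoDecayError("ROI contains fewer than 5 samples")
    if smoothing:
        window = int(smoothing.get("window", 7))
        order = int(smoothing.get("order", 3))
        if window > len(v):
            window = len(v) if len(v) % 2 else len(v) - 1
        if window > order:
            v = savgol_filter(v, window, order)
    runs = [r for r in _decreasing_runs(v) if r[1] - r[0] + 1 >= MIN_DECAY_SAMPLES]
    if not runs:
        raise NoDecayError("no decay phase (decreasing velocity) in ROI")
    lo, hi = runs[-1]
    d1 = np.gradient(v, t)
    d2 = np.gradient(d1, t)
    # sign changes of d2 inside the decay run, sub-frame by linear interp;
    # an identically-zero d2 (linear velocity) is NOT an inflection, but an
    # exact zero sample flanked by opposite signs is.
    seg = d2[lo:hi + 1]
    tseg = t[lo:hi + 1]
    nz = np.flatnonzero(seg != 0.0)
    crossings = []
    for a, b in zip(nz[:-1], nz[1:]):
        if seg[a] * seg[b] < 0:
            if b == a + 1:
                tc = tseg[a] - seg[a] * (tseg[b] - tseg[a]) / (seg[b] - seg[a])
            else:  # zero plateau between opposite signs: take its midpoint
                zs = tseg[a + 1:b]
                tc = zs[len(zs) // 2]
            crossings.append(float(tc))
    if not crossings:
        raise NoInflectionError(
            "second derivative has no sign change in the last decay phase"
        )
    tm = crossings[-1]
    return float(min(max(tm, np.nextafter(t1, t2)), np.nextafter(t2, t1)))


def validate_run(tm: float, tgt: float, t1: float = None,
                 t2: float = None) -> EndTimeEstimate:
    """Apply the 5 % validity criterion |tm − tgt| ≤ 0.05·tgt (inclusive)."""
    if tgt is None or tgt <= 0:
        raise MetadataError("tgt must be positive")
    err = abs(tm - tgt) / tgt
    return EndTimeEstimate(
        t1=t1, t2=t2, tm=tm, valid=bool(err <= VALIDITY_THRESHOLD),
        relative_error=float(err), tgt=tgt,
    )


def estimate_and_validate(trace: COGTrace, hold_map: HoldMap, tgt: float,
                          k: int = 2, smoothing=None) -> EndTimeEstimate:
    """Convenience: ROI detection, inflection estimate and validity filter."""
    roi = detect_roi(trace, hold_map, k=k)
    tm = estimate_end_time(trace, roi, smoothing=smoothing)
    return validate_run(tm, tgt, t1=roi[0], t2=roi[1])
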