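"""Core kinematic types and operations.

Coordinates are wall-plane metres with the y-axis pointing up and the origin
at the wall base; time is in seconds from the start of the recording and
frames are 0-based.  Everything downstream (end-time detection, split times,
limb coordination) consumes the types defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import (
    ConfigurationError,
    HoldNotReachedError,
    ResamplingRequiredError,
    UnusableTrackError,
)

#: Relative tolerance (fraction of the nominal frame interval) for treating
#: timestamps as uniformly sampled.
UNIFORMITY_TOL = 0.01

#: Allowed sampling-rate range in Hz for keypoint input.
RATE_RANGE = (20.0, 120.0)

#: Default wall height in metres (standardised 15 m speed route).
WALL_HEIGHT = 15.0

# Per-joint mass-fraction stand-in used to collapse a keypoint skeleton to a
# single centre-of-gravity point.  This is a documented approximation in the
# spirit of classic segment-inertia tables (trunk mass assigned to shoulders
# and hips, limbs to their distal joints); it is NOT an official model.
DEFAULT_SEGMENT_WEIGHTS = {
    "left_shoulder": 0.14,
    "right_shoulder": 0.14,
    "left_hip": 0.21,
    "right_hip": 0.21,
    "left_knee": 0.06,
    "right_knee": 0.06,
    "left_ankle": 0.03,
    "right_ankle": 0.03,
    "left_wrist": 0.03,
    "right_wrist": 0.03,
    "head": 0.06,
}


def _as_1d(a, name):
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    return arr


def sampling_rate(times: np.ndarray) -> float:
    """Nominal sampling rate in Hz derived from median frame interval."""
    dt = np.median(np.diff(times))
    if dt <= 0:
        raise ValueError("times must be strictly increasing")
    return 1.0 / dt


def check_uniform(times: np.ndarray, tol: float = UNIFORMITY_TOL) -> float:
    """Validate near-uniform sampling; return the nominal interval.

    Raises :class:`ResamplingRequiredError` when any interval deviates from
    the nominal (median) interval by more than ``tol`` relative.
    """
    diffs = np.diff(times)
    if len(diffs) == 0:
        raise ValueError("need at least 2 samples")
    nominal = float(np.median(diffs))
    if nominal <= 0 or np.any(diffs <= 0):
        raise ValueError("times must be strictly increasing")
    if np.max(np.abs(diffs - nominal)) > tol * nominal:
        raise ResamplingRequiredError(
            "timestamps deviate from uniform sampling by more than "
            f"{tol:.0%} of the nominal interval; resample first"
        )
    return nominal


@dataclass
class KeypointTrack:
    """Per-joint time series of 2-D wall-plane positions with gap flags.

    Parameters
    ----------
    joint_name : str
        Skeleton joint label, e.g. ``"left_ankle"``.
    times : (n,) array of float
        Frame timestamps in seconds, strictly increasing, near-uniform.
    positions : (n, 2) array of float
        Wall-plane (x, y) positions in metres per frame.
    valid_mask : (n,) array of bool
        False marks occluded / missing detections.
    """

    joint_name: str
    times: np.ndarray
    positions: np.ndarray
    valid_mask: np.ndarray = None

    def __post_init__(self):
        self.times = _as_1d(self.times, "times")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n, 2)")
        if self.valid_mask is None:
            self.valid_mask = np.ones(len(self.times), dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        n = len(self.times)
        if len(self.positions) != n or len(self.valid_mask) != n:
            raise ValueError("times, positions and valid_mask lengths differ")
        if n >= 2:
            rate = sampling_rate(self.times)
            if not (RATE_RANGE[0] <= rate <= RATE_RANGE[1]):
                raise ValueError(
                    f"sampling rate {rate:.1f} Hz outside {RATE_RANGE}"
                )
        if not np.all(np.isfinite(self.positions[self.valid_mask])):
            raise ValueError("non-finite positions at frames flagged valid")

    def __len__(self):
        return len(self.times)

    @property
    def rate(self) -> float:
        return sampling_rate(self.times)

    @property
    def x(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.positions[:, 1]


@dataclass
class RunMetadata:
    """Per-run annotations: identity, start signal ts and scoreboard time tgt."""

    run_id: str
    athlete_id: str
    sex: str
    technique: str
    ts: float
    tgt: float
    frame_rate: float

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")
        if self.tgt <= 0:
            raise ValueError("tgt must be positive")
        if self.ts < 0:
            raise ValueError("ts must be non-negative")
        if not (RATE_RANGE[0] <= self.frame_rate <= RATE_RANGE[1]):
            raise ValueError(f"frame_rate outside {RATE_RANGE}")


@dataclass
class HoldMap:
    """Heights of hand holds 1..20 on the wall, strictly increasing."""

    heights: np.ndarray
    wall_height: float = WALL_HEIGHT

    def __post_init__(self):
        self.heights = _as_1d(self.heights, "heights")
        if len(self.heights) != 20:
            raise ValueError("hold map must contain exactly 20 heights")
        if np.any(np.diff(self.heights) <= 0):
            raise ValueError("hold heights must be strictly increasing")
        if self.heights[-1] > self.wall_height:
            raise ValueError("top hold above wall height")

    def __len__(self):
        return 20

    @property
    def top(self) -> float:
        return float(self.heights[-1])


def example_hold_map(first: float = 1.9, top: float = 15.0) -> HoldMap:
    """A synthetic, evenly spaced 20-hold example map.

    The official route's hold heights are not bundled with this package;
    this map is a plausible non-official stand-in (holds every ~0.69 m from
    ``first`` up to ``top``) for demos and tests.  Supply the real map for
    real analyses.
    """
    return HoldMap(np.linspace(first, top, 20))


@dataclass
class COGTrace:
    """Centre-of-gravity trajectory: vertical position, velocity, acceleration.

    ``velocity`` is the vertical component of the COG velocity (the quantity
    the end-time and split-time analyses are defined on); ``acceleration``
    its derivative.  Both derive from ``position_y`` by the configured finite
    difference unless supplied explicitly (useful for analytic test traces).
    """

    times: np.ndarray
    position_y: np.ndarray
    velocity: np.ndarray = None
    acceleration: np.ndarray = None

    def __post_init__(self):
        self.times = _as_1d(self.times, "times")
        self.position_y = _as_1d(self.position_y, "position_y")
        if len(self.position_y) != len(self.times):
            raise ValueError("times and position_y lengths differ")
        if self.velocity is None:
            self.velocity = estimate_velocity(self.times, self.position_y)
        else:
            self.velocity = _as_1d(self.velocity, "velocity")
        if self.acceleration is None:
            self.acceleration = estimate_velocity(self.times, self.velocity)
        else:
            self.acceleration = _as_1d(self.acceleration, "acceleration")
        if not (len(self.velocity) == len(self.acceleration) == len(self.times)):
            raise ValueError("field lengths differ")

    def __len__(self):
        return len(self.times)

    @property
    def rate(self) -> float:
        return sampling_rate(self.times)

    @classmethod
    def from_position(cls, times, position_y, smoothing=None) -> "COGTrace":
        """Build a trace from position only, differentiating numerically."""
        times = _as_1d(times, "times")
        position_y = _as_1d(position_y, "position_y")
        v = estimate_velocity(times, position_y, smoothing=smoothing)
        a = estimate_velocity(times, v)
        return cls(times=times, position_y=position_y, velocity=v, acceleration=a)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def interpolate_gaps(track: KeypointTrack) -> KeypointTrack:
    """Fill occlusion gaps by linear interpolation between valid neighbours.

    Leading / trailing invalid frames are trimmed (interpolation has no
    anchor there).  Valid samples are never modified, and the operation is
    idempotent.  Raises :class:`UnusableTrackError` with < 2 valid frames.
    """
    mask = track.valid_mask
    if mask.sum() < 2:
        raise UnusableTrackError(
            f"track {track.joint_name!r} has {int(mask.sum())} valid frames"
        )
    first = int(np.argmax(mask))
    last = len(mask) - 1 - int(np.argmax(mask[::-1]))
    times = track.times[first:last + 1]
    pos = track.positions[first:last + 1].copy()
    sub = mask[first:last + 1]
    if not sub.all():
        tv = times[sub]
        for axis in range(2):
            pos[~sub, axis] = np.interp(times[~sub], tv, pos[sub, axis])
    return KeypointTrack(
        joint_name=track.joint_name,
        times=times,
        positions=pos,
        valid_mask=np.ones(len(times), dtype=bool),
    )


def estimate_velocity(times, positions, smoothing=None) -> np.ndarray:
    """Finite-difference velocity: central interior, one-sided at the ends.

    ``smoothing`` may be ``None`` (off, the default) or a mapping with keys
    ``window`` (odd int, default 7) and ``order`` (default 3) selecting a
    Savitzky-Golay local-polynomial smooth applied to the *positions* before
    differencing — never after.  The result has the input length.
    """
    times = _as_1d(times, "times")
    positions = _as_1d(positions, "positions")
    if len(times) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    check_uniform(times)
    if smoothing:
        window = int(smoothing.get("window", 7))
        order = int(smoothing.get("order", 3))
        if window > len(positions):
            window = len(positions) if len(positions) % 2 else len(positions) - 1
        if window > order:
            positions = savgol_filter(positions, window, order)
    return np.gradient(positions, times)


def compute_cog(tracks, model: str = "segment_weights", weights=None,
                smoothing=None) -> COGTrace:
    """Collapse a set of gap-free keypoint tracks to a COG trace.

    Parameters
    ----------
    tracks : mapping joint_name -> KeypointTrack, or iterable of tracks
    model : {"segment_weights", "midhip"}
        ``segment_weights`` takes a mass-fraction weighted mean of joint
        y-positions (weights default to :data:`DEFAULT_SEGMENT_WEIGHTS`,
        restricted and renormalised to the joints present — all listed
        joints must exist unless explicit ``weights`` are given);
        ``midhip`` is the unweighted mean of left and right hip.
    weights : mapping joint_name -> float, optional
        Explicit weights; must sum to 1 and reference available joints.
    """
    if not isinstance(tracks, dict):
        tracks = {t.joint_name: t for t in tracks}
    if not tracks:
        raise ConfigurationError("no tracks supplied")
    ref = next(iter(tracks.values()))
    for t in tracks.values():
        if not t.valid_mask.all():
            raise ConfigurationError(
                f"track {t.joint_name!r} has gaps; run interpolate_gaps first"
            )
        if len(t) != len(ref) or not np.allclose(t.times, ref.times, atol=1e-9):
            raise ConfigurationError("tracks have differing time bases")

    if model == "midhip":
        needed = ("left_hip", "right_hip")
        missing = [j for j in needed if j not in tracks]
        if missing:
            raise ConfigurationError(f"midhip model requires joints {missing}")
        w = {j: 0.5 for j in needed}
    elif model == "segment_weights":
        if weights is None:
            w = {j: wt for j, wt in DEFAULT_SEGMENT_WEIGHTS.items() if j in tracks}
            if not w:
                raise ConfigurationError(
                    "no joints matching the default segment-weight table"
                )
            total = sum(w.values())
            w = {j: wt / total for j, wt in w.items()}
        else:
            missing = [j for j in weights if j not in tracks]
            if missing:
                raise ConfigurationError(f"weighted joints missing: {missing}")
            total = sum(weights.values())
            if not np.isclose(total, 1.0):
                raise ConfigurationError("weights must sum to 1")
            w = dict(weights)
    else:
        raise ConfigurationError(f"unknown COG model {model!r}")

    y = np.zeros(len(ref))
    for joint, wt in w.items():
        y += wt * tracks[joint].y
    return COGTrace.from_position(ref.times, y, smoothing=smoothing)


def crossing_time(trace: COGTrace, h: float) -> float:
    """First upward crossing of height ``h``, sub-frame by linear interpolation.

    If a sample hits ``h`` exactly, the earliest such sample's time is
    returned.  Raises :class:`HoldNotReachedError` when the trace never
    crosses ``h`` going up.
    """
    y = trace.position_y
    t = trace.times
    hits = np.flatnonzero(y == h)
    below = y[:-1] < h
    above = y[1:] > h
    cross = np.flatnonzero(below & above)
    candidates = []
    if hits.size:
        # exact hit counts as a crossing only if motion is (weakly) upward
        candidates.append((t[hits[0]], hits[0]))
    if cross.size:
        i = cross[0]
        ti = t[i] + (h - y[i]) * (t[i + 1] - t[i]) / (y[i + 1] - y[i])
        candidates.append((ti, i))
    if not candidates:
        raise HoldNotReachedError(f"no upward crossing of h={h} m")
    return float(min(candidates)[0])
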