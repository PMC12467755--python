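"""Synthetic speed-climbing run and cohort generator.

Real competition keypoint data cannot be redistributed, so this module
generates runs with the statistical structure the analysis assumes and with
full embedded ground truth: a COG trajectory rising monotonically through
the hold heights at configured normalised split times, a terminal velocity
decay whose inflection sits at a known buzzer-touch time, approximately
mono-frequent sinusoidal limb velocities with anti-phase left/right feet,
occlusion gaps in hand tracks, and cohorts with a planted correlation
between end time and foot cadence (with frequency dispersion growing for
slower runs).

Determinism contract: identical (config, seed) give bit-identical output.
Every public operation derives its own named substream from the seed, so
the pieces of an assembled run match the same operations called standalone,
and cohort generation is order-independent across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .exceptions import ConfigurationError
from .kinematics import COGTrace, HoldMap, KeypointTrack, RunMetadata, example_hold_map
from .splits import DEFAULT_SECTIONS

#: Per-section normalised split-time means (s/m) used as generator defaults:
#: start, middle, end.
DEFAULT_SPLIT_PROFILE = (0.39, 0.38, 0.45)

#: Per-section split-time scatter (s/m) used when cohort noise is enabled.
SECTION_SIGMA = (0.028, 0.033, 0.035)

# substream tags: cog / limb / occlusion / cohort draws
_STREAM_COG, _STREAM_LIMB, _STREAM_OCCL, _STREAM_COHORT = 0, 1, 2, 3


def _rng(seed: int, stream: int, extra=()) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream, *extra]))


@dataclass
class LimbParams:
    """Sinusoid parameters of one limb's speed signal."""

    A: float = 1.2        # amplitude, m/s
    f: float = 1.8        # frequency, Hz
    phi: float = 0.0      # phase, rad
    C: float = 1.8        # offset, m/s
    noise_sd: float = 0.0  # white-noise sd, m/s


LIMBS = ("left_foot", "right_foot", "left_hand", "right_hand")


@dataclass
class SyntheticRunConfig:
    """Full parameterisation of one synthetic run.

    Defaults are the study conditions the analysis targets: 30 Hz sampling,
    section split-time means (0.39, 0.38, 0.45) s/m, reaction time 0.13 s
    (cohort median), jump time 0.45 s, foot cadence ~1.8 Hz with anti-phase
    left/right feet.
    """

    frame_rate: float = 30.0
    hold_map: HoldMap = None
    split_profile: tuple = DEFAULT_SPLIT_PROFILE   # per-section or per-hold
    split_noise_sd: tuple = (0.0, 0.0, 0.0)        # per-section sd, s/m
    reaction_time: float = 0.13
    jump_time: float = 0.45
    ts: float = 0.0
    start_height: float = 1.0
    limb_params: dict = None
    foot_phase_offset: float = np.pi
    hand_phase_offset: float = np.pi
    occlusion_rate: float = 0.0
    cog_noise_sd: float = 0.0
    terminal_velocity_frac: float = 0.3
    run_id: str = "run-000"
    athlete_id: str = "athlete-000"
    sex: str = "male"
    technique: str = "Tomoa Skip"

    def __post_init__(self):
        if self.hold_map is None:
            self.hold_map = example_hold_map()
        if self.limb_params is None:
            self.limb_params = {
                "left_foot": LimbParams(phi=0.0),
                "right_foot": LimbParams(phi=float(self.foot_phase_offset)),
                "left_hand": LimbParams(A=1.0, f=1.7, phi=0.0, C=1.6),
                "right_hand": LimbParams(A=1.0, f=1.7,
                                         phi=float(self.hand_phase_offset), C=1.6),
            }
        if not (0 < self.frame_rate):
            raise ConfigurationError("frame_rate must be positive")
        if np.shape(self.split_profile) not in ((3,), (20,)):
            raise ConfigurationError("split_profile must have 3 or 20 entries")
        for limb, p in self.limb_params.items():
            if not (0 < p.f < self.frame_rate / 2):
                raise ConfigurationError(
                    f"{limb}: frequency {p.f} outside (0, Nyquist)")
            if p.noise_sd < 0:
                raise ConfigurationError(f"{limb}: negative noise_sd")
        if not (0 <= self.occlusion_rate <= 0.3):
            raise ConfigurationError("occlusion_rate must be in [0, 0.3]")
        if self.reaction_time < 0 or self.jump_time <= 0:
            raise ConfigurationError("reaction_time >= 0 and jump_time > 0 required")
        if self.cog_noise_sd < 0:
            raise ConfigurationError("cog_noise_sd must be non-negative")
        if not (0 < self.terminal_velocity_frac < 1):
            raise ConfigurationError("terminal_velocity_frac must be in (0, 1)")


@dataclass
class GroundTruth:
    """Planted quantities an analysis stage should recover."""

    true_crossing_times: np.ndarray
    true_tm: float
    true_t0: float
    true_limb_params: dict
    true_mu_pi: float

    def __post_init__(self):
        self.true_crossing_times = np.asarray(self.true_crossing_times, dtype=float)
        if np.any(np.diff(self.true_crossing_times) <= 0):
            raise ValueError("crossing times must be strictly increasing")
        if self.true_tm <= self.true_crossing_times[-1]:
            raise ValueError("true_tm must follow the last crossing")

    @property
    def tgt(self) -> float:
        """Scoreboard end time: true_tm rounded to 0.01 s."""
        return round(self.true_tm, 2)


def _section_of_hold(i: int) -> int:
    """0/1/2 for start/middle/end, hold index 1-based."""
    for s, (name, (lo, hi)) in enumerate(DEFAULT_SECTIONS.items()):
        if lo <= i <= hi:
            return s
    raise ValueError(f"hold index {i} outside 1..20")


def _dt_norm_per_hold(config: SyntheticRunConfig, rng) -> np.ndarray:
    """Per-hold normalised split times (s/m), section means plus noise."""
    prof = np.asarray(config.split_profile, dtype=float)
    if prof.shape == (20,):
        base = prof.copy()
    elif prof.shape == (3,):
        base = np.array([prof[_section_of_hold(i)] for i in range(1, 21)])
    else:
        raise ConfigurationError("split_profile must have 3 or 20 entries")
    sds = np.asarray(config.split_noise_sd, dtype=float)
    if sds.shape == (3,):
        sds = np.array([sds[_section_of_hold(i)] for i in range(1, 21)])
    elif sds.shape != (20,):
        raise ConfigurationError("split_noise_sd must have 3 or 20 entries")
    out = base + rng.normal(0.0, 1.0, 20) * sds
    out = np.clip(out, 0.05, None)
    if np.any(out <= 0):
        raise ConfigurationError("split profile implies non-increasing crossings")
    return out


def _plan_run(config: SyntheticRunConfig, rng):
    """Crossing schedule: (t0, crossing times t1..t20, true_tm)."""
    t0 = config.ts + config.reaction_time
    h = config.hold_map.heights
    dh = np.diff(np.concatenate(([config.start_height], h)))
    if np.any(dh <= 0):
        raise ConfigurationError("start_height must lie below the first hold")
    dtn = _dt_norm_per_hold(config, rng)
    t = t0 + np.cumsum(dtn * dh)
    return t0, t, float(t[-1] + config.jump_time)


def _terminal_coeffs(config, v20):
    """Cubic velocity v(u) = alpha*u^3 + beta*u + vm in u = t - tm.

    alpha < 0 and beta < 0 make the velocity strictly decreasing over the
    whole terminal segment with its (only) inflection exactly at u = 0;
    continuity v(-jump_time) = v20 fixes beta given alpha.
    """
    jt = config.jump_time
    vm = config.terminal_velocity_frac * v20
    alpha = -0.9 * (v20 - vm) / jt ** 3
    u20 = -jt
    beta = (v20 - vm - alpha * u20 ** 3) / u20
    return alpha, beta, vm


def generate_cog_trajectory(config: SyntheticRunConfig, seed: int):
    """Synthesise a COG trace with known crossing times and buzzer time.

    The climb is a monotone (PCHIP) spline through the hold heights at the
    planned crossing times, preceded by a rest of length ``reaction_time``;
    past the last hold the vertical velocity follows a cubic decay whose
    second derivative crosses zero exactly at ``true_tm``, turning into
    downward motion shortly after (so the end-time ROI is well defined).

    Returns (COGTrace, GroundTruth).
    """
    rng = _rng(seed, _STREAM_COG)
    t0, t_cross, tm = _plan_run(config, rng)
    h = config.hold_map.heights
    knots_t = [0.0]
    knots_h = [config.start_height]
    for anchor in (config.ts, t0):
        if anchor > knots_t[-1] + 1e-12:
            knots_t.append(anchor)
            knots_h.append(config.start_height)
    knots_t.extend(t_cross)
    knots_h.extend(h)
    spline = PchipInterpolator(np.array(knots_t), np.array(knots_h))
    v20 = float(spline.derivative()(t_cross[-1]))
    alpha, beta, vm = _terminal_coeffs(config, v20)
    jt = config.jump_time

    # apex (first positive root of the terminal velocity) and trace end
    roots = np.roots([alpha, 0.0, beta, vm])
    real = roots[np.abs(roots.imag) < 1e-9].real
    pos = real[real > 0]
    if len(pos) == 0:
        raise ConfigurationError("terminal decay never reaches zero velocity")
    u_apex = float(pos.min())
    t_end = tm + u_apex + 0.3

    dt = 1.0 / config.frame_rate
    times = np.arange(int(np.floor(t_end / dt)) + 1) * dt
    y = np.empty_like(times)
    before = times <= t_cross[-1]
    y[before] = spline(times[before])
    u = times[~before] - tm
    u20 = -jt
    y[~before] = (h[-1]
                  + alpha * (u ** 4 - u20 ** 4) / 4
                  + beta * (u ** 2 - u20 ** 2) / 2
                  + vm * (u - u20))
    if config.cog_noise_sd > 0:
        y = y + rng.normal(0.0, config.cog_noise_sd, len(y))
    trace = COGTrace.from_position(times, y)
    truth = GroundTruth(
        true_crossing_times=t_cross, true_tm=tm, true_t0=t0,
        true_limb_params=config.limb_params, true_mu_pi=_planted_mu_pi(config),
    )
    return trace, truth


def _planted_mu_pi(config: SyntheticRunConfig) -> float:
    """Analytic mu_pi of the feet pair: |offset - pi| for equal frequencies."""
    pl = config.limb_params["left_foot"]
    pr = config.limb_params["right_foot"]
    if pl.f != pr.f:
        return float("nan")
    offset = np.mod(pr.phi - pl.phi, 2 * np.pi)
    return float(abs(offset - np.pi))


def generate_limb_velocities(config: SyntheticRunConfig, seed: int, times=None):
    """Sinusoid-plus-noise speed series for all four limbs.

    Each limb's speed is A*sin(2*pi*f*t + phi) + C plus white noise of the
    configured sd, sampled on ``times`` (default: the COG trace time grid
    for the same seed).  Returns (dict limb -> series, GroundTruth).
    """
    if times is None:
        trace, truth = generate_cog_trajectory(config, seed)
        times = trace.times
    else:
        rng_plan = _rng(seed, _STREAM_COG)
        t0, t_cross, tm = _plan_run(config, rng_plan)
        truth = GroundTruth(
            true_crossing_times=t_cross, true_tm=tm, true_t0=t0,
            true_limb_params=config.limb_params,
            true_mu_pi=_planted_mu_pi(config),
        )
        times = np.asarray(times, dtype=float)
    rng = _rng(seed, _STREAM_LIMB)
    out = {}
    for limb in LIMBS:
        p = config.limb_params[limb]
        clean = p.A * np.sin(2 * np.pi * p.f * times + p.phi) + p.C
        noise = rng.normal(0.0, p.noise_sd, len(times)) if p.noise_sd > 0 else 0.0
        out[limb] = clean + noise
    return out, truth


_JOINT_OF_LIMB = {
    "left_foot": "left_ankle", "right_foot": "right_ankle",
    "left_hand": "left_wrist", "right_hand": "right_wrist",
}
_LIMB_X = {"left_ankle": -0.2, "right_ankle": 0.2,
           "left_wrist": -0.25, "right_wrist": 0.25}
_LIMB_Y0 = {"left_ankle": 0.2, "right_ankle": 0.2,
            "left_wrist": 1.5, "right_wrist": 1.5}


def assemble_run(config: SyntheticRunConfig, seed: int):
    """Full synthetic run: keypoint tracks, metadata and ground truth.

    The hip pair carries the whole-body COG (midhip == COG by construction);
    ankle/wrist tracks integrate the limb speed signals into monotone upward
    paths (speed magnitude equals the planted sinusoid as long as it stays
    positive, which the default C > A guarantees in the noiseless case).
    Hand tracks are occluded at ``occlusion_rate`` (never the first or last
    frame); feet are never masked.

    Returns (dict joint_name -> KeypointTrack, RunMetadata, GroundTruth).
    """
    trace, truth = generate_cog_trajectory(config, seed)
    limb_v, _ = generate_limb_velocities(config, seed, times=trace.times)
    rng = _rng(seed, _STREAM_OCCL)
    times = trace.times
    dt = 1.0 / config.frame_rate
    tracks = {}
    for hip, x in (("left_hip", -0.1), ("right_hip", 0.1)):
        pos = np.column_stack([np.full(len(times), x), trace.position_y])
        tracks[hip] = KeypointTrack(hip, times, pos)
    for limb, joint in _JOINT_OF_LIMB.items():
        v = limb_v[limb]
        y = _LIMB_Y0[joint] + np.concatenate(
            ([0.0], np.cumsum((v[:-1] + v[1:]) / 2 * dt)))
        pos = np.column_stack([np.full(len(times), _LIMB_X[joint]), y])
        mask = np.ones(len(times), dtype=bool)
        if "wrist" in joint and config.occlusion_rate > 0:
            occl = rng.random(len(times)) < config.occlusion_rate
            occl[0] = occl[-1] = False
            mask = ~occl
        tracks[joint] = KeypointTrack(joint, times, pos, mask)
    meta = RunMetadata(
        run_id=config.run_id, athlete_id=config.athlete_id, sex=config.sex,
        technique=config.technique, ts=config.ts, tgt=truth.tgt,
        frame_rate=config.frame_rate,
    )
    return tracks, meta, truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """A planted cohort: per-run configs/seeds plus the planted-value table."""

    configs: list
    seeds: list
    table: pd.DataFrame            # run_id, athlete_id, end_time, planted freqs
    planted_correlation: float

    def assemble(self):
        """Yield (tracks, metadata, ground_truth) per run."""
        for cfg, seed in zip(self.configs, self.seeds):
            yield assemble_run(cfg, seed)


def generate_cohort(n_runs: int = 321, planted_correlation: float = -0.7,
                    seed: int = 0, end_time_range=(4.7, 6.0),
                    n_athletes: int = 63, freq_center: float = 1.85,
                    freq_sd_base: float = 0.05, freq_sd_slope: float = 0.12,
                    split_noise_sd=SECTION_SIGMA, limb_noise_sd: float = 0.15,
                    occlusion_rate: float = 0.05,
                    hand_freq: float = 1.7, hand_freq_sd: float = 0.1,
                    frame_rate: float = 30.0) -> SyntheticCohort:
    """Generate a cohort with a planted end-time/foot-frequency correlation.

    End times are uniform on ``end_time_range``; the foot frequency of each
    run is Gaussian given its end time, with a linear mean whose slope is
    solved in closed form so the population Pearson correlation equals
    ``planted_correlation``, and a linearly increasing sd (slower runs show
    more cadence scatter).  Hand frequencies are drawn independently of end
    time, so hand metrics act as planted-null features.

    Per-run randomness comes from a substream keyed on (seed, run index),
    making generation order-independent.
    """
    if n_runs < 10:
        raise ConfigurationError("n_runs must be >= 10")
    r = float(planted_correlation)
    if not (-1.0 < r < 1.0):
        raise ConfigurationError("|planted correlation| must be < 1")
    lo, hi = end_time_range
    if not hi > lo:
        raise ConfigurationError("end_time_range must be increasing")
    span = hi - lo
    var_e = span ** 2 / 12.0
    # E[sd(e)^2] for e ~ U(lo, hi) with sd(e) = s0 + s1*(e - lo)
    m2 = (freq_sd_base ** 2 + freq_sd_base * freq_sd_slope * span
          + freq_sd_slope ** 2 * span ** 2 / 3.0)
    if r == 0.0:
        slope = 0.0
    else:
        slope = np.sign(r) * np.sqrt(r ** 2 * m2 / ((1 - r ** 2) * var_e))

    rng = _rng(seed, _STREAM_COHORT)
    end_times = rng.uniform(lo, hi, n_runs)
    eps = rng.standard_normal(n_runs)
    sd_e = freq_sd_base + freq_sd_slope * (end_times - lo)
    freqs = freq_center + slope * (end_times - (lo + hi) / 2) + sd_e * eps
    freqs = np.clip(freqs, 1.0, min(2.9, frame_rate / 2 - 0.5))
    lr_jitter = rng.normal(0.0, 0.02, n_runs)
    hand_freqs = np.clip(rng.normal(hand_freq, hand_freq_sd, n_runs), 0.8, 2.9)
    reaction = np.clip(rng.normal(0.13, 0.03, n_runs), 0.05, 0.27)
    jump = np.clip(rng.normal(0.45, 0.04, n_runs), 0.30, 0.60)

    configs, seeds, rows = [], [], []
    base_profile = np.asarray(DEFAULT_SPLIT_PROFILE)
    hold_map = example_hold_map()
    for i in range(n_runs):
        run_seed_rng = _rng(seed, _STREAM_COHORT, (i,))
        f_l = float(freqs[i] - lr_jitter[i] / 2)
        f_r = float(freqs[i] + lr_jitter[i] / 2)
        # scale the split profile so the climb exactly fills the planned
        # window t20 - t0 implied by the drawn end time
        dh = np.diff(np.concatenate(([1.0], hold_map.heights)))
        dtn_sections = np.array([base_profile[_section_of_hold(j)]
                                 for j in range(1, 21)])
        sds = np.array([np.asarray(split_noise_sd)[_section_of_hold(j)]
                        for j in range(1, 21)])
        dtn = np.clip(dtn_sections + run_seed_rng.normal(0, 1, 20) * sds,
                      0.05, None)
        t_climb = float(end_times[i]) - jump[i] - reaction[i]
        dtn = dtn * (t_climb / float(np.sum(dtn * dh)))
        cfg = SyntheticRunConfig(
            frame_rate=frame_rate, hold_map=hold_map,
            split_profile=tuple(dtn), split_noise_sd=(0.0, 0.0, 0.0),
            reaction_time=float(reaction[i]), jump_time=float(jump[i]),
            limb_params={
                "left_foot": LimbParams(f=f_l, phi=0.0, noise_sd=limb_noise_sd),
                "right_foot": LimbParams(f=f_r, phi=np.pi, noise_sd=limb_noise_sd),
                "left_hand": LimbParams(A=1.0, f=float(hand_freqs[i]), phi=0.0,
                                        C=1.6, noise_sd=limb_noise_sd),
                "right_hand": LimbParams(A=1.0, f=float(hand_freqs[i]), phi=np.pi,
                                         C=1.6, noise_sd=limb_noise_sd),
            },
            occlusion_rate=occlusion_rate,
            run_id=f"run-{i:03d}", athlete_id=f"athlete-{i % n_athletes:02d}",
        )
        configs.append(cfg)
        seeds.append(int(np.random.SeedSequence([seed, _STREAM_COHORT, i])
                         .generate_state(1)[0] % (2 ** 31)))
        rows.append({
            "run_id": cfg.run_id, "athlete_id": cfg.athlete_id,
            "end_time": float(end_times[i]), "foot_freq": float(freqs[i]),
            "foot_freq_left": f_l, "foot_freq_right": f_r,
            "hand_freq": float(hand_freqs[i]),
            "reaction_time": float(reaction[i]), "jump_time": float(jump[i]),
        })
    return SyntheticCohort(configs=configs, seeds=seeds,
                           table=pd.DataFrame(rows),
                           planted_correlation=r)
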