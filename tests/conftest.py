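import numpy as np
import pytest

from speedclimb.cohort import AnalysisConfig, analyze_run, run_pipeline
from speedclimb.synthetic import (
    SyntheticRunConfig,
    assemble_run,
    generate_cog_trajectory,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_run():
    """One assembled noiseless run with ground truth (seed 42)."""
    cfg = SyntheticRunConfig()
    tracks, meta, truth = assemble_run(cfg, 42)
    return cfg, tracks, meta, truth


@pytest.fixture(scope="session")
def default_trace():
    """Noiseless COG trace + ground truth for the default configuration."""
    cfg = SyntheticRunConfig()
    trace, truth = generate_cog_trajectory(cfg, 42)
    return cfg, trace, truth


@pytest.fixture(scope="session")
def small_cohort_results():
    """Planted cohort of 30 runs pushed through the full pipeline."""
    cohort = generate_cohort(n_runs=30, planted_correlation=-0.7, seed=5)
    results = run_pipeline(
        ((tracks, meta) for tracks, meta, _ in cohort.assemble()),
        hold_map=cohort.configs[0].hold_map,
    )
    return cohort, results


def tone(f=1.7, rate=30.0, duration=10.0, amp=1.0, phi=0.0, offset=0.0):
    t = np.arange(0.0, duration, 1.0 / rate)
    return t, amp * np.sin(2 * np.pi * f * t + phi) + offset
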