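"""Cohort filtering, correlation reporting, pipeline and CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from speedclimb.cli import main as cli_main
from speedclimb.cohort import (
    analyze_cohort,
    correlation_matrix,
    filter_cohort,
    frequency_by_endtime,
    pearson_with_p,
    run_pipeline,
)
from speedclimb.exceptions import (
    EmptyInputError,
    SampleSizeError,
    UndefinedCorrelationError,
)
from speedclimb.io import read_manifest, write_cohort
from speedclimb.synthetic import assemble_run, generate_cohort


def toy_table():
    return pd.DataFrame({
        "run_id": [f"r{i}" for i in range(5)],
        "sex": ["male", "male", "female", "male", "male"],
        "technique": ["Tomoa Skip", "Tomoa Skip", "Tomoa Skip",
                      "Reza Move", "Tomoa Skip"],
        "end_time": [5.2, 6.5, 5.1, 5.4, 5.9],
    })


class TestFilterCohort:
    def test_toy_predicates(self):
        out = filter_cohort(toy_table())
        assert list(out["run_id"]) == ["r0", "r4"]

    def test_wildcards_are_identity(self):
        t = toy_table()
        out = filter_cohort(t, sex=None, technique=None, max_end_time=np.inf)
        pd.testing.assert_frame_equal(out, t)

    def test_strict_end_time_comparison(self):
        t = toy_table()
        out = filter_cohort(t, sex=None, technique=None, max_end_time=5.9)
        assert "r4" not in set(out["run_id"])

    def test_count_matches_manual_scan(self):
        t = toy_table()
        out = filter_cohort(t, sex="male", technique="Tomoa Skip",
                            max_end_time=6.0)
        manual = sum(1 for _, r in t.iterrows()
                     if r["sex"] == "male" and r["technique"] == "Tomoa Skip"
                     and r["end_time"] < 6.0)
        assert len(out) == manual

    def test_predicate_order_commutes(self):
        t = toy_table()
        a = filter_cohort(filter_cohort(t, sex="male", technique=None,
                                        max_end_time=None),
                          sex=None, technique="Tomoa Skip", max_end_time=6.0)
        b = filter_cohort(filter_cohort(t, sex=None, technique="Tomoa Skip",
                                        max_end_time=6.0),
                          sex="male", technique=None, max_end_time=None)
        pd.testing.assert_frame_equal(a.sort_values("run_id").reset_index(drop=True),
                                      b.sort_values("run_id").reset_index(drop=True))

    def test_empty_table_rejected(self):
        with pytest.raises(EmptyInputError):
            filter_cohort(pd.DataFrame())


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-8

    def test_orthogonal_contrast(self):
        r, _ = pearson_with_p([1, 2, 3, 4], [1, -1, -1, 1])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_constant_input(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_with_p([1, 1, 1, 1], [1, 2, 3, 4])

    def test_small_sample(self):
        with pytest.raises(SampleSizeError):
            pearson_with_p([1, 2], [3, 4])

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = 0.4 * x + rng.normal(size=40)
        r, _ = pearson_with_p(x, y)
        manual = (np.mean(x * y) - x.mean() * y.mean()) / (
            x.std() * y.std())
        assert r == pytest.approx(manual, abs=1e-12)


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame({"end_time": rng.uniform(4.7, 6, 20)})
        t["left_foot_r2"] = t["end_time"]
        out = correlation_matrix(t, features=["left_foot_r2"])
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_feet_strong_hands_null(self, small_cohort_results):
        cohort, results = small_cohort_results
        corr = results["correlations"].set_index("feature")
        feet = abs(corr.loc["left_foot_dominant_freq", "r"])
        hands = abs(corr.loc["left_hand_dominant_freq", "r"])
        assert feet > hands
        assert corr.loc["left_foot_dominant_freq", "r"] < 0

    def test_missing_feature_skipped(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame({"end_time": rng.uniform(4.7, 6, 15),
                          "left_foot_r2": rng.uniform(0, 1, 15),
                          "right_foot_r2": np.nan})
        out = correlation_matrix(t, features=["left_foot_r2", "right_foot_r2"])
        assert list(out["feature"]) == ["left_foot_r2"]


class TestFrequencyByEndtime:
    def table(self):
        rng = np.random.default_rng(4)
        e = rng.uniform(4.7, 6.0, 40)
        return pd.DataFrame({
            "end_time": e,
            "left_foot_dominant_freq": rng.normal(1.8, 0.1, 40),
            "right_foot_dominant_freq": rng.normal(1.8, 0.1, 40),
        })

    def test_single_bin_reproduces_global_stats(self):
        t = self.table()
        out = frequency_by_endtime(t, [4.7, 5.4, 6.0])
        merged = frequency_by_endtime(t, [4.7, 6.0 - 1e-12, 6.0])
        left = merged[merged["foot"] == "left_foot"].iloc[0]
        x = t["left_foot_dominant_freq"]
        assert left["mean"] == pytest.approx(x.mean())
        assert left["sd"] == pytest.approx(x.std(ddof=1))

    def test_planted_heteroscedasticity_monotone_sd(self):
        cohort = generate_cohort(n_runs=300, planted_correlation=0.0, seed=6)
        t = cohort.table.rename(columns={"foot_freq_left":
                                         "left_foot_dominant_freq",
                                         "foot_freq_right":
                                         "right_foot_dominant_freq"})
        out = frequency_by_endtime(t, [4.7, 5.13, 5.57, 6.0])
        sds = out[out["foot"] == "left_foot"]["sd"].to_numpy()
        assert np.all(np.diff(sds) >= 0)

    def test_two_runs_per_bin_quartiles(self):
        t = pd.DataFrame({
            "end_time": [5.0, 5.1, 5.6, 5.7],
            "left_foot_dominant_freq": [1.6, 2.0, 1.7, 1.9],
            "right_foot_dominant_freq": [1.6, 2.0, 1.7, 1.9],
        })
        out = frequency_by_endtime(t, [4.9, 5.4, 5.9])
        row = out[(out["foot"] == "left_foot")].iloc[0]
        assert row["q1"] == pytest.approx(1.7)   # type-7 interpolation
        assert row["median"] == pytest.approx(1.8)
        assert row["q3"] == pytest.approx(1.9)


class TestPipeline:
    def test_corrupted_runs_excluded_exactly(self):
        cohort = generate_cohort(n_runs=12, seed=8)
        runs = []
        corrupted = {"run-002", "run-005", "run-009"}
        for tracks, meta, _ in cohort.assemble():
            if meta.run_id in corrupted:
                meta.tgt = meta.tgt * 1.2  # forces the 5 % filter to fail
            runs.append((tracks, meta))
        results = analyze_cohort(runs, cohort.configs[0].hold_map)
        validity = results["validity"].set_index("run_id")
        assert set(validity[~validity["valid"]].index) == corrupted
        assert set(results["cohort"]["run_id"]) == \
            {f"run-{i:03d}" for i in range(12)} - corrupted

    def test_byte_identical_reruns(self, tmp_path):
        cohort = generate_cohort(n_runs=10, seed=4)
        outs = []
        for name in ("a", "b"):
            run_pipeline(((t, m) for t, m, _ in cohort.assemble()),
                         hold_map=cohort.configs[0].hold_map,
                         out_dir=tmp_path / name)
            outs.append({p.name: p.read_bytes()
                         for p in sorted((tmp_path / name).glob("*.csv"))})
        assert outs[0] == outs[1]

    def test_roundtrip_through_disk(self, tmp_path):
        cohort = generate_cohort(n_runs=10, seed=2)
        manifest = write_cohort(cohort, tmp_path)
        results = run_pipeline(manifest)
        assert len(results["validity"]) == 10
        assert results["validity"]["valid"].all()
        # in-memory and on-disk routes agree
        direct = analyze_cohort(((t, m) for t, m, _ in cohort.assemble()),
                                cohort.configs[0].hold_map)
        pd.testing.assert_frame_equal(
            results["cohort"].reset_index(drop=True),
            direct["cohort"].reset_index(drop=True),
            check_exact=False, atol=1e-9,
        )


class TestCli:
    def test_generate_analyze_report_determinism(self, tmp_path):
        runner = CliRunner()
        gen = runner.invoke(cli_main, [
            "generate", "--n-runs", "10", "--seed", "3",
            "--out-dir", str(tmp_path / "cohort")])
        assert gen.exit_code == 0, gen.output
        manifest = tmp_path / "cohort" / "manifest.csv"
        outs = []
        for name in ("r1", "r2"):
            res = runner.invoke(cli_main, [
                "analyze-cohort", "--manifest", str(manifest),
                "--out-dir", str(tmp_path / name), "--seed", "1"])
            assert res.exit_code == 0, res.output
            outs.append({p.name: p.read_bytes()
                         for p in sorted((tmp_path / name).glob("*.csv"))})
        assert outs[0] == outs[1]
        assert "cohort.csv" in outs[0]

    def test_analyze_single_run(self, tmp_path):
        from speedclimb.io import (write_hold_map, write_keypoints_csv,
                                   write_metadata)
        from speedclimb.synthetic import SyntheticRunConfig
        cfg = SyntheticRunConfig()
        tracks, meta, _ = assemble_run(cfg, 42)
        write_keypoints_csv(tracks, tmp_path / "kp.csv")
        write_metadata(meta, tmp_path / "meta.yaml")
        write_hold_map(cfg.hold_map, tmp_path / "holds.yaml")
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "analyze-run", "--keypoints", str(tmp_path / "kp.csv"),
            "--meta", str(tmp_path / "meta.yaml"),
            "--holds", str(tmp_path / "holds.yaml"),
            "--out-dir", str(tmp_path / "out")])
        assert res.exit_code == 0, res.output
        metrics = pd.read_csv(tmp_path / "out" / "run_metrics.csv")
        assert bool(metrics.iloc[0]["valid"])
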