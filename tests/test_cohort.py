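"""Cohort orchestration: classification summaries, filter comparison,
volume redundancy, report round-trips and the end-to-end pipeline."""

import numpy as np
import pandas as pd
import pytest

from petrep import (PhantomConfig, PipelineConfig, RepeatabilityRecord,
                    ValidationError, classification_summary, compare_filters,
                    generate_cohort, run_pipeline, volume_redundancy)
from petrep.cohort import (frame_to_records, read_repeatability_report,
                           records_to_frame, repeatability_records)

import oracles


def _rec(name, cls, icc=0.9):
    return RepeatabilityRecord(feature_name=name, n=10, wcv_pct=1.0, rc_pct=2.77,
                               b_pct=0.0, loa_low_pct=-2.77, loa_high_pct=2.77,
                               icc=icc, icc_ci_low=icc - 0.05, icc_ci_high=icc + 0.05,
                               reliability_class=cls)


class TestClassificationSummary:
    def test_all_excellent(self):
        recs = {f"f{i}": _rec(f"f{i}", "excellent") for i in range(5)}
        s = classification_summary(recs)
        assert s["percent"]["excellent"] == 100.0

    def test_good_or_excellent_percentage_arithmetic(self):
        recs = {}
        for i in range(50):
            recs[f"e{i}"] = _rec(f"e{i}", "excellent")
        for i in range(24):
            recs[f"g{i}"] = _rec(f"g{i}", "good")
        for i in range(33):
            recs[f"p{i}"] = _rec(f"p{i}", "poor")
        s = classification_summary(recs)
        assert s["n_features"] == 107
        assert s["good_or_excellent_percent"] == pytest.approx(100 * 74 / 107, rel=1e-12)

    def test_family_counts_sum_to_total(self):
        recs = {"original_glcm_Contrast": _rec("original_glcm_Contrast", "good"),
                "original_shape_MeshVolume": _rec("original_shape_MeshVolume", "excellent"),
                "suv_mean": _rec("suv_mean", "excellent")}
        s = classification_summary(recs)
        total = sum(sum(v.values()) for v in s["by_family"].values())
        assert total == s["n_features"] == 3

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            classification_summary({})


class TestCompareFilters:
    def test_identical_iccs_not_significant(self):
        t = pd.DataFrame({"original": np.linspace(0.5, 0.9, 20),
                          "square": np.linspace(0.5, 0.9, 20)})
        res = compare_filters(t)
        row = res.iloc[0]
        assert row.p_value == 1.0 and row.all_ties and not row.significant

    def test_bonferroni_arithmetic(self):
        # p = 0.004 with m = 16 -> adjusted 0.064, not significant
        assert min(1.0, 16 * 0.004) == pytest.approx(0.064)
        rng = np.random.default_rng(8)
        orig = rng.uniform(0.4, 0.9, 30)
        cols = {"original": orig}
        for i in range(16):
            cols[f"f{i}"] = orig + rng.normal(0, 0.02, 30)
        res = compare_filters(pd.DataFrame(cols))
        assert np.all(res.p_adjusted >= res.p_value)
        assert np.all((res.p_adjusted <= 1.0) & (res.p_adjusted >= 0.0))

    def test_uniform_shift_gives_minimal_statistic(self):
        orig = np.linspace(0.3, 0.8, 93)
        t = pd.DataFrame({"original": orig, "shift": orig + 0.2})
        res = compare_filters(t)
        row = res.iloc[0]
        assert row.statistic == 0.0  # all differences share one sign
        assert row.p_value < 1e-10


class TestVolumeRedundancy:
    def test_volume_itself_scores_one(self, rng):
        vol = rng.uniform(1, 30, 20)
        table = pd.DataFrame({"f_vol": vol, "f_dec": -3 * vol + 1})
        res = volume_redundancy(table, vol).set_index("feature")
        assert res.loc["f_vol", "abs_spearman_r"] == pytest.approx(1.0)
        assert res.loc["f_dec", "abs_spearman_r"] == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        vol = rng.uniform(1, 30, 20)
        feat = rng.normal(size=20) + 0.1 * vol
        res = volume_redundancy(pd.DataFrame({"f": feat}), vol)
        assert res.abs_spearman_r[0] == pytest.approx(
            abs(oracles.spearman_oracle(feat, vol)), abs=1e-12)

    def test_constant_feature_flagged(self, rng):
        res = volume_redundancy(pd.DataFrame({"c": np.ones(5)}), rng.uniform(1, 9, 5))
        assert res.flag[0] == "constant" and np.isnan(res.abs_spearman_r[0])

    def test_too_few_lesions(self):
        with pytest.raises(ValidationError):
            volume_redundancy(pd.DataFrame({"f": [1.0, 2.0]}), np.array([1.0, 2.0]))


@pytest.fixture(scope="module")
def noisy_cohort(tmp_path_factory):
    cfg = PhantomConfig(grid_shape=(64, 64, 48), n_lesions=2,
                        lesion_radius_range_mm=(8.0, 11.0), seed=99)
    return generate_cohort(3, "intratracer_A", cfg,
                           out_dir=tmp_path_factory.mktemp("coh") / "data")


class TestPipeline:
    def test_conventional_only_run(self, noisy_cohort, tmp_path):
        res = run_pipeline(noisy_cohort, PipelineConfig(radiomics=False),
                           out_dir=tmp_path / "out")
        assert res.group_label == "intratracer_A"
        assert set(res.records) == {"suv_max", "suv_mean", "suv_total", "volume_ml"}
        assert (tmp_path / "out" / "repeatability.csv").exists()
        assert (tmp_path / "out" / "classification.json").exists()

    def test_report_round_trip_exact(self, noisy_cohort, tmp_path):
        res = run_pipeline(noisy_cohort, PipelineConfig(radiomics=False),
                           out_dir=tmp_path / "rt")
        back = read_repeatability_report(tmp_path / "rt" / "repeatability.csv")
        assert set(back) == set(res.records)
        for k in res.records:
            a, b = res.records[k], back[k]
            assert a.wcv_pct == pytest.approx(b.wcv_pct, rel=1e-12, nan_ok=True)
            assert a.icc == pytest.approx(b.icc, rel=1e-12, nan_ok=True)
            assert a.reliability_class == b.reliability_class

    def test_deterministic_reports(self, noisy_cohort, tmp_path):
        run_pipeline(noisy_cohort, PipelineConfig(radiomics=False), out_dir=tmp_path / "a")
        run_pipeline(noisy_cohort, PipelineConfig(radiomics=False), out_dir=tmp_path / "b")
        for f in ("repeatability.csv", "classification.json"):
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()

    def test_radiomics_run_emits_volume_correlation(self, noisy_cohort, tmp_path):
        res = run_pipeline(noisy_cohort, PipelineConfig(radiomics=True, filters="none"),
                           out_dir=tmp_path / "rad")
        assert res.volume_correlation is not None
        assert (tmp_path / "rad" / "volume_correlation.csv").exists()
        # 107 radiomics + 4 conventional records
        assert len(res.records) == 111

    def test_unpaired_rows_dropped(self, noisy_cohort):
        from petrep.cohort import extract_cohort_features
        table, _ = extract_cohort_features(noisy_cohort, PipelineConfig(radiomics=False))
        broken = table[~((table.subject_id == "sub-001")
                         & (table.lesion_id == "les001")
                         & (table.scan == "retest"))]
        records = repeatability_records(broken)
        assert records["suv_mean"].n == len(broken[broken.scan == "test"]) - 1


class TestCli:
    def test_simulate_extract_repeatability_report(self, tmp_path):
        from click.testing import CliRunner
        from petrep.cli import main
        runner = CliRunner()
        data = tmp_path / "data"
        r = runner.invoke(main, ["simulate", "--out", str(data), "--subjects", "2",
                                 "--seed", "21"])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["extract", "--data", str(data),
                                 "--out", str(tmp_path / "features.csv")])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["repeatability", "--features",
                                 str(tmp_path / "features.csv"),
                                 "--out", str(tmp_path / "rep.csv"),
                                 "--group", "intratracer_A"])
        assert r.exit_code == 0, r.output
        rep = pd.read_csv(tmp_path / "rep.csv")
        assert {"suv_max", "suv_mean", "suv_total", "volume_ml"} <= set(rep.feature)
        r = runner.invoke(main, ["report", "--data", str(data),
                                 "--out", str(tmp_path / "rep"), "--no-radiomics"])
        assert r.exit_code == 0, r.output
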