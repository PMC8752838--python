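"""End-to-end behaviour of BurdenModel / BurdenResults on small inputs."""

import pytest

from pafburden import (
    BurdenModel,
    ConfigurationError,
    DataGapError,
    DirectPafEntry,
    ExposureDistribution,
    IncidenceRecord,
    RelativeRiskEntry,
    RiskFactorSpec,
    RunConfig,
    run_pipeline,
)
from pafburden import tables as tbl

from conftest import write


def harmful(factor, cancers, **kw):
    return RiskFactorSpec(factor, factor, "rr_based", frozenset(cancers),
                          framing="harmful", **kw)


def tiny_config(paths):
    return RunConfig(
        incidence_year=2018, tables=paths,
        factors={"smoking": {"framing": "harmful",
                             "cancers": ["lung", "pancreas"]}})


class TestFit:
    def test_single_factor_single_cancer(self):
        spec = harmful("smoking", ["lung"])
        dist = ExposureDistribution.from_nonreference(
            "smoking", "male", [("current", 0.25)])
        rrs = [RelativeRiskEntry("smoking", "lung", "male", "current", 9.0)]
        incidence = [IncidenceRecord("lung", "male", 2018, 1000)]
        res = BurdenModel([spec], [dist], rrs, incidence).fit()
        # p(RR-1)/(1+p(RR-1)) = 2/3
        (row,) = res.attribution.rows
        assert row.paf == pytest.approx(2.0 / 3.0, abs=1e-12)
        (crow,) = res.attribution.combined
        assert crow.paf == row.paf  # one factor: combined equals single row
        assert res.attribution.total_attributable == pytest.approx(2000 / 3)
        assert res.attribution.total_cases == 1000

    def test_combined_rows_obey_multiplicative_identity(self):
        specs = [harmful(f, ["lung"]) for f in ("a", "b", "c")]
        dists = [ExposureDistribution.from_nonreference(
            f, "male", [("exposed", p)])
            for f, p in (("a", 0.2), ("b", 0.3), ("c", 0.1))]
        rrs = [RelativeRiskEntry(f, "lung", "male", "exposed", rr)
               for f, rr in (("a", 2.0), ("b", 1.5), ("c", 4.0))]
        incidence = [IncidenceRecord("lung", "male", 2018, 5000)]
        res = BurdenModel(specs, dists, rrs, incidence).fit()
        singles = [r.paf for r in res.attribution.rows]
        expected = 1.0
        for p in singles:
            expected *= 1.0 - p
        (crow,) = res.attribution.combined
        assert crow.paf == pytest.approx(1.0 - expected, abs=1e-12)
        assert crow.paf >= max(singles)

    def test_direct_paf_factor_passes_published_value_through(self):
        uv = RiskFactorSpec("uv", "UV", "direct_paf", frozenset({"melanoma"}))
        direct = [DirectPafEntry("uv", "melanoma", "male", 0.932)]
        incidence = [IncidenceRecord("melanoma", "male", 2018, 1500)]
        res = BurdenModel([uv], [], [], incidence, direct_pafs=direct).fit()
        (row,) = res.attribution.rows
        assert row.paf == 0.932
        assert row.attributable_cases == pytest.approx(0.932 * 1500)

    def test_missing_direct_paf_is_a_data_gap(self):
        uv = RiskFactorSpec("uv", "UV", "direct_paf", frozenset({"melanoma"}))
        incidence = [IncidenceRecord("melanoma", "male", 2018, 1500)]
        with pytest.raises(DataGapError, match="uv"):
            BurdenModel([uv], [], [], incidence).fit()

    def test_latency_mismatch_aborts_naming_factor(self):
        spec = harmful("smoking", ["lung"], exposure_year=2008,
                       latency_years=20)
        incidence = [IncidenceRecord("lung", "male", 2018, 1000)]
        with pytest.raises(ConfigurationError, match="smoking"):
            BurdenModel([spec], [], [], incidence).fit()

    def test_twenty_year_latency_scenario_uses_older_vintage(self):
        spec = harmful("smoking", ["lung"], exposure_year=1998,
                       latency_years=20)
        dist = ExposureDistribution.from_nonreference(
            "smoking", "male", [("current", 0.35)])
        rrs = [RelativeRiskEntry("smoking", "lung", "male", "current", 9.0)]
        incidence = [IncidenceRecord("lung", "male", 2018, 1000)]
        res = BurdenModel([spec], [dist], rrs, incidence).fit()
        assert res.attribution.rows[0].paf == pytest.approx(
            0.35 * 8 / (1 + 0.35 * 8), abs=1e-12)

    def test_sex_additivity_of_overall_attributable(self, tiny_tables):
        res = BurdenModel.from_config(tiny_config(tiny_tables)).fit()
        by_sex = {"male": 0.0, "female": 0.0}
        for r in res.attribution.combined:
            by_sex[r.sex] += r.attributable_cases
        assert res.attribution.total_attributable == pytest.approx(
            by_sex["male"] + by_sex["female"])

    def test_forced_null_cells_logged_and_zero(self, tiny_tables):
        res = BurdenModel.from_config(tiny_config(tiny_tables)).fit()
        pancreas = [r for r in res.attribution.rows
                    if r.cancer_type_id == "pancreas"]
        assert pancreas and all(r.paf == 0.0 for r in pancreas)
        assert any("forced RR=1" in line for line in res.log)

    def test_subtype_attribution_rolls_up_into_parent(self):
        spec = harmful("smoking", ["lung_adeno"])
        dist = ExposureDistribution.from_nonreference(
            "smoking", "male", [("current", 0.5)])
        rrs = [RelativeRiskEntry("smoking", "lung_adeno", "male", "current",
                                 3.0)]
        incidence = [
            IncidenceRecord("lung", "male", 2018, 1000),
            IncidenceRecord("lung_adeno", "male", 2018, 400,
                            subtype_of="lung"),
        ]
        res = BurdenModel([spec], [dist], rrs, incidence).fit()
        # totals count each case once: the parent's 1000, not 1400
        assert res.attribution.total_cases == 1000
        summary = res.cancer_summary()
        parent = summary[(summary.cancer_type_id == "lung")
                         & (summary.sex == "male")].iloc[0]
        assert parent.attributable_cases == pytest.approx(0.5 * 400)

    def test_summary_text_reports_overall_paf(self, tiny_tables):
        res = BurdenModel.from_config(tiny_config(tiny_tables)).fit()
        text = res.summary()
        assert "Overall PAF" in text and "smoking" in text


class TestRunPipeline:
    def test_outputs_are_byte_identical_across_runs(self, tiny_tables,
                                                    tmp_path):
        cfg = tiny_config(tiny_tables)
        out1, out2 = tmp_path / "run1", tmp_path / "run2"
        run_pipeline(cfg, out1)
        run_pipeline(cfg, out2)
        for name in ("attribution.csv", "factor_summary.csv",
                     "cancer_summary.csv", "run.log"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_written_attribution_reads_back_identically(self, tiny_tables,
                                                        tmp_path):
        res = run_pipeline(tiny_config(tiny_tables), tmp_path / "out")
        back = tbl.read_attribution_table(tmp_path / "out" / "attribution.csv")
        assert back.rows == res.attribution.rows
        assert back.combined == res.attribution.combined

    def test_yaml_config_run(self, tiny_tables, tmp_path):
        cfg_path = write(tmp_path / "run.yaml", f"""
            incidence_year: 2018
            tables:
              exposure: {tiny_tables['exposure']}
              rr: {tiny_tables['rr']}
              incidence: {tiny_tables['incidence']}
            factors:
              smoking:
                framing: harmful
                cancers: [lung, pancreas]
        """)
        res = run_pipeline(cfg_path, tmp_path / "out")
        assert res.attribution.total_cases == 5680
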