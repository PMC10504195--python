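import dataclasses

import numpy as np
import pandas as pd
import pytest

from bpref.cohort import MIN_AGE_MONTHS, apply_exclusions, cohort_summary
from bpref.simulate import SimulationConfig, fig1_like_config, generate_cohort


def _record(**kw):
    base = dict(
        child_id="C0", sex="boy", age_months=25, height_cm=84.0, weight_kg=11.5,
        season="spring", chronic_disease=False, posture="sitting",
        condition_flag="stable",
        sbp1=100.0, sbp2=92.0, sbp3=94.0, dbp1=60.0, dbp2=55.0, dbp3=58.0,
    )
    base.update(kw)
    return base


class TestBucketOrder:
    def test_chronic_precedes_everything(self, standard):
        df = pd.DataFrame([_record(chronic_disease=True, sbp2=np.nan, sbp3=np.nan)])
        sbp, dbp, flow = apply_exclusions(df, standard)
        assert flow.counts["sbp"]["excluded_chronic"] == 1
        assert flow.counts["dbp"]["excluded_chronic"] == 1
        assert len(sbp) == 0 and len(dbp) == 0

    def test_underage(self, standard):
        assert MIN_AGE_MONTHS == 24
        df = pd.DataFrame([_record(age_months=23)])
        sbp, dbp, flow = apply_exclusions(df, standard)
        assert flow.counts["sbp"]["excluded_underage"] == 1
        assert len(sbp) == 0

    def test_missing_covariate(self, standard):
        df = pd.DataFrame([_record(season=None)])
        _, _, flow = apply_exclusions(df, standard)
        assert flow.counts["sbp"]["excluded_covariates_or_height_outlier"] == 1
        assert flow.sub_reasons["sbp"]["missing_season"] == 1

    def test_height_outlier(self, standard):
        df = pd.DataFrame([_record(height_cm=84.0 * 1.3)])  # ~ +8.8 SD
        _, _, flow = apply_exclusions(df, standard)
        assert flow.counts["sbp"]["excluded_covariates_or_height_outlier"] == 1
        assert flow.sub_reasons["sbp"]["height_outlier"] == 1

    def test_channel_asymmetry_dbp_zero(self, standard):
        df = pd.DataFrame([_record(dbp2=0.0)])
        sbp, dbp, flow = apply_exclusions(df, standard)
        assert len(sbp) == 1 and len(dbp) == 0
        assert flow.counts["dbp"]["excluded_missing_or_condition"] == 1
        assert flow.sub_reasons["dbp"]["dbp_zero"] == 1

    def test_condition_flag_grouped_box(self, standard):
        df = pd.DataFrame([_record(condition_flag="sleeping")])
        _, _, flow = apply_exclusions(df, standard)
        assert flow.counts["sbp"]["excluded_missing_or_condition"] == 1
        assert flow.sub_reasons["sbp"]["condition_sleeping"] == 1

    def test_unstable_bp(self, standard):
        df = pd.DataFrame([_record(sbp1=100.0, sbp2=92.0, sbp3=86.0)])
        _, _, flow = apply_exclusions(df, standard)
        assert flow.counts["sbp"]["excluded_unstable_bp"] == 1
        assert flow.counts["dbp"]["analyzed"] == 1

    def test_analyzed_carries_zht_and_bp(self, standard):
        df = pd.DataFrame([_record()])
        sbp, dbp, _ = apply_exclusions(df, standard)
        assert sbp["bp"].iloc[0] == 93.0
        assert dbp["bp"].iloc[0] == 56.5
        assert np.isfinite(sbp["zht"].iloc[0])


class TestFlowConservation:
    def test_planted_counts_match_exactly(self, standard):
        cfg = dataclasses.replace(
            fig1_like_config(n_children=3000, seed=7), within_child_noise_sd=0.0
        )
        df, truth = generate_cohort(cfg, standard, return_truth=True)
        _, _, flow = apply_exclusions(df, standard)
        counts = truth["planted_category"].value_counts().to_dict()
        g = counts.get
        assert flow.check_conservation()
        for ch in ("sbp", "dbp"):
            c = flow.counts[ch]
            assert c["excluded_chronic"] == g("chronic", 0)
            assert c["excluded_unstable_bp"] == g("unstable", 0)
            assert c["excluded_underage"] == g("underage", 0)
            assert c["excluded_covariates_or_height_outlier"] == g("height_outlier", 0)
        assert flow.counts["sbp"]["excluded_missing_or_condition"] == (
            g("missing_two", 0) + g("crying", 0)
        )
        assert flow.counts["dbp"]["excluded_missing_or_condition"] == (
            g("missing_two", 0) + g("crying", 0) + g("dbp_zero", 0)
        )
        assert flow.counts["sbp"]["analyzed"] == (
            g("none", 0) + g("missing_second", 0) + g("dbp_zero", 0)
        )
        assert flow.counts["dbp"]["analyzed"] == g("none", 0) + g("missing_second", 0)

    def test_conservation_with_noise(self, standard):
        cfg = fig1_like_config(n_children=1500, seed=3)
        df = generate_cohort(cfg, standard)
        _, _, flow = apply_exclusions(df, standard)
        assert flow.check_conservation()
        for ch in ("sbp", "dbp"):
            assert sum(flow.counts[ch].values()) == 1500

    def test_flow_report_round_trip(self, standard):
        df = pd.DataFrame([_record(), _record(child_id="C1", age_months=23)])
        _, _, flow = apply_exclusions(df, standard)
        d = flow.to_dict()
        assert d["total_in"] == 2
        assert "sbp" in d["channels"] and "dbp" in d["channels"]
        text = flow.to_text()
        assert "records in: 2" in text
        assert "excluded_underage: 1" in text


class TestSummary:
    def test_two_record_arithmetic(self, standard):
        df = pd.DataFrame(
            [
                _record(child_id="A", sbp1=90, sbp2=90, sbp3=90, dbp1=55, dbp2=55, dbp3=55),
                _record(child_id="B", sbp1=92, sbp2=92, sbp3=92, dbp1=55, dbp2=55, dbp3=55),
            ]
        )
        sbp, dbp, _ = apply_exclusions(df, standard)
        s = cohort_summary(sbp, dbp)
        row = s.iloc[0]
        assert row["sbp_mean"] == pytest.approx(91.0)
        assert row["sbp_sd"] == pytest.approx(1.414, abs=1e-3)
        assert row["n"] == 2

    def test_all_boys(self, standard):
        df = pd.DataFrame([_record(child_id=f"C{i}") for i in range(3)])
        sbp, dbp, _ = apply_exclusions(df, standard)
        assert cohort_summary(sbp, dbp).iloc[0]["pct_male"] == 100.0

    def test_empty_marker(self, standard):
        df = pd.DataFrame([_record(age_months=20)])
        sbp, dbp, _ = apply_exclusions(df, standard)
        s = cohort_summary(sbp, dbp)
        assert s.iloc[0]["n"] == 0

    def test_mean_bp_matches_quadrature_oracle(self, standard):
        """Analyzed-set mean SBP vs the truth surface's population mean."""
        cfg = SimulationConfig(n_children=10_000, seed=11)
        df = generate_cohort(cfg, standard)
        sbp, dbp, _ = apply_exclusions(df, standard)
        s = cohort_summary(sbp, dbp).iloc[0]
        # quadrature over zht ~ N(0,1) and u ~ N(0,1), mixing the two sexes
        truth = cfg.resolve_truth()
        zg, zw = np.polynomial.hermite_e.hermegauss(40)
        ug, uw = np.polynomial.hermite_e.hermegauss(40)
        zw, uw = zw / np.sqrt(2 * np.pi), uw / np.sqrt(2 * np.pi)
        mean = 0.0
        for sex, w_sex in (("boy", 0.497), ("girl", 0.503)):
            ts = truth[(sex, "sbp")]
            vals = ts.sample(np.repeat(zg, len(ug)), np.tile(ug, len(zg)))
            wts = np.repeat(zw, len(ug)) * np.tile(uw, len(zg))
            mean += w_sex * float(np.sum(vals * wts))
        assert s["sbp_mean"] == pytest.approx(mean, abs=0.5)
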