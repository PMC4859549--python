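"""Bland-Altman agreement: pairing, ratios, conventional and
repeated-measures limits of agreement, confidence intervals."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pzqma import agreement
from pzqma.agreement import (
    AgreementResult,
    concentration_agreement_table,
    loa_confidence_intervals,
    loa_conventional,
    loa_repeated,
    pair_measurements,
    parameter_ratio_table,
    pearson_pooled,
    percentage_ratios,
)
from pzqma import nca

from oracles import anova_variance_components


class TestPairing:
    def test_full_noiseless_cohort_pair_count(self, noiseless_cohort):
        conc, _ = noiseless_cohort
        for analyte in conc.analyte.unique():
            pairs = pair_measurements(conc[conc.analyte == analyte], "blood")
            assert len(pairs) == 99  # 9 subjects x 11 common times

    def test_dbs_yields_fewer_pairs_than_blood(self, noiseless_cohort):
        conc, _ = noiseless_cohort
        sub = conc[conc.analyte == "S-PZQ"]
        assert len(pair_measurements(sub, "DBS")) < len(
            pair_measurements(sub, "blood"))

    def test_blq_reference_drops_pair(self):
        conc = pd.DataFrame({
            "subject_id": ["S01"] * 4,
            "analyte": ["R-PZQ"] * 4,
            "matrix": ["plasma", "plasma", "blood", "blood"],
            "time_h": [2.0, 4.0, 2.0, 4.0],
            "conc_ug_ml": [np.nan, 0.5, 0.4, 0.45],
            "blq": [1, 0, 0, 0],
        })
        pairs = pair_measurements(conc, "blood")
        assert list(pairs["time_h"]) == [4.0]

    def test_zero_surviving_pairs_is_error(self):
        conc = pd.DataFrame({
            "subject_id": ["S01", "S01"],
            "analyte": ["R-PZQ", "R-PZQ"],
            "matrix": ["plasma", "blood"],
            "time_h": [2.0, 4.0],  # disjoint times
            "conc_ug_ml": [0.5, 0.4],
            "blq": [0, 0],
        })
        with pytest.raises(ValueError):
            pair_measurements(conc, "blood")


class TestRatiosAndCorrelation:
    def test_proportional_measurements_correlate_perfectly(self):
        ref = np.linspace(0.1, 2.0, 20)
        pairs = pd.DataFrame({"reference_value": ref, "test_value": 0.8 * ref})
        assert pearson_pooled(pairs) == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_cohort_correlation_is_one(self, noiseless_cohort):
        conc, _ = noiseless_cohort
        for matrix in ("blood", "DBS"):
            pairs = pair_measurements(conc[conc.analyte == "S-PZQ"], matrix)
            assert pearson_pooled(pairs) == pytest.approx(1.0, abs=1e-12)

    def test_ratio_values(self):
        pairs = pd.DataFrame({"reference_value": [1.0, 1.0],
                              "test_value": [1.0, 0.8]})
        out = percentage_ratios(pairs)
        assert list(out["ratio_pct"]) == [100.0, 80.0]

    def test_nonpositive_reference_excluded(self):
        pairs = pd.DataFrame({"reference_value": [0.0, 2.0],
                              "test_value": [1.0, 1.0]})
        out = percentage_ratios(pairs)
        assert len(out) == 1 and out["ratio_pct"].iloc[0] == 50.0

    def test_noiseless_ratio_mean_recovers_partition(self, noiseless_cohort):
        conc, _ = noiseless_cohort
        pairs = percentage_ratios(
            pair_measurements(conc[conc.analyte == "R-PZQ"], "blood"))
        assert pairs["ratio_pct"].mean() == pytest.approx(80.0, abs=1e-9)


class TestConventionalLoa:
    def test_indicative_bioanalytical_envelope(self):
        # mean 100%, SD 15%: the +/-15% validation envelope translated
        # into limits of agreement
        res = loa_conventional([85.0, 100.0, 115.0])
        assert res.mean_ratio_pct == pytest.approx(100.0)
        assert res.sd_total_pct == pytest.approx(15.0)
        assert res.loa_lower_pct == pytest.approx(70.6)
        assert res.loa_upper_pct == pytest.approx(129.4)

    def test_degenerate_identical_ratios(self):
        res = loa_conventional([80.0] * 5)
        assert res.loa_lower_pct == res.loa_upper_pct == 80.0

    def test_monte_carlo_matches_closed_form(self):
        rng = np.random.default_rng(9)
        draws = rng.normal(80.0, 10.0, size=1000)
        res = loa_conventional(draws)
        assert res.loa_lower_pct == pytest.approx(60.4, abs=1.5)
        assert res.loa_upper_pct == pytest.approx(99.6, abs=1.5)

    def test_symmetric_bracketing_width(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(90.0, 7.0, size=50)
        res = loa_conventional(draws)
        assert res.loa_upper_pct - res.mean_ratio_pct == pytest.approx(
            res.mean_ratio_pct - res.loa_lower_pct)
        assert res.loa_upper_pct - res.loa_lower_pct == pytest.approx(
            2 * 1.96 * res.sd_total_pct)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            loa_conventional([100.0])


class TestRepeatedMeasuresLoa:
    def test_constant_ratios_collapse(self):
        res = loa_repeated([95.0] * 6, ["a", "a", "b", "b", "c", "c"])
        assert res.mean_ratio_pct == 95.0
        assert res.sd_total_pct == 0.0
        assert (res.loa_lower_pct, res.loa_upper_pct) == (95.0, 95.0)

    def test_balanced_equal_means_reduces_to_within_sd(self):
        # two subjects x three observations, equal subject means
        ratios = [78.0, 80.0, 82.0, 79.0, 80.0, 81.0]
        subjects = ["a"] * 3 + ["b"] * 3
        res = loa_repeated(ratios, subjects)
        assert res.sigma_between_pct == 0.0
        ss_within = sum((r - 80.0) ** 2 for r in ratios)
        assert res.sd_total_pct == pytest.approx(np.sqrt(ss_within / 4))

    def test_unbalanced_case_matches_anova_oracle(self):
        groups = [[72.0, 81.0], [88.0, 90.0, 95.0], [79.0, 84.0, 77.0, 86.0]]
        ratios = [v for g in groups for v in g]
        subjects = [s for i, g in enumerate(groups) for s in [f"s{i}"] * len(g)]
        res = loa_repeated(ratios, subjects)
        grand, var_b, var_w, sd_total = anova_variance_components(groups)
        assert res.mean_ratio_pct == pytest.approx(grand, rel=1e-12)
        assert res.sigma_between_pct**2 == pytest.approx(var_b, rel=1e-12)
        assert res.sigma_within_pct**2 == pytest.approx(var_w, rel=1e-12)
        assert res.sd_total_pct == pytest.approx(sd_total, rel=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(
        st.lists(st.floats(min_value=40.0, max_value=160.0),
                 min_size=1, max_size=6),
        min_size=2, max_size=5,
    ).filter(lambda gs: max(len(g) for g in gs) >= 2))
    def test_variance_components_match_oracle_on_small_instances(self, groups):
        ratios = [v for g in groups for v in g]
        subjects = [s for i, g in enumerate(groups) for s in [f"s{i}"] * len(g)]
        res = loa_repeated(ratios, subjects)
        grand, var_b, var_w, sd_total = anova_variance_components(groups)
        assert res.mean_ratio_pct == pytest.approx(grand, rel=1e-12, abs=1e-12)
        assert res.sigma_between_pct**2 == pytest.approx(var_b, rel=1e-9,
                                                         abs=1e-9)
        assert res.sd_total_pct == pytest.approx(sd_total, rel=1e-9, abs=1e-9)

    def test_all_singletons_falls_back_to_conventional(self):
        ratios = [70.0, 90.0, 110.0]
        res = loa_repeated(ratios, ["a", "b", "c"])
        assert res.method == "conventional"
        assert "singleton_fallback" in res.flags
        conv = loa_conventional(ratios)
        assert res.sd_total_pct == conv.sd_total_pct

    def test_total_sd_at_least_within_sd(self):
        rng = np.random.default_rng(17)
        subjects = np.repeat([f"s{i}" for i in range(9)], 8)
        ratios = rng.normal(90, 10, size=subjects.size) + np.repeat(
            rng.normal(0, 6, size=9), 8)
        res = loa_repeated(ratios, subjects)
        assert res.sd_total_pct >= res.sigma_within_pct

    def test_homogeneous_subjects_agree_with_conventional(self):
        # no true between-subject component: both estimators target the
        # same spread
        rng = np.random.default_rng(3)
        subjects = np.repeat([f"s{i}" for i in range(10)], 20)
        ratios = rng.normal(85, 9, size=subjects.size)
        rep = loa_repeated(ratios, subjects)
        conv = loa_conventional(ratios)
        assert rep.sd_total_pct == pytest.approx(conv.sd_total_pct, rel=0.15)


class TestConfidenceIntervals:
    def test_zero_sd_gives_zero_width(self):
        res = loa_confidence_intervals(
            loa_repeated([95.0] * 6, ["a", "a", "b", "b", "c", "c"]))
        assert res.ci_mean == (95.0, 95.0)
        assert res.ci_loa_lower == (95.0, 95.0)
        assert res.ci_loa_upper == (95.0, 95.0)

    def test_mean_ci_shrinks_as_root_m(self):
        def width(m):
            res = AgreementResult(
                n_pairs=m, n_subjects=m, mean_ratio_pct=100.0,
                sd_total_pct=10.0, loa_lower_pct=80.4, loa_upper_pct=119.6)
            res = loa_confidence_intervals(res)
            return res.ci_mean[1] - res.ci_mean[0]

        assert width(100) / width(400) == pytest.approx(2.0, rel=0.02)

    def test_formula_direct_evaluation_m9(self):
        from scipy import stats
        m, sd = 9, 12.3
        res = AgreementResult(
            n_pairs=m, n_subjects=m, mean_ratio_pct=100.0, sd_total_pct=sd,
            loa_lower_pct=100 - 1.96 * sd, loa_upper_pct=100 + 1.96 * sd)
        res = loa_confidence_intervals(res)
        t_crit = stats.t.ppf(0.975, m - 1)
        assert res.ci_mean[1] - res.ci_mean[0] == pytest.approx(
            2 * t_crit * sd / np.sqrt(m), rel=1e-12)
        se_exact = sd * np.sqrt(1 / m + 1.96**2 / (2 * (m - 1)))
        assert res.ci_loa_upper[1] - res.ci_loa_upper[0] == pytest.approx(
            2 * t_crit * se_exact, rel=1e-12)
        # classical approximation SE ~ 1.71 sd / sqrt(m)
        assert se_exact == pytest.approx(1.71 * sd / np.sqrt(m), rel=0.05)

    def test_too_few_subjects_flagged(self):
        res = loa_confidence_intervals(
            loa_repeated([90.0, 95.0, 80.0, 85.0], ["a", "a", "b", "b"]))
        assert "ci_unavailable" in res.flags
        assert res.ci_mean is None


class TestPublicationTables:
    def test_noiseless_parameter_ratios(self, noiseless_cohort):
        conc, _ = noiseless_cohort
        params = nca.nca_analyze(conc)
        table = parameter_ratio_table(params, test_matrices=("blood",))
        table = table.set_index(["analyte", "parameter"])
        for analyte, r in (("R-PZQ", 80.0), ("S-PZQ", 80.0),
                           ("R-trans-4-OH", 115.0)):
            assert table.loc[(analyte, "auc_0_24"),
                             "mean_ratio_pct"] == pytest.approx(r, rel=1e-9)
            assert table.loc[(analyte, "cmax"),
                             "mean_ratio_pct"] == pytest.approx(r, rel=1e-9)
            assert table.loc[(analyte, "tmax"),
                             "mean_ratio_pct"] == pytest.approx(100.0,
                                                                rel=1e-9)
            assert table.loc[(analyte, "t_half"),
                             "mean_ratio_pct"] == pytest.approx(100.0,
                                                                rel=1e-9)

    def test_concentration_table_shape(self, default_cohort):
        conc, _ = default_cohort
        table = concentration_agreement_table(conc)
        assert len(table) == 6  # 3 analytes x {blood, DBS}
        assert set(table["method"]) == {"repeated"}
        assert (table["n_subjects"] == 9).all()

    def test_single_subject_parameter_ratio(self):
        params = pd.DataFrame([
            {"subject_id": "S01", "analyte": "R-PZQ", "matrix": m,
             "parameter": "cmax", "value": v, "flag": ""}
            for m, v in (("plasma", 0.2), ("blood", 0.16))
        ])
        table = parameter_ratio_table(params, test_matrices=("blood",),
                                      parameters=("cmax",))
        assert table["mean_ratio_pct"].iloc[0] == pytest.approx(80.0)
        assert table["n_subjects"].iloc[0] == 1
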