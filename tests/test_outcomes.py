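"""Outcome statistics: KM, log-rank, chi-square, Mann-Whitney,
cumulative incidence of relapse, characteristics table."""

import numpy as np
import pandas as pd
import pytest

from kinarray import outcomes as oc
from kinarray.datatypes import ClinicalTable, ValidationError
from oracles import (
    km_hand_oracle,
    logrank_permutation_p,
    logrank_statistic,
    mann_whitney_enumeration,
)


class TestKaplanMeier:
    def test_worked_product_limit_example(self):
        times, events, expected = km_hand_oracle()
        curve = oc.km_estimate(times, events)
        assert curve["time"].iloc[0] == 0.0
        assert curve["survival"].iloc[0] == 1.0
        lookup = dict(zip(curve["time"], curve["survival"]))
        for t, s in expected.items():
            assert lookup[t] == pytest.approx(s)

    def test_no_events_curve_stays_at_one(self):
        curve = oc.km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert (curve["survival"] == 1.0).all()

    def test_monotone_non_increasing(self, rng):
        times = rng.exponential(size=40)
        events = rng.integers(0, 2, size=40)
        curve = oc.km_estimate(times, events)
        assert (np.diff(curve["survival"]) <= 1e-12).all()

    def test_empty_input_is_error(self):
        with pytest.raises(ValidationError, match="empty"):
            oc.km_estimate([], [])


class TestLogRank:
    def test_statistic_matches_hand_formula(self, rng):
        times = rng.exponential(size=30)
        events = rng.integers(0, 2, size=30)
        group = rng.integers(0, 2, size=30)
        if events.sum() == 0 or len(np.unique(group)) < 2:
            pytest.skip("degenerate draw")
        res = oc.logrank_test(times, events, group)
        assert res.statistic == pytest.approx(logrank_statistic(times, events, group), rel=1e-9)
        assert res.df == 1

    def test_p_agrees_with_permutation_null(self):
        rng = np.random.default_rng(7)
        times = np.concatenate([rng.exponential(1.0, 15), rng.exponential(2.5, 15)])
        events = np.ones(30, int)
        group = np.repeat([0, 1], 15)
        res = oc.logrank_test(times, events, group)
        p_perm = logrank_permutation_p(times, events, group, n_perm=2000)
        assert res.p_value == pytest.approx(p_perm, abs=0.03)

    def test_needs_exactly_two_groups(self):
        with pytest.raises(ValidationError, match="2 groups"):
            oc.logrank_test([1, 2, 3], [1, 1, 1], ["a", "b", "c"])


class TestChiSquare2x2:
    def test_table_1a_sex_example(self):
        res = oc.chi_square_2x2([[22, 15], [41, 15]])
        assert res.p_value == pytest.approx(0.16, abs=0.005)
        assert res.statistic == pytest.approx(1.93, abs=0.01)

    def test_relapse_example_closed_form(self):
        # chi2 = N (ad - bc)^2 / (r1 r2 c1 c2)
        a, b, c, d = 10, 29, 26, 31
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        res = oc.chi_square_2x2([[a, b], [c, d]])
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert res.p_value == pytest.approx(0.047, abs=0.001)

    def test_proportional_table_gives_zero(self):
        res = oc.chi_square_2x2([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_is_error(self):
        with pytest.raises(ValidationError, match="zero margin"):
            oc.chi_square_2x2([[0, 5], [0, 7]])

    def test_wrong_shape_is_error(self):
        with pytest.raises(ValidationError, match="2x2"):
            oc.chi_square_2x2([[1, 2, 3], [4, 5, 6]])


class TestMannWhitney:
    @pytest.mark.parametrize("nx,ny", [(3, 4), (5, 5), (6, 6)])
    def test_exact_p_matches_full_enumeration(self, nx, ny, rng):
        for _ in range(4):
            x = rng.normal(size=nx)
            y = rng.normal(1.0, size=ny)
            res = oc.mann_whitney_u(x, y)
            assert res.method == "mann-whitney-exact"
            assert res.p_value == pytest.approx(
                mann_whitney_enumeration(x, y), abs=1e-12
            )

    def test_large_samples_use_asymptotic(self, rng):
        res = oc.mann_whitney_u(rng.normal(size=20), rng.normal(size=20))
        assert res.method == "mann-whitney-asymptotic"

    def test_ties_force_asymptotic(self):
        res = oc.mann_whitney_u([1.0, 2.0, 2.0], [3.0, 4.0, 5.0])
        assert res.method == "mann-whitney-asymptotic"

    def test_symmetric_in_arguments(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=9)
        assert oc.mann_whitney_u(x, y).p_value == pytest.approx(
            oc.mann_whitney_u(y, x).p_value
        )

    def test_empty_sample_is_error(self):
        with pytest.raises(ValidationError, match="empty"):
            oc.mann_whitney_u([], [1.0])


def _labels_and_clinical(default_cohort):
    _, _, clinical, truth = default_cohort
    return clinical, pd.Series(truth.labels)


class TestCumulativeIncidence:
    def test_proportions_and_test_on_cohort(self, default_cohort):
        clinical, labels = _labels_and_clinical(default_cohort)
        proportions, test, curves = oc.cumulative_incidence_relapse(clinical, labels)
        assert set(proportions) == {1, 2}
        for c in (1, 2):
            assert 0.0 <= proportions[c] <= 1.0
            ci = curves[c]["cumulative_incidence"]
            assert (np.diff(ci) >= -1e-12).all()
            assert ci.iloc[0] == pytest.approx(0.0)
        assert test.method == "pearson-chi2"
        assert 0.0 <= test.p_value <= 1.0

    def test_curve_endpoint_is_below_relapse_proportion_bound(self, default_cohort):
        clinical, labels = _labels_and_clinical(default_cohort)
        proportions, _, curves = oc.cumulative_incidence_relapse(clinical, labels)
        for c in (1, 2):
            # 1 - KM at last event time is at least the crude proportion
            assert curves[c]["cumulative_incidence"].iloc[-1] >= proportions[c] - 1e-9

    def test_missing_relapse_flags_excluded(self, default_cohort, caplog):
        clinical, labels = _labels_and_clinical(default_cohort)
        df = clinical.data.copy()
        df.loc[df.index[0], "relapse"] = np.nan
        table = ClinicalTable(data=df)
        with caplog.at_level("INFO"):
            proportions, _, _ = oc.cumulative_incidence_relapse(table, labels)
        assert "missing relapse flag" in caplog.text

    def test_single_cluster_is_error(self, default_cohort):
        clinical, labels = _labels_and_clinical(default_cohort)
        with pytest.raises(ValidationError, match="2 clusters"):
            oc.cumulative_incidence_relapse(clinical, labels * 0 + 1)


class TestCharacteristicsTable:
    def test_covers_expected_variables(self, default_cohort):
        clinical, labels = _labels_and_clinical(default_cohort)
        table = oc.characteristics_table(clinical, labels)
        for var in oc.CONTINUOUS_VARS:
            assert table.loc[var, "method"].startswith("mann-whitney")
        assert (table["p_value"] <= 1.0).all() and (table["p_value"] >= 0.0).all()

    def test_single_level_variable_skipped_with_warning(self, default_cohort, caplog):
        clinical, labels = _labels_and_clinical(default_cohort)
        df = clinical.data.copy()
        df["sex"] = "male"
        with caplog.at_level("WARNING"):
            table = oc.characteristics_table(ClinicalTable(data=df), labels)
        assert "sex" not in table.index
        assert "skipping sex" in caplog.text

    def test_unknowns_excluded_not_imputed(self, default_cohort):
        clinical, labels = _labels_and_clinical(default_cohort)
        df = clinical.data.copy()
        # force half of cluster-1 unknown; test must still run on the rest
        c1 = labels.index[labels == 1]
        df.loc[c1[: len(c1) // 2], "sex"] = "unknown"
        table = oc.characteristics_table(ClinicalTable(data=df), labels)
        if "sex" in table.index:
            assert 0.0 <= table.loc["sex", "p_value"] <= 1.0


class TestOverallSurvival:
    def test_curves_and_logrank_on_cohort(self, default_cohort):
        clinical, labels = _labels_and_clinical(default_cohort)
        curves, test = oc.overall_survival(clinical, labels)
        assert set(curves) == {1, 2}
        for c in (1, 2):
            assert curves[c]["survival"].iloc[0] == 1.0
        assert test.method == "log-rank"
        assert 0.0 <= test.p_value <= 1.0
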