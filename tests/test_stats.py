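"""Diagnostic statistics: 2x2 tallies, DOR, chi-square, binomial, grid search."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from egmdur import (
    ContingencyTable,
    binomial_test,
    chi_square,
    contingency,
    diagnostic_odds_ratio,
    grid_search,
    sensitivity_specificity,
)
from egmdur.errors import DataError, GridSearchError, ParameterError


def _summary(flags):
    """Build a minimal 17-row summary with given (abnormal, ablated) flags."""
    rows = []
    for i in range(17):
        if i < len(flags):
            abnormal, ablated = flags[i]
            rows.append((i + 1, 10, 80.0, 0.5, "border", ablated, abnormal))
        else:
            rows.append((i + 1, 0, np.nan, np.nan, "empty", False, False))
    return pd.DataFrame(rows, columns=["segment", "n_points", "mean_duration_ms",
                                       "mean_voltage_mv", "voltage_class",
                                       "ablated", "abnormal"])


class TestContingency:
    def test_direct_tally(self):
        s = _summary([(True, True), (True, False), (False, True), (False, False)])
        t = contingency([s])
        assert (t.tp, t.fn, t.fp, t.tn) == (1, 1, 1, 1)

    def test_additive_over_patients(self):
        s = _summary([(True, True), (False, False), (True, False)])
        one = contingency([s])
        two = contingency([s, s])
        assert (two.tp, two.fn, two.fp, two.tn) == (2 * one.tp, 2 * one.fn,
                                                    2 * one.fp, 2 * one.tn)

    def test_empty_segments_excluded(self):
        s = _summary([(True, True)])
        t = contingency([s])
        assert t.total == 1

    def test_all_empty_is_data_error(self):
        with pytest.raises(DataError):
            contingency([_summary([])])


class TestDiagnosticOddsRatio:
    def test_closed_form(self):
        res = diagnostic_odds_ratio(ContingencyTable(10, 5, 2, 20))
        assert res.dor == pytest.approx(20.0)
        assert not res.corrected
        assert res.ci_low <= res.dor <= res.ci_high

    def test_haldane_correction_on_zero_cell(self):
        # cells become (5.5, 0.5, 2.5, 10.5): (5.5*10.5)/(0.5*2.5) = 46.2
        res = diagnostic_odds_ratio(ContingencyTable(5, 0, 2, 10))
        assert res.corrected
        assert res.dor == pytest.approx(46.2)

    def test_swap_symmetry_inverts(self):
        a = diagnostic_odds_ratio(ContingencyTable(10, 5, 2, 20))
        b = diagnostic_odds_ratio(ContingencyTable(5, 10, 20, 2))
        assert a.dor * b.dor == pytest.approx(1.0)

    def test_independent_table_has_unit_dor(self):
        res = diagnostic_odds_ratio(ContingencyTable(30, 20, 60, 40))
        assert res.dor == pytest.approx(1.0, abs=1e-12)

    def test_ci_matches_lognormal_formula(self):
        t = ContingencyTable(10, 5, 2, 20)
        res = diagnostic_odds_ratio(t)
        se = np.sqrt(1 / 10 + 1 / 5 + 1 / 2 + 1 / 20)
        z = sps.norm.ppf(0.975)
        assert res.ci_low == pytest.approx(20.0 * np.exp(-z * se))
        assert res.ci_high == pytest.approx(20.0 * np.exp(z * se))

    def test_ci_coverage_under_known_odds(self):
        # fixed-odds sampling model: coverage of the 95% CI must be ~95%
        rng = np.random.default_rng(42)
        p1, p2, n1, n2 = 0.6, 0.2, 50, 60
        true_or = (p1 / (1 - p1)) / (p2 / (1 - p2))
        hits = 0
        for _ in range(500):
            tp = rng.binomial(n1, p1)
            fp = rng.binomial(n2, p2)
            res = diagnostic_odds_ratio(ContingencyTable(tp, n1 - tp, fp, n2 - fp))
            hits += res.ci_low <= true_or <= res.ci_high
        assert 0.90 <= hits / 500 <= 0.99


class TestSensitivitySpecificity:
    def test_direct_ratios(self):
        sens, spec = sensitivity_specificity(ContingencyTable(10, 5, 2, 20))
        assert sens == pytest.approx(10 / 15)
        assert spec == pytest.approx(20 / 22)

    def test_perfect_and_inverted(self):
        assert sensitivity_specificity(ContingencyTable(7, 0, 0, 9)) == (1.0, 1.0)
        assert sensitivity_specificity(ContingencyTable(0, 7, 9, 0)) == (0.0, 0.0)

    def test_empty_margin_rejected(self):
        with pytest.raises(DataError, match="ablated"):
            sensitivity_specificity(ContingencyTable(0, 0, 5, 5))


class TestChiSquare:
    def test_independence_gives_zero(self):
        stat, p = chi_square(ContingencyTable(10, 10, 10, 10))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        stat, _ = chi_square(ContingencyTable(20, 5, 5, 20))
        assert stat == pytest.approx(18.0)

    def test_equals_squared_z_for_proportions(self):
        t = ContingencyTable(18, 7, 11, 30)
        stat, _ = chi_square(t)
        # two-proportion z-statistic on the same table
        n1, n2 = t.tp + t.fn, t.fp + t.tn
        p1, p2 = t.tp / n1, t.fp / n2
        pool = (t.tp + t.fp) / (n1 + n2)
        z = (p1 - p2) / np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        assert stat == pytest.approx(z**2)

    def test_zero_margin_rejected(self):
        with pytest.raises(DataError):
            chi_square(ContingencyTable(0, 0, 5, 5))


class TestBinomialTest:
    def test_whole_sample_space(self):
        assert binomial_test(1, 1, 0.95, sided="one") == pytest.approx(1.0)

    def test_lower_tail_closed_form(self):
        assert binomial_test(0, 3, 0.5, sided="one") == pytest.approx(0.125)

    def test_two_sided_at_mode_is_one(self):
        assert binomial_test(5, 10, 0.5, sided="two") == pytest.approx(1.0)

    def test_invalid_args(self):
        with pytest.raises(ParameterError):
            binomial_test(5, 3, 0.5)
        with pytest.raises(ParameterError):
            binomial_test(1, 3, 1.5)


class TestGridSearch:
    def test_recovers_constructed_optimum(self, small_cohort):
        maps, _ = small_cohort
        res = grid_search(maps, w_range=[20, 40], theta_range=[0.15],
                          c_range=[60, 70, 80])
        assert res.best_dor == res.surface["dor"].max()
        n = len(res.surface)
        assert n == 2 * 1 * 3

    def test_surface_matches_independent_pipeline_run(self, small_cohort):
        from egmdur import cohort_statistics
        from egmdur.duration import DurationParams
        maps, _ = small_cohort
        res = grid_search(maps, w_range=[40], theta_range=[0.15], c_range=[70])
        row = res.surface.iloc[0]
        cs = cohort_statistics(maps, DurationParams(40, 0.15, 70))
        t = cs["table"]
        assert (row.tp, row.fn, row.fp, row.tn) == (t.tp, t.fn, t.fp, t.tn)
        assert row.dor == pytest.approx(cs["dor"].dor)

    def test_duplicating_patients_preserves_argmax(self, small_cohort):
        maps, _ = small_cohort
        a = grid_search(maps, w_range=[20, 40], theta_range=[0.10, 0.30],
                        c_range=[60, 70])
        b = grid_search(list(maps) + list(maps), w_range=[20, 40],
                        theta_range=[0.10, 0.30], c_range=[60, 70])
        assert a.best_params == b.best_params

    def test_abnormal_count_nonincreasing_in_cutoff(self, small_cohort):
        maps, _ = small_cohort
        res = grid_search(maps, w_range=[40], theta_range=[0.15],
                          c_range=[60, 65, 70, 75, 80])
        s = res.surface.sort_values("c_ms")
        abnormal = (s.tp + s.fp).to_numpy()
        assert np.all(np.diff(abnormal) <= 0)

    def test_unablated_cohort_is_search_error(self, small_cohort):
        from egmdur.model import ElectroanatomicMap
        maps, _ = small_cohort
        bare = [ElectroanatomicMap(m.patient_id, m.points, m.landmarks, m.mesh, [])
                for m in maps]
        with pytest.raises(GridSearchError):
            grid_search(bare, w_range=[40], theta_range=[0.15], c_range=[70])
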