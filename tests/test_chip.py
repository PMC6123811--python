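import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from _oracles import oracle_binom_tail
from ampliclone.chip import (
    ExportRecord,
    PenRecord,
    contamination_rate,
    doubling_time,
    export_efficiency,
    exports_from_tsv,
    exports_to_tsv,
    occe,
    pens_from_tsv,
    pens_to_tsv,
    screening_plan,
    staining_positivity,
    viability_by_export_size,
)
from ampliclone.errors import ConfigurationError, InputError, UndefinedStatisticError
from ampliclone.simulate import GrowthModel, simulate_exports, simulate_pens


def _pen(pen_id, initial, counts, condition="edited", fluorescence=None):
    return PenRecord(pen_id, condition, initial, counts, fluorescence)


GROWN = {0: 1, 24: 2, 48: 4, 72: 8}
STUCK = {0: 1, 24: 1, 48: 1, 72: 1}
EMPTY = {0: 0, 24: 0, 48: 0, 72: 0}


class TestOcce:
    def test_hand_counted(self):
        pens = [_pen(f"p{i}", 1, GROWN) for i in range(4)] + [
            _pen(f"q{i}", 1, STUCK) for i in range(6)
        ]
        assert occe(pens) == pytest.approx(0.4)

    def test_multi_cell_pen_excluded(self):
        pens = [
            _pen("a", 1, GROWN),
            _pen("b", 2, {0: 2, 24: 6, 48: 12, 72: 20}),  # not clonal: ignored
        ]
        assert occe(pens) == 1.0

    def test_no_single_cell_pens_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            occe([_pen("a", 0, EMPTY)])

    def test_round_trip_with_simulator(self):
        # doubling 18 h -> 16 cells at 72 h; p_no_growth 0.6 -> occe ~ 0.4
        growth = GrowthModel(doubling_time_h=18.0, p_no_growth=0.6, p_contam_pen=0.0)
        pens = simulate_pens(growth, 3000, 1.0, 42)
        got = occe(pens)
        lo, hi = stats.binom.interval(0.99, 3000, 0.4)
        assert lo / 3000 <= got <= hi / 3000

    def test_order_invariant(self):
        pens = [_pen(f"p{i}", 1, GROWN if i % 3 else STUCK) for i in range(30)]
        assert occe(pens) == occe(list(reversed(pens)))


class TestContamination:
    def test_hand_counted(self):
        pens = [_pen(f"p{i}", 0, EMPTY) for i in range(99)]
        pens.append(_pen("gain", 0, {0: 0, 24: 1, 48: 2, 72: 4}))
        assert contamination_rate(pens) == pytest.approx(0.01)

    def test_all_stay_empty(self):
        assert contamination_rate([_pen(f"p{i}", 0, EMPTY) for i in range(10)]) == 0.0

    def test_no_empty_pens_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            contamination_rate([_pen("a", 1, GROWN)])


class TestDoublingTime:
    def test_exact_24h(self):
        assert doubling_time({0: 1, 24: 2, 48: 4, 72: 8}) == pytest.approx(24.0)

    def test_exact_18h(self):
        assert doubling_time({0: 1, 24: 2.52, 48: 6.35, 72: 16}) == pytest.approx(
            18.0, rel=0.01
        )
        assert doubling_time({0: 1, 72: 16}, method="endpoint") == pytest.approx(18.0)

    def test_zero_counts_excluded(self):
        assert doubling_time({0: 0, 24: 2, 48: 4, 72: 8}) == pytest.approx(24.0)

    def test_non_increasing_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            doubling_time({0: 8, 24: 4, 48: 2})

    def test_too_few_points_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            doubling_time({0: 0, 24: 0, 48: 5})

    def test_unknown_method(self):
        with pytest.raises(ConfigurationError):
            doubling_time({0: 1, 24: 2}, method="banana")

    @settings(max_examples=60, deadline=None)
    @given(d=st.floats(min_value=1.0, max_value=100.0, allow_nan=False))
    def test_exact_series_recovers_d(self, d):
        counts = {t: 2.0 ** (t / d) for t in (0, 24, 48, 72)}
        assert math.isclose(doubling_time(counts), d, rel_tol=1e-9)

    def test_noisy_recovery_within_10_percent(self):
        rng = np.random.default_rng(7)
        true_d = 24.0
        estimates = []
        for _ in range(100):
            counts = {
                t: 2.0 ** (t / true_d) * rng.lognormal(0.0, 0.1) for t in (0, 24, 48, 72)
            }
            estimates.append(doubling_time(counts))
        estimates = np.array(estimates)
        assert abs(np.mean(estimates) - true_d) / true_d < 0.10
        assert np.median(np.abs(estimates - true_d)) / true_d < 0.10


class TestExportStats:
    def test_export_efficiency_worked_example(self):
        recs = [
            ExportRecord(f"c{i}", 10 if i < 40 else 1, i < 40, i < 40 and i % 2 == 0)
            for i in range(48)
        ]
        assert export_efficiency(recs) == pytest.approx(40 / 48)

    def test_all_ok(self):
        recs = [ExportRecord(f"c{i}", 12, True, False) for i in range(5)]
        assert export_efficiency(recs) == 1.0

    def test_empty_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            export_efficiency([])

    def test_viability_high_stratum(self):
        recs = [ExportRecord(f"c{i}", 15, True, i < 6) for i in range(10)]
        summary = viability_by_export_size(recs, threshold_cells=10)
        assert summary.high_survival == pytest.approx(0.6)
        assert summary.low_n == 0 and summary.low_survival is None

    def test_logistic_model_positive_rank_correlation(self):
        recs = simulate_exports(500, 3, p_export_fail=0.0)
        summary = viability_by_export_size(recs, threshold_cells=10)
        assert summary.rank_correlation is not None and summary.rank_correlation > 0
        assert summary.high_survival >= summary.low_survival

    def test_calibrated_survival_within_binomial_interval(self):
        recs = simulate_exports(1000, 11, p_export_fail=0.0, survival_prob=0.6)
        summary = viability_by_export_size(recs, threshold_cells=10)
        n = summary.high_n
        lo, hi = stats.binom.interval(0.99, n, 0.6)
        assert lo / n <= summary.high_survival <= hi / n

    def test_survived_requires_exported_ok(self):
        with pytest.raises(InputError):
            ExportRecord("c", 0, False, True)


class TestStainingPositivity:
    def test_threshold_extremes(self):
        pens = [_pen(f"p{i}", 1, GROWN, fluorescence=100.0 + i) for i in range(10)]
        res = staining_positivity(pens, intensity_threshold=1e9)
        assert res["edited"].fraction_positive == 0.0
        res = staining_positivity(pens, intensity_threshold=0.0)
        assert res["edited"].fraction_positive == 1.0

    def test_simulated_control_positive_rate(self):
        growth = GrowthModel(p_no_growth=0.0, p_contam_pen=0.0)
        pens = simulate_pens(
            growth, 2000, 1.0, 5, condition="control", p_positive=0.9
        )
        res = staining_positivity(pens, intensity_threshold=500.0)
        n = res["control"].n_colonies
        lo, hi = stats.binom.interval(0.99, n, 0.9)
        assert lo / n <= res["control"].fraction_positive <= hi / n

    def test_missing_intensities_counted(self):
        pens = [
            _pen("a", 1, GROWN, fluorescence=900.0),
            _pen("b", 1, GROWN, fluorescence=None),
        ]
        res = staining_positivity(pens, intensity_threshold=500.0)
        assert res["edited"].n_missing_intensity == 1
        assert res["edited"].n_colonies == 1


class TestScreeningPlan:
    def test_worked_example_expectation(self):
        plan = screening_plan(0.05, 0.5, n_screened=100)
        assert plan.expected_viable == pytest.approx(2.5)

    def test_tail_matches_closed_form_and_oracle(self):
        plan = screening_plan(0.05, 0.5, n_screened=100, k=1)
        closed = 1.0 - 0.975**100
        assert plan.p_at_least_k == pytest.approx(closed, abs=1e-12)
        assert plan.p_at_least_k == pytest.approx(
            oracle_binom_tail(100, 0.025, 1), abs=1e-9
        )

    def test_certain_success_needs_one_clone(self):
        plan = screening_plan(1.0, 1.0, target_prob=0.99, k=1)
        assert plan.n_screened == 1

    def test_inverse_mode_monotone_in_target(self):
        sizes = [
            screening_plan(0.05, 0.5, target_prob=t, k=1).n_screened
            for t in (0.5, 0.8, 0.9, 0.95, 0.99)
        ]
        assert sizes == sorted(sizes)

    def test_inverse_achieves_target(self):
        plan = screening_plan(0.05, 0.5, target_prob=0.95, k=2)
        assert plan.p_at_least_k >= 0.95
        smaller = screening_plan(0.05, 0.5, n_screened=plan.n_screened - 1, k=2)
        assert smaller.p_at_least_k < 0.95

    def test_invalid_probabilities(self):
        with pytest.raises(ConfigurationError):
            screening_plan(0.0, 0.5, n_screened=10)
        with pytest.raises(ConfigurationError):
            screening_plan(0.5, 1.5, n_screened=10)

    def test_missing_mode(self):
        with pytest.raises(ConfigurationError):
            screening_plan(0.5, 0.5)


class TestTsvRoundTrips:
    def test_pens(self, tmp_path):
        growth = GrowthModel()
        pens = simulate_pens(growth, 25, 0.6, 1, p_positive=0.8)
        path = str(tmp_path / "pens.tsv")
        pens_to_tsv(pens, path)
        back = pens_from_tsv(path)
        assert len(back) == 25
        assert occe(back) == occe(pens)
        assert contamination_rate(back) == contamination_rate(pens)

    def test_exports(self, tmp_path):
        recs = simulate_exports(40, 2)
        path = str(tmp_path / "exports.tsv")
        exports_to_tsv(recs, path)
        assert exports_from_tsv(path) == recs

    def test_pen_invariants(self):
        with pytest.raises(InputError):
            PenRecord("p", "edited", 1, {0: 2})
        with pytest.raises(InputError):
            PenRecord("p", "edited", 1, {0: 1, 24: -1})
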