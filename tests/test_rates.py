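import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deukin import (
    ESFractionParams,
    ParameterError,
    classify_peak,
    end_gain_rate,
    es_closed_form,
    gain_rate,
    gain_rate_bound,
    initial_gain_rate,
    initial_loss_rate,
    intersection_criterion,
    k_transform,
    kh_map,
    lifespan_fold_error,
    loss_rate,
    maintenance_summary,
    rate_summary,
    simulate_es,
    simulate_kh,
)
from conftest import REFERENCE_CASES, random_es_params


def _params(case):
    return ESFractionParams(d1=case["d1"], p2=case["p2"], d2=case["d2"], k=case["k"])


class TestAnalyticApproximations:
    @pytest.mark.parametrize("case", REFERENCE_CASES, ids=str)
    def test_reference_gain_and_loss_rates(self, case):
        """All printed initial/final gain and post-pulse loss rates."""
        p = _params(case)
        assert round(initial_gain_rate(p), 2) == case["p0"]
        assert round(end_gain_rate(p), 2) == case["p1"]
        assert round(initial_loss_rate(p), 2) == case["dpost"]

    def test_nondividing_poi_starts_at_zero_rate(self):
        assert initial_gain_rate(ESFractionParams(0.4, 0.0, 0.3, 1)) == 0.0

    def test_exact_gain_rate_at_zero_equals_initial(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            p = random_es_params(rng, lo=0.05, hi=3.0)
            assert gain_rate(p, 0.0, "exact") == pytest.approx(
                initial_gain_rate(p), abs=1e-12
            )

    def test_linear_gain_rate_at_one_equals_end(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            p = random_es_params(rng)
            assert gain_rate(p, 1.0, "linear") == pytest.approx(
                end_gain_rate(p), abs=1e-12
            )

    def test_exact_gain_rate_matches_finite_difference(self, step_schedule):
        p = ESFractionParams(d1=0.5, p2=0.1, d2=0.2, k=1)
        h = 1e-5
        for t in (0.2, 0.5, 0.9):
            sim = simulate_es(p, step_schedule, [t - h, t + h], method="ode")
            l2 = sim.series("poi")[1]
            fd = (l2[1] - l2[0]) / (2 * h)
            assert gain_rate(p, t, "exact") == pytest.approx(fd, abs=1e-4)

    def test_loss_rate_constant_when_source_vanishes(self):
        p = ESFractionParams(d1=0.7, p2=0.3 - 1e-12, d2=0.3, k=1)
        for t in (1.1, 1.5, 2.5):
            assert loss_rate(p, t, "exact") == pytest.approx(0.3, abs=1e-9)

    def test_loss_rate_matches_finite_difference(self, step_schedule):
        p = ESFractionParams(d1=0.5, p2=0.1, d2=0.2, k=1)
        h = 1e-5
        t = 1.1
        sim = simulate_es(p, step_schedule, [t - h, t, t + h], method="ode")
        l2 = sim.series("poi")[1]
        fd = -(l2[2] - l2[0]) / (2 * h) / l2[1]
        assert loss_rate(p, t, "exact") == pytest.approx(fd, abs=1e-4)

    def test_linear_loss_rate_limit_for_nondividing_poi(self):
        # p2=0, k=1: the linear loss rate just after the pulse is -1,
        # i.e. the pool keeps gaining labelled DNA
        p = ESFractionParams(d1=0.5, p2=0.0, d2=0.2, k=1)
        assert loss_rate(p, 1.0, "linear") == pytest.approx(
            initial_loss_rate(p), abs=1e-12
        )
        assert round(initial_loss_rate(p), 2) == -1.0

    @pytest.mark.parametrize("case", REFERENCE_CASES, ids=str)
    def test_post_pulse_loss_sign_matches_dynamics(self, case, step_schedule):
        """The sign of d*(1+eps) predicts gain vs loss right after the pulse."""
        p = _params(case)
        h = 1e-4
        sim = simulate_es(p, step_schedule, [1.0 + h, 1.0 + 3 * h], method="ode")
        l2 = sim.series("poi")[1]
        slope = l2[1] - l2[0]
        assert (initial_loss_rate(p) < 0) == (slope > 0)


class TestGainRateBound:
    def test_maximum_below_turnover_rate(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            p = random_es_params(rng, lo=0.05, hi=3.0)
            t_c, p_max = gain_rate_bound(p)
            assert p_max < p.d2

    def test_refined_maximum_beats_neighbours(self):
        p = ESFractionParams(d1=0.5, p2=0.1, d2=0.2, k=1)
        t_c, p_max = gain_rate_bound(p)
        assert p_max >= gain_rate(p, max(t_c - 0.01, 0.0), "exact")
        assert p_max >= gain_rate(p, t_c + 0.01, "exact")

    def test_no_source_limit_peaks_at_start(self):
        p = ESFractionParams(d1=0.5, p2=0.3 - 1e-9, d2=0.3, k=1)
        t_c, p_max = gain_rate_bound(p)
        assert t_c == 0.0
        assert p_max == pytest.approx(0.3, abs=1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        d1=st.floats(0.05, 3.0),
        d2=st.floats(0.05, 3.0),
        frac=st.floats(0.0, 0.99),
        k=st.sampled_from([1, 2]),
    )
    def test_gain_rate_always_below_turnover_property(self, d1, d2, frac, k):
        """p*(t) < d2 for all t whenever p2 < d2."""
        p = ESFractionParams(d1=d1, p2=frac * d2, d2=d2, k=k)
        t = np.linspace(0.0, 5.0, 201)
        assert np.all(gain_rate(p, t, "exact") < d2)


class TestPeakClassification:
    def test_nondividing_poi_peaks_late(self):
        v = classify_peak(ESFractionParams(d1=0.5, p2=0.0, d2=0.2, k=1))
        assert v.timing == "after_end"

    def test_dividing_poi_outpacing_precursor_peaks_at_end(self):
        v = classify_peak(ESFractionParams(d1=0.2, p2=0.3, d2=0.5, k=1))
        assert v.timing == "at_end"

    def test_division_linked_influx_peaks_at_end(self):
        v = classify_peak(ESFractionParams(d1=0.2, p2=0.1, d2=0.5, k=2))
        assert v.timing == "at_end"

    def test_tie_reported_as_boundary(self):
        v = classify_peak(ESFractionParams(d1=0.25, p2=0.25, d2=0.5, k=1))
        assert v.timing == "boundary"

    def test_at_end_verdict_is_exact(self):
        """Whenever p*(0) > d1 the simulated curve peaks exactly at tau."""
        rng = np.random.default_rng(21)
        grid = np.round(np.arange(0.0, 6.0 + 1e-9, 1e-3), 10)
        checked = 0
        while checked < 60:
            p = random_es_params(rng)
            if classify_peak(p).timing != "at_end":
                continue
            checked += 1
            l2 = es_closed_form(p, grid)[1]
            assert abs(grid[np.argmax(l2)] - 1.0) <= 2e-3

    def test_nondividing_k1_late_peak_is_exact(self):
        rng = np.random.default_rng(22)
        grid = np.round(np.arange(0.0, 8.0 + 1e-9, 1e-3), 10)
        for _ in range(30):
            d1, d2 = rng.uniform(0.05, 0.95, size=2)
            p = ESFractionParams(d1=d1, p2=0.0, d2=d2, k=1)
            assert classify_peak(p).timing == "after_end"
            l2 = es_closed_form(p, grid)[1]
            assert grid[np.argmax(l2)] > 1.0


class TestIdentifiabilityTransforms:
    def test_kh_map_case_study_values(self):
        m = kh_map(ESFractionParams(d1=0.001, p2=0.04, d2=0.28, k=1))
        assert m.alpha == pytest.approx(0.86, abs=0.005)
        assert m.valid_kh
        assert m.delta_bar == 0.04

    def test_kh_map_no_source_gives_pure_fast_pool(self):
        m = kh_map(ESFractionParams(d1=0.5, p2=0.3 - 1e-12, d2=0.3, k=1))
        assert m.alpha == pytest.approx(0.0, abs=1e-9)

    def test_faster_precursor_is_not_heterogeneous(self):
        m = kh_map(ESFractionParams(d1=0.5, p2=0.1, d2=0.2, k=1))
        assert m.alpha == pytest.approx(-1 / 3)
        assert not m.valid_kh

    def test_kh_map_identity_is_exact(self, step_schedule):
        rng = np.random.default_rng(13)
        t = np.linspace(0.0, 3.0, 31)
        for _ in range(20):
            p = random_es_params(rng, k=1)
            if abs(p.d1 - p.d2) < 1e-3:
                continue
            kh = kh_map(p).as_kh_params()
            khv = simulate_kh(kh, step_schedule, t).series("poi")[1]
            esv = es_closed_form(p, t)[1]
            np.testing.assert_allclose(khv, esv, atol=1e-12)

    def test_kh_map_degenerate_rates_rejected(self):
        with pytest.raises(ParameterError):
            kh_map(ESFractionParams(d1=0.3, p2=0.1, d2=0.3, k=1))

    @pytest.mark.parametrize(
        "p21, d2, expected",
        [(0.25, 0.5, 0.0), (0.5 - 1e-9, 0.5, pytest.approx(0.5, abs=1e-8)),
         (0.1, 0.5, None)],
    )
    def test_k_transform_values(self, p21, d2, expected):
        result = k_transform(p21, d2)
        if expected is None:
            assert result is None
        else:
            assert result == expected

    def test_k_transform_preserves_the_curve(self, step_schedule):
        """(k=1, p21) and (k=2, 2 p21 - d2) are indistinguishable."""
        rng = np.random.default_rng(17)
        t = np.linspace(0.0, 3.0, 61)
        for _ in range(25):
            d1 = rng.uniform(0.05, 2.0)
            d2 = rng.uniform(0.05, 2.0)
            p21 = rng.uniform(0.5, 0.999) * d2  # feasible branch
            p22 = k_transform(p21, d2)
            assert p22 is not None
            c1 = es_closed_form(ESFractionParams(d1, p21, d2, 1), t)[1]
            c2 = es_closed_form(ESFractionParams(d1, p22, d2, 2), t)[1]
            np.testing.assert_allclose(c1, c2, atol=1e-8)


class TestIntersectionCriterion:
    GRID = np.round(np.arange(0.0, 8.0 + 1e-9, 2e-3), 10)

    def test_nondividing_chain_peak_on_crossing(self, step_schedule):
        sim = simulate_es(
            ESFractionParams(d1=0.5, p2=0.0, d2=0.2, k=1), step_schedule, self.GRID
        )
        verdict, t_peak, _ = intersection_criterion(sim)
        assert verdict
        assert t_peak > 1.0

    def test_dividing_poi_peak_off_crossing(self, step_schedule):
        sim = simulate_es(
            ESFractionParams(d1=0.5, p2=0.12, d2=0.2, k=1), step_schedule, self.GRID
        )
        verdict, _, reason = intersection_criterion(sim)
        assert not verdict

    def test_peak_during_labelling_returns_false(self, step_schedule):
        sim = simulate_es(
            ESFractionParams(d1=0.2, p2=0.3, d2=0.5, k=1), step_schedule, self.GRID
        )
        verdict, _, reason = intersection_criterion(sim)
        assert not verdict
        assert "before" in reason or "at" in reason


class TestMaintenance:
    def test_source_dominated_pool(self):
        m = maintenance_summary(ESFractionParams(d1=0.3, p2=0.12, d2=0.4, k=1))
        assert m.division_fraction == pytest.approx(0.30)
        assert m.source_maintained
        assert not m.self_renewal_robust

    def test_fully_self_renewing_pool(self):
        m = maintenance_summary(ESFractionParams(d1=0.3, p2=0.4 - 1e-12, d2=0.4, k=1))
        assert m.division_fraction == pytest.approx(1.0)
        assert m.self_renewal_robust

    def test_robustness_threshold(self):
        m = maintenance_summary(ESFractionParams(d1=0.3, p2=0.32, d2=0.4, k=1))
        assert m.self_renewal_robust  # p2 = 0.8 d2 >= 3 d2/4


class TestLifespanFoldError:
    def test_fast_precursor_is_safe(self):
        # with a fully labelled precursor the only residual factor is the
        # saturation of the curve itself, exp(d2) -- far below the danger
        # threshold of 2
        fe = lifespan_fold_error(50.0, 0.2, p2=0.0, k=1)
        assert fe == pytest.approx(math.exp(0.2), abs=0.01)
        assert fe < 1.5

    def test_negligible_source_is_safe(self):
        # p2 -> d2: the end-of-labelling gain rate is d2 exp(-d2) exactly
        fe = lifespan_fold_error(0.5, 0.3, p2=0.3 - 1e-9, k=1)
        assert fe == pytest.approx(math.exp(0.3), abs=1e-6)
        assert fe < 1.5

    def test_memory_t_cell_regime_is_dangerous(self):
        # slow precursor feeding a faster non-dividing pool
        assert lifespan_fold_error(0.025, 0.3, p2=0.0, k=1) > 2.0

    def test_fold_error_at_least_one(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            p = random_es_params(rng, lo=0.05, hi=3.0)
            fe = lifespan_fold_error(p.d1, p.d2, p.p2, p.k)
            assert fe >= 1.0 or math.isinf(fe)


def test_rate_summary_two_decimal_presentation():
    s = rate_summary(ESFractionParams(d1=0.5, p2=0.1, d2=0.2, k=1))
    assert s.rounded() == {"p_star_0": 0.10, "p_star_1": 0.13, "d_star_post": -0.20}
    assert s.p_star_max < 0.2
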