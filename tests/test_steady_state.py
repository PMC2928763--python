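"""Fixed-point finding, critical values and multiplicity conditions."""

import math

import numpy as np
import pytest

from tbpkinetics import (
    critical_k0,
    critical_k3,
    critical_k5,
    find_steady_states,
    nondimensionalize,
    predicted_multiplicity,
    steady_state_function,
)
from tbpkinetics.steady_state import bound_tbp, high_state

from conftest import draw_parameters


def quadratic_roots(p):
    """Independent closed-form roots for k6=2, k0=0.

    In t = T/D0 units the positive fixed points solve
    (1+K7^2) t^2 + (2K*K7^2 - K5) t + K7^2 K^2 = 0.
    """
    dp = nondimensionalize(p)
    K, K5, K7 = dp.K, dp.K5, dp.K7
    a, b, c = 1 + K7**2, 2 * K * K7**2 - K5, K7**2 * K**2
    disc = b * b - 4 * a * c
    if disc < 0:
        return []
    r = sorted([(-b - math.sqrt(disc)) / (2 * a), (-b + math.sqrt(disc)) / (2 * a)])
    return [t * p.D0 for t in r if t > 0]


class TestSteadyStateFunction:
    def test_zero_is_root_without_basal(self, table2_k0zero):
        assert steady_state_function(0.0, table2_k0zero) == 0.0

    def test_basal_rate_makes_origin_negative(self, table2):
        expected = -table2.k0 * table2.k7 ** 2
        assert steady_state_function(0.0, table2) == pytest.approx(expected, rel=1e-12, abs=0)

    def test_two_sign_changes_without_basal(self, table2_k0zero):
        grid = np.logspace(-16, -6, 100_000)
        vals = steady_state_function(grid, table2_k0zero)
        assert int(np.sum(np.sign(vals[:-1]) != np.sign(vals[1:]))) == 2


class TestFindSteadyStates:
    def test_three_states_match_closed_form(self, table2_k0zero):
        recs = find_steady_states(table2_k0zero, classify_stability=False)
        assert [r.label for r in recs] == ["zero", "low", "high"]
        exact = quadratic_roots(table2_k0zero)
        assert recs[1].T == pytest.approx(exact[0], rel=1e-9, abs=0)
        assert recs[2].T == pytest.approx(exact[1], rel=1e-9, abs=0)

    def test_records_satisfy_dimer_and_binding_relations(self, table2_k0zero):
        p = table2_k0zero
        for rec in find_steady_states(p, classify_stability=False):
            assert rec.T2 == pytest.approx((p.k1 / p.k2) * rec.T**2, rel=1e-12, abs=0)
            assert rec.TD == pytest.approx(float(bound_tbp(rec.T, p)), rel=1e-12, abs=0)
            assert abs(steady_state_function(rec.T, p)) <= 1e-8 * p.k5 * p.k7**2

    def test_basal_rate_leaves_single_state_near_high(self, table2):
        recs = find_steady_states(table2, classify_stability=False)
        assert len(recs) == 1
        high_total = find_steady_states(table2.replace(k0=0.0),
                                        classify_stability=False)[-1].total
        assert recs[0].total == pytest.approx(high_total, rel=0.05, abs=0)

    def test_weak_binding_leaves_only_zero_state(self, table2_k0zero):
        recs = find_steady_states(table2_k0zero.replace(k3=5e4),
                                  classify_stability=False)
        assert len(recs) == 1 and recs[0].T == 0.0

    def test_roots_invariant_to_dimerization_constants(self, table2_k0zero):
        p = table2_k0zero
        alt = p.replace(k1=3.3e6, k2=2e-2)
        recs = find_steady_states(p, classify_stability=False)
        recs_alt = find_steady_states(alt, classify_stability=False)
        assert len(recs) == len(recs_alt)
        for a, b in zip(recs, recs_alt):
            assert b.T == pytest.approx(a.T, rel=1e-9, abs=1e-30)
            assert b.TD == pytest.approx(a.TD, rel=1e-9, abs=1e-30)
            # totals shift by exactly the dimer-pool difference
            shift = 2 * (alt.k1 / alt.k2 - p.k1 / p.k2) * a.T**2
            assert b.total - a.total == pytest.approx(shift, rel=1e-9, abs=1e-30)

    def test_no_root_missed_against_dense_sign_scan(self):
        rng = np.random.default_rng(42)
        grid = np.logspace(-16, -3, 100_000)
        for _ in range(50):
            p = draw_parameters(rng, k0_zero=bool(rng.integers(2)))
            vals = steady_state_function(grid, p)
            sign_flip = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
            roots = [r.T for r in find_steady_states(p, classify_stability=False)
                     if r.T > 0]
            for i in sign_flip:
                a, b = grid[i], grid[i + 1]
                assert any(a * (1 - 1e-6) <= r <= b * (1 + 1e-6) for r in roots), \
                    f"missed root in [{a:g}, {b:g}]"


class TestCriticalValues:
    def test_branches_coalesce_at_the_fold(self, table2_k0zero):
        k3c = critical_k3(table2_k0zero).value
        recs = find_steady_states(table2_k0zero.replace(k3=k3c * (1 + 1e-7)),
                                  classify_stability=False)
        pos = [r for r in recs if r.T > 0]
        totals = sorted(r.total for r in pos)
        if len(pos) == 1:  # merged into one multiplicity-2 record
            assert pos[0].multiplicity == 2
        else:
            assert (totals[1] - totals[0]) / totals[1] < 1e-3

    def test_closed_form_matches_numeric_fold(self, table2_k0zero):
        p = table2_k0zero
        assert critical_k3(p, method="numeric_scan").value == pytest.approx(
            critical_k3(p).value, rel=1e-4, abs=0)
        assert critical_k5(p, method="numeric_scan").value == pytest.approx(
            critical_k5(p).value, rel=1e-4, abs=0)

    def test_closed_form_agrees_with_tangency_on_random_draws(self):
        # oracle: solve f=0 and df/dT=0 simultaneously by scanning the
        # discriminant-free formulation numerically
        rng = np.random.default_rng(11)
        for _ in range(10):
            p = draw_parameters(rng, k6=2.0, k0_zero=True)
            k5c = critical_k5(p).value
            below = find_steady_states(p.replace(k5=k5c * 0.995),
                                       classify_stability=False)
            above = find_steady_states(p.replace(k5=k5c * 1.005),
                                       classify_stability=False)
            assert sum(r.T > 0 for r in below) == 0
            assert sum(r.T > 0 for r in above) == 2

    def test_half_saturation_limit(self, table2_k0zero):
        small = critical_k5(table2_k0zero.replace(k7=table2_k0zero.k7 * 1e-6)).value
        assert small < 1e-5 * critical_k5(table2_k0zero).value

    def test_degenerate_synthesis_rejected(self, table2_k0zero):
        with pytest.raises(ZeroDivisionError):
            critical_k3(table2_k0zero.replace(k5=0.0))

    def test_basal_threshold_stable_under_grid_refinement(self, table2_k0zero):
        coarse = critical_k0(table2_k0zero, n_grid=4000).value
        fine = critical_k0(table2_k0zero, n_grid=8000).value
        assert fine == pytest.approx(coarse, rel=1e-3, abs=0)
        recs_below = find_steady_states(table2_k0zero.replace(k0=coarse * 0.9),
                                        classify_stability=False)
        recs_above = find_steady_states(table2_k0zero.replace(k0=coarse * 1.1),
                                        classify_stability=False)
        assert len(recs_below) == 3
        assert len(recs_above) == 1


class TestPredictedMultiplicity:
    @pytest.mark.parametrize("k6,k0_zero", [(2.0, True), (2.0, False),
                                            (1.0, True), (1.0, False)])
    def test_matches_computed_root_counts(self, k6, k0_zero):
        rng = np.random.default_rng(int(k6 * 10) + k0_zero)
        for _ in range(25):
            p = draw_parameters(rng, k6=k6, k0_zero=k0_zero)
            dp = nondimensionalize(p)
            k0c = None
            if k6 == 2.0 and not k0_zero:
                cv = critical_k0(p)
                if cv.value is None:
                    continue  # no fold in (0, k5]: prediction undefined
                k0c = cv.value / (p.k8 * p.D0)
            predicted = predicted_multiplicity(dp, k6, k0_zero, k0c)
            # widened search window: the prediction covers all positive T,
            # and extreme draws push the low root below 1e-16 M
            computed = sum(r.multiplicity for r in
                           find_steady_states(p, classify_stability=False,
                                              search_range=(1e-30, 1e-1),
                                              n_grid=6000)
                           if r.T > 0)
            assert predicted == computed

    def test_table2_point_is_multistable(self, table2_k0zero):
        dp = nondimensionalize(table2_k0zero)
        assert predicted_multiplicity(dp, 2.0, True) == 2  # low + high

    def test_unsupported_hill_exponent_signalled(self, table2):
        with pytest.raises(NotImplementedError):
            predicted_multiplicity(nondimensionalize(table2), 1.5, True)


def test_high_state_helper_returns_largest_total(table2_k0zero):
    recs = find_steady_states(table2_k0zero, classify_stability=False)
    assert high_state(recs).label == "high"
    only_zero = find_steady_states(table2_k0zero.replace(k3=5e4),
                                   classify_stability=False)
    assert high_state(only_zero) is None
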