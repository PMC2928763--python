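"""Stiff integration, basins of attraction, the slow manifold and buffering."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tbpkinetics import (
    SystemState,
    compare_dimer_effect,
    find_steady_states,
    integrate,
    phase_plane,
    response_time,
    rhs,
    slow_manifold_ratio,
)
from tbpkinetics.steady_state import high_state


class TestIntegrate:
    def test_origin_stays_at_origin_without_basal(self, table2_k0zero):
        s0 = SystemState(0.0, 0.0, 0.0, table2_k0zero.D0)
        traj = integrate(table2_k0zero, s0, 10.0 / table2_k0zero.k8)
        assert np.max(np.abs(traj.y)) == 0.0

    def test_near_high_state_relaxes_back(self, table2_k0zero):
        hs = high_state(find_steady_states(table2_k0zero, classify_stability=False))
        s0 = SystemState.from_reduced(1.05 * hs.T, 1.05 * hs.T2, 1.05 * hs.TD,
                                      p=table2_k0zero)
        traj = integrate(table2_k0zero, s0, 100.0 / table2_k0zero.k8)
        ref = np.array([hs.T, hs.T2, hs.TD])
        assert np.max(np.abs(traj.y[:, -1] - ref) / ref) < 1e-3

    def test_full_system_conserves_sites_and_matches_reduced(self, table2_k0zero):
        # independent 4-variable integration of the unreduced mass balances
        p = table2_k0zero
        y0 = [1e-9, 0.0, 0.0, p.D0]
        sol = solve_ivp(
            lambda t, y: rhs(SystemState(*np.clip(y, 0, None)), p),
            (0.0, 20.0 / p.k8), y0, method="LSODA", rtol=1e-8, atol=1e-20)
        assert sol.success
        drift = np.abs(sol.y[2] + sol.y[3] - p.D0)
        assert np.max(drift) <= 1e-6 * p.D0
        traj = integrate(p, SystemState(1e-9, 0.0, 0.0, p.D0), 20.0 / p.k8)
        assert traj.T[-1] == pytest.approx(sol.y[0][-1], rel=1e-4, abs=0)

    def test_tolerance_refinement_converges(self, table2_k0zero):
        p = table2_k0zero
        s0 = SystemState(1e-9, 0.0, 0.0, p.D0)
        a = integrate(p, s0, 50.0 / p.k8, rtol=1e-8).y[:, -1]
        b = integrate(p, s0, 50.0 / p.k8, rtol=4e-9).y[:, -1]
        assert np.max(np.abs(a - b) / np.abs(a)) < 10 * 1e-8 * 100

    def test_nonpositive_horizon_rejected(self, table2):
        with pytest.raises(ValueError):
            integrate(table2, SystemState(0, 0, 0, table2.D0), 0.0)


class TestPhasePlane:
    def test_basins_split_around_the_saddle(self, table2_k0zero):
        p = table2_k0zero
        inits = [SystemState.from_reduced(t0, 0.0, 0.0, p=p)
                 for t0 in (1e-11, 1e-7)]
        trajs, summary = phase_plane(p, inits)
        assert trajs[0].attractor == "zero"
        assert trajs[1].attractor == "high"
        assert summary["largest_total_to_zero"] == pytest.approx(1e-11, rel=1e-9, abs=0)
        assert summary["smallest_total_to_high"] == pytest.approx(1e-7, rel=1e-9, abs=0)

    def test_saddle_initial_condition_lingers(self, table2_k0zero):
        p = table2_k0zero
        low = find_steady_states(p, classify_stability=False)[1]
        traj = integrate(p, low.state(), 1.0 / p.k8)
        ref = low.state().reduced()
        assert np.max(np.abs(traj.y[:, -1] - ref) / ref) < 1e-3


class TestSlowManifold:
    def test_late_time_ratio_equals_binding_dissociation_constant(self, table2_k0zero):
        p = table2_k0zero
        traj = integrate(p, SystemState.from_reduced(1e-8, 0.0, 0.0, p=p),
                         50.0 / p.k8)
        _, med = slow_manifold_ratio(traj, p)
        assert med == pytest.approx(p.k4 / p.k3, rel=0.05, abs=0)

    def test_ratio_halves_when_binding_doubles(self, table2_k0zero):
        p = table2_k0zero.replace(k3=2 * table2_k0zero.k3)
        traj = integrate(p, SystemState.from_reduced(1e-8, 0.0, 0.0, p=p),
                         50.0 / p.k8)
        _, med = slow_manifold_ratio(traj, p)
        assert med == pytest.approx(0.5 * table2_k0zero.k4 / table2_k0zero.k3,
                                    rel=0.05, abs=0)

    def test_early_transient_excluded(self, table2_k0zero):
        # started off-manifold (TD = 0) the pointwise ratio is wildly off at
        # first; the reported median must ignore that segment
        p = table2_k0zero
        # dense sampling so the sub-1/k4 binding transient is resolved
        traj = integrate(p, SystemState.from_reduced(1e-8, 0.0, 0.0, p=p),
                         50.0 / p.k8, n_points=20000)
        ratio, med = slow_manifold_ratio(traj, p)
        early = ratio[(traj.t < 1.0 / p.k4) & np.isfinite(ratio)]
        assert np.nanmax(early) > 2 * med
        short = integrate(p, SystemState.from_reduced(1e-8, 0.0, 0.0, p=p),
                          1.0 / p.k4)
        with pytest.raises(ValueError):
            slow_manifold_ratio(short, p)


class TestResponseTime:
    def test_no_perturbation_is_instant(self, table2):
        assert response_time(table2, perturbation=0.0) == 0.0

    def test_shallower_recovery_is_faster(self, table2):
        deep = response_time(table2, recovery=0.99)
        shallow = response_time(table2, recovery=0.95)
        assert 0 < shallow <= deep

    def test_monostable_zero_rejected(self, table2_k0zero):
        with pytest.raises(ValueError):
            response_time(table2_k0zero.replace(k3=5e4))


class TestDimerEffect:
    def test_dimer_free_input_gives_unit_ratio(self, table2):
        res = compare_dimer_effect(table2.replace(k1=0.0))
        assert res.ratio == 1.0

    def test_shared_high_state_totals_differ_by_dimer_pool(self, table2):
        p = table2
        hs = high_state(find_steady_states(p, classify_stability=False))
        hs0 = high_state(find_steady_states(p.replace(k1=0.0),
                                            classify_stability=False))
        assert hs0.T == pytest.approx(hs.T, rel=1e-9, abs=0)
        assert hs0.TD == pytest.approx(hs.TD, rel=1e-9, abs=0)
        assert hs.total - hs0.total == pytest.approx(
            2 * (p.k1 / p.k2) * hs.T**2, rel=1e-9, abs=0)

    def test_mammalian_conditions_dimer_barely_matters(self, table2):
        res = compare_dimer_effect(table2, "mammalian")
        assert 0.8 <= res.ratio <= 1.25

    def test_yeast_conditions_dimer_speeds_recovery(self):
        from tbpkinetics.scenarios import preset

        res = compare_dimer_effect(preset("yeast").params, "yeast")
        assert res.ratio < 0.5
        assert res.dimer_to_bound_ratio > 1.0

    def test_monostable_variant_named_in_error(self, table2_k0zero):
        with pytest.raises(ValueError, match="with dimer"):
            compare_dimer_effect(table2_k0zero.replace(k3=5e4))
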