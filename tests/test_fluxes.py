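"""Flux model: rate law, linear operator, steady states, conservation."""

import numpy as np
import pytest

from nodusim import (
    AuxinState,
    CarrierLayout,
    ModelParams,
    SimulationError,
    build_rate_operator,
    cell_dynamics_rate,
    generate_grid_tissue,
    generate_two_cell_tissue,
    simulate,
    steady_state_direct,
    total_auxin,
)

from conftest import random_grid_tissue, random_layout, random_params


def brute_force_rate(state, tissue, layout, params):
    """Naive per-interface re-derivation of the flux law, used as a third
    independent route alongside cell_dynamics_rate and the operator."""
    order = {c.cell_id: k for k, c in enumerate(tissue.cells)}
    a = state.concentrations
    rate = np.zeros(len(a))
    for m, itf in enumerate(tissue.interfaces):
        i, j = order[itf.cell_a], order[itf.cell_b]
        e_i = params.d_wall + params.p_pin * layout.pin[m, 0]
        e_j = params.d_wall + params.p_pin * layout.pin[m, 1]
        i_i = params.i_base + params.p_aux * layout.aux[m, 0]
        i_j = params.i_base + params.p_aux * layout.aux[m, 1]
        j_ij = (e_i * i_j * a[i] - e_j * i_i * a[j]) / (i_i + i_j)
        rate[i] -= itf.wall_length * j_ij / tissue.cells[i].area
        rate[j] += itf.wall_length * j_ij / tissue.cells[j].area
    for k, c in enumerate(tissue.cells):
        rate[k] += params.sigma - params.delta * a[k]
        if c.has_frankia:
            rate[k] += params.s_frankia
    return rate


class TestRateLaw:
    def test_pure_decay_without_transport_or_sources(self, grid3):
        params = ModelParams(
            d_wall=0.0, p_pin=0.0, p_aux=0.0, sigma=0.0, s_frankia=0.0, delta=0.7
        )
        layout = CarrierLayout.zeros(grid3)
        a = np.linspace(1.0, 2.0, 9)
        rate = cell_dynamics_rate(AuxinState(a), grid3, layout, params)
        np.testing.assert_allclose(rate, -0.7 * a, rtol=1e-12)

    def test_uniform_state_has_zero_passive_transport(self, grid3):
        params = ModelParams(d_wall=2.0, p_pin=0.0, p_aux=0.0, sigma=0.0,
                             s_frankia=0.0, delta=0.5)
        layout = CarrierLayout.zeros(grid3)
        a = np.full(9, 3.0)
        rate = cell_dynamics_rate(AuxinState(a), grid3, layout, params)
        np.testing.assert_allclose(rate, -0.5 * a, rtol=1e-12)

    def test_two_cell_pin_moves_mass_from_cell1_to_cell2(self):
        """Hand expansion: with PIN only on the cell-1 side and equal influx,
        J(1->2) = [(d+p) a1 - d a2] / 2 per unit wall."""
        t = generate_two_cell_tissue(area_a=2.0, area_b=3.0, wall_length=1.5)
        layout = CarrierLayout(aux=np.zeros((1, 2)), pin=np.array([[1.0, 0.0]]))
        params = ModelParams(d_wall=1.0, p_pin=4.0, p_aux=0.0, i_base=1.0,
                             sigma=0.0, s_frankia=0.0, delta=1.0)
        a = np.array([2.0, 1.0])
        rate = cell_dynamics_rate(AuxinState(a), t, layout, params)
        j12 = ((1.0 + 4.0) * 2.0 - 1.0 * 1.0) / 2.0  # = 4.5 per unit wall
        expected = np.array(
            [-1.5 * j12 / 2.0 - 1.0 * 2.0, +1.5 * j12 / 3.0 - 1.0 * 1.0]
        )
        np.testing.assert_allclose(rate, expected, rtol=1e-12)
        assert rate[0] < 0  # cell 1 loses
        assert rate[1] > 0  # cell 2 gains

    def test_mismatched_state_length_rejected(self, grid3):
        layout = CarrierLayout.zeros(grid3)
        with pytest.raises(SimulationError):
            cell_dynamics_rate(AuxinState(np.ones(4)), grid3, layout, ModelParams())


class TestRateOperator:
    @pytest.mark.parametrize("seed", range(5))
    def test_operator_matches_rate_on_random_states(self, seed):
        rng = np.random.default_rng(seed)
        t = random_grid_tissue(rng, 4, 4)
        layout = random_layout(rng, t)
        params = random_params(rng)
        M, c = build_rate_operator(t, layout, params)
        for _ in range(10):
            a = rng.uniform(0.0, 5.0, size=16)
            np.testing.assert_allclose(
                M @ a + c,
                cell_dynamics_rate(AuxinState(a), t, layout, params),
                rtol=1e-12,
                atol=1e-12,
            )

    def test_no_transport_reduces_to_decay_identity(self, grid3):
        params = ModelParams(d_wall=0.0, p_pin=0.0, p_aux=0.0, delta=0.9,
                             sigma=0.0, s_frankia=0.0)
        M, _ = build_rate_operator(grid3, CarrierLayout.zeros(grid3), params)
        np.testing.assert_allclose(M.toarray(), -0.9 * np.eye(9), atol=1e-15)

    def test_transport_conserves_area_weighted_mass(self):
        """With delta = 0 the area-weighted column sums of M vanish."""
        rng = np.random.default_rng(42)
        t = random_grid_tissue(rng, 5, 3)
        layout = random_layout(rng, t)
        params = random_params(rng).with_overrides(delta=0.0)
        M, _ = build_rate_operator(t, layout, params)
        colsums = t.areas() @ M.toarray()
        np.testing.assert_allclose(colsums, 0.0, atol=1e-12)


class TestSteadyStates:
    def test_uniform_production_decay_fixed_point(self, grid3):
        params = ModelParams(p_pin=0.0, p_aux=0.0, sigma=0.6, delta=0.3,
                             s_frankia=0.0, a0=5.0, steady_tol=1e-12)
        res = simulate(grid3, CarrierLayout.zeros(grid3), params)
        assert res.converged
        np.testing.assert_allclose(res.final_state.concentrations, 2.0, rtol=1e-8)
        direct = steady_state_direct(grid3, CarrierLayout.zeros(grid3), params)
        np.testing.assert_allclose(direct.concentrations, 2.0, rtol=1e-12)

    def test_total_auxin_decays_exponentially_without_sources(self, grid3):
        rng = np.random.default_rng(0)
        layout = random_layout(rng, grid3)
        params = ModelParams(sigma=0.0, s_frankia=0.0, delta=0.8, a0=2.0,
                             dt=0.001, t_max=1.0, steady_tol=1e-300)
        res = simulate(grid3, layout, params)
        m0 = 9 * 2.0
        expected = m0 * np.exp(-0.8 * res.final_state.time)
        got = total_auxin(res.final_state, grid3)
        # first-order integrator: tolerance reflects O(dt) bias
        np.testing.assert_allclose(got, expected, rtol=1e-3)

    def test_two_cell_pin_steady_state_matches_symbolic_solution(self):
        """Steady state of the 2-cell PIN system vs an independent sympy solve."""
        import sympy as sp

        a1, a2 = sp.symbols("a1 a2")
        d, p, i0, w, A1, A2, sig, dlt = sp.symbols(
            "d p i0 w A1 A2 sig dlt", positive=True
        )
        e1, e2 = d + p, d
        j12 = (e1 * i0 * a1 - e2 * i0 * a2) / (2 * i0)
        eq1 = sp.Eq(-w * j12 / A1 + sig - dlt * a1, 0)
        eq2 = sp.Eq(+w * j12 / A2 + sig - dlt * a2, 0)
        sol = sp.solve([eq1, eq2], [a1, a2], dict=True)[0]
        subs = {d: 1.0, p: 7.0, i0: 1.0, w: 1.5, A1: 2.0, A2: 1.0,
                sig: 0.4, dlt: 0.9}
        expected = np.array(
            [float(sol[a1].subs(subs)), float(sol[a2].subs(subs))]
        )

        t = generate_two_cell_tissue(area_a=2.0, area_b=1.0, wall_length=1.5)
        layout = CarrierLayout(aux=np.zeros((1, 2)), pin=np.array([[1.0, 0.0]]))
        params = ModelParams(d_wall=1.0, p_pin=7.0, p_aux=0.0, i_base=1.0,
                             sigma=0.4, delta=0.9, s_frankia=0.0,
                             steady_tol=1e-13)
        direct = steady_state_direct(t, layout, params)
        np.testing.assert_allclose(direct.concentrations, expected, rtol=1e-10)
        res = simulate(t, layout, params)
        assert res.converged
        np.testing.assert_allclose(res.final_state.concentrations, expected,
                                   rtol=1e-8)
        assert expected[1] > expected[0]  # PIN drains cell 1 into cell 2

    def test_direct_solve_requires_decay(self, grid3):
        params = ModelParams(delta=0.0)
        with pytest.raises(SimulationError, match="delta > 0"):
            steady_state_direct(grid3, CarrierLayout.zeros(grid3), params)

    @pytest.mark.parametrize("a0", [0.0, 5.0])
    def test_steady_state_independent_of_initial_level(self, a0):
        rng = np.random.default_rng(3)
        t = random_grid_tissue(rng, 3, 3)
        layout = random_layout(rng, t)
        params = random_params(rng).with_overrides(a0=a0, steady_tol=1e-12)
        res = simulate(t, layout, params)
        assert res.converged
        ref = steady_state_direct(t, layout, params)
        np.testing.assert_allclose(
            res.final_state.concentrations, ref.concentrations,
            rtol=1e-6, atol=1e-12,
        )


class TestStructuralProperties:
    def test_mirror_symmetric_system_has_mirror_symmetric_steady_state(self):
        """1x4 strip with infected ends: steady state symmetric under reflection."""
        t = generate_grid_tissue(
            4, 1, lambda r, c: "infected" if c in (0, 3) else "uninfected"
        )
        from nodusim import place_carriers_discaria

        layout = place_carriers_discaria(t)
        params = ModelParams(steady_tol=1e-13)
        a = steady_state_direct(t, layout, params).concentrations
        np.testing.assert_allclose(a, a[::-1], rtol=1e-10)

    def test_nonnegativity_preserved(self):
        rng = np.random.default_rng(9)
        t = random_grid_tissue(rng, 4, 4)
        layout = random_layout(rng, t)
        params = random_params(rng)
        res = simulate(t, layout, params)
        assert res.final_state.concentrations.min() >= 0.0

    def test_stability_guard_halves_oversized_dt(self, grid3):
        layout = CarrierLayout.zeros(grid3)
        params = ModelParams(dt=10.0, t_max=50.0, sigma=0.5, s_frankia=0.0,
                             steady_tol=1e-10)
        res = simulate(grid3, layout, params)
        assert res.converged
        np.testing.assert_allclose(
            res.final_state.concentrations, 0.5 / params.delta, rtol=1e-7
        )

    def test_pin_on_own_membrane_never_raises_own_steady_level(self):
        """Adding efflux carrier to cell 5's membrane cannot raise cell 5."""
        t = generate_grid_tissue(3, 3)
        params = ModelParams(sigma=0.3, s_frankia=0.0, delta=0.8)
        base = CarrierLayout.zeros(t)
        order = {c.cell_id: k for k, c in enumerate(t.cells)}
        a_before = steady_state_direct(t, base, params).concentrations
        for m, itf in enumerate(t.interfaces):
            if 5 in (itf.cell_a, itf.cell_b):
                side = 0 if itf.cell_a == 5 else 1
                layout = CarrierLayout.zeros(t)
                layout.pin[m, side] = 1.0
                a_after = steady_state_direct(t, layout, params).concentrations
                assert a_after[order[5]] <= a_before[order[5]] + 1e-12

    def test_aux_on_own_membrane_never_lowers_own_steady_level(self):
        t = generate_grid_tissue(3, 3)
        params = ModelParams(sigma=0.3, s_frankia=0.0, delta=0.8)
        base = CarrierLayout.zeros(t)
        order = {c.cell_id: k for k, c in enumerate(t.cells)}
        a_before = steady_state_direct(t, base, params).concentrations
        for m, itf in enumerate(t.interfaces):
            if 5 in (itf.cell_a, itf.cell_b):
                side = 0 if itf.cell_a == 5 else 1
                layout = CarrierLayout.zeros(t)
                layout.aux[m, side] = 1.0
                a_after = steady_state_direct(t, layout, params).concentrations
                assert a_after[order[5]] >= a_before[order[5]] - 1e-12

    def test_brute_force_rate_agrees_with_package_routes(self):
        rng = np.random.default_rng(17)
        t = random_grid_tissue(rng, 4, 3)
        layout = random_layout(rng, t)
        params = random_params(rng)
        a = rng.uniform(0, 3, size=12)
        r1 = cell_dynamics_rate(AuxinState(a), t, layout, params)
        M, c = build_rate_operator(t, layout, params)
        r3 = brute_force_rate(AuxinState(a), t, layout, params)
        np.testing.assert_allclose(r1, r3, rtol=1e-12)
        np.testing.assert_allclose(M @ a + c, r3, rtol=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(delta=-1.0)
        with pytest.raises(ValueError):
            ModelParams(i_base=0.0)
        with pytest.raises(ValueError):
            ModelParams(dt=-0.1)
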