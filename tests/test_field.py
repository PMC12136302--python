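"""Grid construction, nonlocal interaction, diffusion stencil and the
assembled right-hand side, each checked against brute-force oracles."""

import numpy as np
import pytest

from csdwave import (
    FieldState,
    RunConfig,
    build_grid,
    connectivity_kernel,
    firing_rate,
    interaction,
    interaction_matrix,
    laplacian,
    potassium_drive,
    rate_to_potassium,
    rhs,
    stimulus_profile,
)
from csdwave.field import StimulusParams


class TestGrid:
    def test_three_node_example(self):
        g = build_grid(1.0, 3)
        assert g.spacing == 1.0
        np.testing.assert_allclose(g.coords, [-1.0, 0.0, 1.0])

    def test_two_endpoints(self):
        assert build_grid(5.0, 2).spacing == 10.0

    @pytest.mark.parametrize("Lx,N", [(1.0, 3), (20.0, 201), (7.5, 16)])
    def test_endpoint_identity_and_spacing(self, Lx, N):
        g = build_grid(Lx, N)
        assert g.coords[0] == -Lx
        assert g.coords[-1] == pytest.approx(Lx, abs=1e-12)
        assert g.spacing * (N - 1) == pytest.approx(2 * Lx, abs=1e-12)
        assert np.all(np.diff(g.coords) > 0)

    def test_odd_grid_center_at_zero(self):
        g = build_grid(20.0, 201)
        assert g.coords[g.center_index] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(g.coords, -g.coords[::-1], atol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_grid(1.0, 1)
        with pytest.raises(ValueError):
            build_grid(0.0, 5)


class TestInteraction:
    def test_single_nonzero_node(self):
        g = build_grid(3.0, 13)
        rates = np.zeros(13)
        m0, s0 = 4, 0.7
        rates[m0] = s0
        out = interaction(rates, g)
        expected = g.spacing * connectivity_kernel(g.coords - g.coords[m0]) * s0
        np.testing.assert_allclose(out, expected, atol=1e-14)

    def test_uniform_rate_matches_kernel_mass(self):
        # interior response to uniform rate s equals s * integral of the
        # kernel = s * sqrt(pi)/2, once the domain dwarfs the kernel width
        g = build_grid(15.0, 301)
        s = 0.6
        out = interaction(np.full(301, s), g)
        interior = out[100:201]
        np.testing.assert_allclose(
            interior, s * np.sqrt(np.pi) / 2.0, rtol=1e-3
        )

    def test_mirror_symmetry_and_linearity(self, rng):
        g = build_grid(4.0, 21)
        r1 = rng.uniform(0, 1, 21)
        sym = 0.5 * (r1 + r1[::-1])
        out = interaction(sym, g)
        np.testing.assert_allclose(out, out[::-1], atol=1e-14)
        r2 = rng.uniform(0, 1, 21)
        a, b = 0.3, 1.7
        np.testing.assert_allclose(
            interaction(a * r1 + b * r2, g),
            a * interaction(r1, g) + b * interaction(r2, g),
            atol=1e-12,
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            interaction(np.zeros(5), build_grid(1.0, 3))


class TestLaplacian:
    def test_constant_and_linear_profiles(self):
        g = build_grid(2.0, 9)
        np.testing.assert_allclose(laplacian(np.full(9, 3.3), g), 0.0, atol=1e-12)
        lin = 0.7 * g.coords
        np.testing.assert_allclose(laplacian(lin, g)[1:-1], 0.0, atol=1e-12)

    def test_quadratic_profile_exact(self):
        g = build_grid(2.0, 17)
        out = laplacian(g.coords**2, g)
        np.testing.assert_allclose(out[1:-1], 2.0, atol=1e-10)

    def test_neumann_mass_conservation(self, rng):
        g = build_grid(5.0, 41)
        k = rng.uniform(0.0, 3.0, 41)
        total = laplacian(k, g).sum()
        assert abs(total) <= 1e-10 * np.abs(laplacian(k, g)).max()

    def test_too_few_nodes(self):
        with pytest.raises(ValueError):
            laplacian(np.zeros(2), build_grid(1.0, 2))


class TestStimulus:
    P = StimulusParams(amplitude=2.0, center=0.0, width=1.0, onset=1.0, duration=0.5)

    def test_zero_outside_window(self):
        g = build_grid(2.0, 11)
        assert np.all(stimulus_profile(g, 0.99, self.P) == 0)
        assert np.all(stimulus_profile(g, 1.5, self.P) == 0)  # half-open window

    def test_peak_and_symmetry(self):
        g = build_grid(2.0, 11)
        prof = stimulus_profile(g, 1.2, self.P)
        assert prof[g.center_index] == pytest.approx(self.P.amplitude)
        np.testing.assert_allclose(prof, prof[::-1], atol=1e-14)
        assert np.all(prof >= 0)


def _brute_force_rhs(state, t, params, grid):
    """Naive double-loop reference implementation of the field equations."""
    n = grid.n_nodes
    cp = params.coupling
    pr = params.production
    se = np.array([firing_rate(state.ve[j], state.k[j], params.transfer_e) for j in range(n)])
    si = np.array([firing_rate(state.vi[j], state.k[j], params.transfer_i) for j in range(n)])
    Se = np.zeros(n)
    Si = np.zeros(n)
    for j in range(n):
        for m in range(n):
            w = grid.spacing * connectivity_kernel(grid.coords[j] - grid.coords[m])
            Se[j] += w * se[m]
            Si[j] += w * si[m]
    lap = np.zeros(n)
    for j in range(1, n - 1):
        lap[j] = (state.k[j - 1] - 2 * state.k[j] + state.k[j + 1]) / grid.spacing**2
    lap[0] = (state.k[1] - state.k[0]) / grid.spacing**2
    lap[-1] = (state.k[-2] - state.k[-1]) / grid.spacing**2
    se_star, si_star = params.reference_rates()
    I = stimulus_profile(grid, t, params.stimulus)
    dve = np.zeros(n)
    dvi = np.zeros(n)
    dk = np.zeros(n)
    for j in range(n):
        gve = potassium_drive(state.ve[j], state.k[j], params.drive.beta_ve, params.drive.kv_star)
        gvi = potassium_drive(state.vi[j], state.k[j], params.drive.beta_vi, params.drive.kv_star)
        dve[j] = (-state.ve[j] + cp.c_ee * Se[j] - cp.c_ei * Si[j] + gve) / cp.tau
        dvi[j] = (-state.vi[j] + cp.c_ie * Se[j] - cp.c_ii * Si[j] + gvi) / cp.tau
        prod = cp.c1 * rate_to_potassium(se[j], se_star, pr.a, pr.b, pr.c) + cp.c2 * rate_to_potassium(si[j], si_star, pr.a, pr.b, pr.c)
        dk[j] = (cp.delta * lap[j] + prod + I[j]) / cp.tau
    return dve, dvi, dk


class TestRhs:
    def test_matches_brute_force_on_random_state(self, rng):
        cfg = RunConfig.reference().with_overrides(
            **{"grid.n_nodes": 11, "grid.half_length": 2.0}
        )
        grid = cfg.grid()
        params = cfg.model_parameters()
        state = FieldState(
            rng.normal(0, 0.5, 11), rng.normal(0, 0.5, 11), rng.uniform(0.0, 2.0, 11)
        )
        got = rhs(state, 0.2, params, grid)
        want = _brute_force_rhs(state, 0.2, params, grid)
        for g_, w_ in zip(got, want):
            np.testing.assert_allclose(g_, w_, atol=1e-12, rtol=0)

    def test_decoupled_fixed_point(self):
        """With couplings, production weights, diffusion and stimulus off,
        v = gv(k0) solves the voltage equations (bisection oracle)."""
        cfg = RunConfig.reference().with_overrides(
            **{
                "grid.n_nodes": 11,
                "grid.half_length": 2.0,
                "coupling.c_ee": 0.0,
                "coupling.c_ei": 0.0,
                "coupling.c_ie": 0.0,
                "coupling.c_ii": 0.0,
                "coupling.c1": 0.0,
                "coupling.c2": 0.0,
                "coupling.delta": 0.0,
                "stimulus.amplitude": 0.0,
            }
        )
        params = cfg.model_parameters()
        grid = cfg.grid()
        k0 = cfg.initial_k0
        # bisection on f(v) = -v + gv(v, k0): gv does not depend on v, so
        # the root is gv(k0); the oracle recovers it without assuming that
        lo, hi = -2.0, 2.0
        f = lambda v: -v + potassium_drive(v, k0, params.drive.beta_ve, params.drive.kv_star)
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if f(lo) * f(mid) <= 0:
                hi = mid
            else:
                lo = mid
        v_star = 0.5 * (lo + hi)
        state = FieldState(np.full(11, v_star), np.full(11, v_star), np.full(11, k0))
        dve, dvi, dk = rhs(state, 0.0, params, grid)
        np.testing.assert_allclose(dve, 0.0, atol=1e-9)
        np.testing.assert_allclose(dvi, 0.0, atol=1e-9)
        np.testing.assert_allclose(dk, 0.0, atol=1e-12)  # production off

    def test_uniform_state_gives_uniform_voltage_derivatives(self):
        cfg = RunConfig.reference().with_overrides(
            **{"grid.n_nodes": 21, "grid.half_length": 4.0, "stimulus.amplitude": 0.0}
        )
        grid = cfg.grid()
        params = cfg.model_parameters()
        state = FieldState(np.full(21, 0.1), np.full(21, 0.1), np.full(21, 0.3))
        dve, dvi, dk = rhs(state, 0.0, params, grid)
        # interactions see the truncated kernel near the edges; interior
        # nodes far from the boundary must agree
        np.testing.assert_allclose(dve[8:13], dve[10], rtol=1e-6)
        np.testing.assert_allclose(dvi[8:13], dvi[10], rtol=1e-6)

    def test_mirror_symmetric_state_gives_mirror_symmetric_rhs(self, rng):
        cfg = RunConfig.reference().with_overrides(
            **{"grid.n_nodes": 21, "grid.half_length": 4.0}
        )
        grid = cfg.grid()
        params = cfg.model_parameters()
        half = rng.uniform(0, 1, 11)
        sym = np.concatenate([half[:0:-1], half])
        state = FieldState(sym, 0.5 * sym, 0.3 + 0.1 * sym)
        out = rhs(state, 0.1, params, grid)  # stimulus centered -> symmetric
        for arr in out:
            np.testing.assert_allclose(arr, arr[::-1], atol=1e-12)

    def test_production_floor_bounds_dk(self):
        """dk >= (c1 + c2) a / tau wherever the stimulus is off: total K+
        can only grow."""
        cfg = RunConfig.reference().with_overrides(
            **{"grid.n_nodes": 21, "grid.half_length": 4.0, "coupling.delta": 0.0,
               "stimulus.amplitude": 0.0}
        )
        params = cfg.model_parameters()
        grid = cfg.grid()
        state = FieldState(np.zeros(21), np.zeros(21), np.full(21, 0.3))
        _, _, dk = rhs(state, 0.0, params, grid)
        cp, pr = params.coupling, params.production
        floor = (cp.c1 + cp.c2) * pr.a / cp.tau
        assert np.all(dk >= floor - 1e-15)
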