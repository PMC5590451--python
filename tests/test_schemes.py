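import numpy as np
import pytest
from scipy.linalg import expm

from nsfdpk import (
    DoseRegimen,
    Grid,
    PKParameters,
    bolus_solution,
    build_rate_matrix,
    equilibrium,
    infusion_solution,
    nsfd_coefficients,
    nsfd_integrate_bolus,
    nsfd_integrate_infusion,
    random_parameter_fixture,
    rk45_integrate,
    sfd_integrate,
)
from nsfdpk.schemes import nsfd_integrate_infusion_substitution, nsfd_step_matrix


class TestGrid:
    def test_nodes_and_horizon(self):
        g = Grid.from_N(4, 20.0)
        assert g.h == 5.0 and g.T == 20.0
        np.testing.assert_array_equal(g.nodes, [0, 5, 10, 15, 20])

    def test_exact_step_from_N(self):
        assert Grid.from_N(1024, 20.0).h == 20.0 / 1024

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            Grid(h=0.0, N=2)
        with pytest.raises(ValueError):
            Grid(h=1.0, N=0)
        with pytest.raises(ValueError):
            Grid.from_h(3.0, 20.0)  # horizon not a multiple of h


class TestSFD:
    def test_bolus_one_step_hand_values(self, subject1):
        traj = sfd_integrate(subject1, DoseRegimen.bolus(), Grid(h=10.0, N=2))
        assert traj.c[1] == pytest.approx(0.501, rel=1e-15)
        assert traj.p[1] == pytest.approx(0.405, rel=1e-15)

    def test_infusion_one_step_hand_values(self, subject1):
        traj = sfd_integrate(subject1, DoseRegimen.infusion(1.0), Grid(h=10.0, N=2))
        assert traj.c[1] == pytest.approx(10.0, rel=1e-15)
        assert traj.p[1] == 0.0

    def test_first_order_consistency(self, subject1):
        # halving h with N*h fixed roughly halves the endpoint error
        errs = []
        for N in (64, 128, 256):
            traj = sfd_integrate(subject1, DoseRegimen.bolus(), Grid.from_N(N, 20.0))
            c_exact, _ = bolus_solution(subject1, 20.0)
            errs.append(abs(traj.c[-1] - float(c_exact)))
        ratios = [a / b for a, b in zip(errs, errs[1:])]
        assert all(1.8 < r < 2.2 for r in ratios)


class TestNSFDCoefficients:
    def test_small_h_limits(self, subject1):
        # phi(h) = h + O(h^2), varphi(h) = 1 + O(h)
        for h in (1e-3, 1e-5, 1e-7):
            co = nsfd_coefficients(subject1, h)
            assert co.phi_denom == pytest.approx(h, rel=0.1 * h)
            assert co.phi_weight == pytest.approx(1.0, abs=0.1 * h)

    def test_repeated_root_confluent_limit(self):
        a = 0.02
        p = PKParameters(k10=a, k12=0.0, k21=a)
        co = nsfd_coefficients(p, 10.0)
        assert co.phi_denom == pytest.approx(10.0 * np.exp(-a * 10), rel=1e-14)
        assert co.phi_weight == pytest.approx((1 + a * 10) * np.exp(-a * 10), rel=1e-14)

    def test_step_matrix_is_matrix_exponential(self, subject1):
        # Lagrange-Sylvester identity for 2x2: varphi*I + phi*A = expm(A h)
        A = build_rate_matrix(subject1).as_array()
        for h in (0.01, 1.0, 10.0, 100.0):
            M = nsfd_step_matrix(subject1, h)
            np.testing.assert_allclose(M, expm(A * h), rtol=1e-13, atol=1e-16)

    def test_positive_and_finite(self):
        for params in random_parameter_fixture(seed=3, n_sets=20):
            for h in (0.01, 1.0, 50.0):
                co = nsfd_coefficients(params, h)
                assert np.isfinite(co.phi_denom) and co.phi_denom > 0
                assert np.isfinite(co.phi_weight) and co.phi_weight > 0


class TestNSFDExactness:
    def test_bolus_nodes_equal_closed_form(self, subject1):
        grid = Grid(h=10.0, N=2)
        traj = nsfd_integrate_bolus(subject1, DoseRegimen.bolus(), grid)
        c_exact, p_exact = bolus_solution(subject1, grid.nodes)
        np.testing.assert_allclose(traj.c, c_exact, rtol=1e-12)
        np.testing.assert_allclose(traj.p, p_exact, rtol=1e-12, atol=1e-15)
        assert traj.c[1] == pytest.approx(0.645913386, abs=1e-9)
        assert traj.p[1] == pytest.approx(0.278729283, abs=1e-9)

    def test_infusion_nodes_equal_closed_form(self, subject1):
        grid = Grid(h=10.0, N=2)
        traj = nsfd_integrate_infusion(subject1, DoseRegimen.infusion(1.0), grid)
        c_exact, p_exact = infusion_solution(subject1, 1.0, grid.nodes)
        np.testing.assert_allclose(traj.c, c_exact, rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose(traj.p, p_exact, rtol=1e-12, atol=1e-12)
        assert traj.c[1] == pytest.approx(8.01673739, abs=1e-8)

    def test_exactness_over_random_parameters_and_steps(self):
        # the headline property: node-exact for ANY step size
        rng = np.random.default_rng(123)
        for params in random_parameter_fixture(seed=5, n_sets=50):
            h = float(np.exp(rng.uniform(np.log(0.01), np.log(100.0))))
            grid = Grid(h=h, N=20)
            bol = nsfd_integrate_bolus(params, DoseRegimen.bolus(), grid)
            cb, pb = bolus_solution(params, grid.nodes)
            scale_b = max(1.0, np.max(np.abs(cb)), np.max(np.abs(pb)))
            assert np.max(np.abs(bol.c - cb)) < 1e-10 * scale_b
            assert np.max(np.abs(bol.p - pb)) < 1e-10 * scale_b
            inf = nsfd_integrate_infusion(params, DoseRegimen.infusion(1.0), grid)
            ci, pi = infusion_solution(params, 1.0, grid.nodes)
            eq = equilibrium(params, DoseRegimen.infusion(1.0))
            scale_i = max(1.0, eq.c_star, eq.p_star)  # intrinsic problem scale
            assert np.max(np.abs(inf.c - ci)) < 1e-10 * scale_i
            assert np.max(np.abs(inf.p - pi)) < 1e-10 * scale_i

    def test_infusion_formulations_agree(self, subject1):
        # affine exact-flow map vs node substitution into the closed form
        regimen = DoseRegimen.infusion(1.0)
        for h, N in ((0.5, 40), (10.0, 20), (100.0, 10)):
            grid = Grid(h=h, N=N)
            a = nsfd_integrate_infusion(subject1, regimen, grid)
            b = nsfd_integrate_infusion_substitution(subject1, regimen, grid)
            np.testing.assert_allclose(a.c, b.c, rtol=1e-12, atol=1e-12)
            np.testing.assert_allclose(a.p, b.p, rtol=1e-12, atol=1e-12)

    def test_equilibrium_is_fixed_point(self, subject1):
        eq = equilibrium(subject1, DoseRegimen.infusion(1.0))
        regimen = DoseRegimen(mode="infusion", c0=eq.c_star, p0=eq.p_star, I0=1.0)
        traj = nsfd_integrate_infusion(subject1, regimen, Grid(h=26.0, N=30))
        np.testing.assert_allclose(traj.c, eq.c_star, rtol=1e-12)
        np.testing.assert_allclose(traj.p, eq.p_star, rtol=1e-12)

    def test_positivity_and_boundedness(self):
        # dynamical consistency: nonnegative iterates, infusion bounded by c*
        for params in random_parameter_fixture(seed=9, n_sets=20):
            grid = Grid(h=40.0, N=200)
            bol = nsfd_integrate_bolus(params, DoseRegimen.bolus(), grid)
            assert np.all(bol.c >= 0) and np.all(bol.p >= 0)
            inf = nsfd_integrate_infusion(params, DoseRegimen.infusion(1.0), grid)
            eq = equilibrium(params, DoseRegimen.infusion(1.0))
            assert np.all(inf.c >= 0) and np.all(inf.p >= 0)
            assert np.max(inf.c) <= eq.c_star * (1 + 1e-12)

    def test_mode_mismatch_rejected(self, subject1):
        with pytest.raises(ValueError):
            nsfd_integrate_bolus(subject1, DoseRegimen.infusion(1.0), Grid(h=1, N=1))
        with pytest.raises(ValueError):
            nsfd_integrate_infusion(subject1, DoseRegimen.bolus(), Grid(h=1, N=1))


class TestRK45:
    def test_tracks_closed_form_on_benchmark(self, subject1):
        grid = Grid.from_N(10, 20.0)
        traj = rk45_integrate(subject1, DoseRegimen.bolus(), grid)
        c_exact, p_exact = bolus_solution(subject1, grid.nodes)
        assert np.max(np.abs(traj.c - c_exact)) < 1e-5
        assert np.max(np.abs(traj.p - p_exact)) < 1e-5

    def test_tighter_tolerance_reduces_error(self, subject1):
        grid = Grid.from_N(10, 20.0)
        c_exact, _ = bolus_solution(subject1, grid.nodes)
        errs = []
        for rtol, atol in ((1e-3, 1e-6), (1e-8, 1e-11)):
            traj = rk45_integrate(subject1, DoseRegimen.bolus(), grid, rtol=rtol, atol=atol)
            errs.append(np.max(np.abs(traj.c - c_exact)))
        assert errs[1] < errs[0]
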