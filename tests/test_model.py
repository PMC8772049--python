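"""Unit tests for the deterministic circuit model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edacircuit import (
    CORRECTED,
    PAPER_LITERAL,
    AdmissibilityError,
    DegenerateParameterError,
    InitialConditions,
    InvariantRegionError,
    MarkLaw,
    NoiseSpec,
    RateConstants,
    ReducedState,
    ValidationError,
    conservation_residuals,
    derive_coefficients,
    full_rhs,
    integrate_ode,
    invariant_region_contains,
    lv_bound_C,
    lyapunov_V,
    reconstruct_full,
    reduced_rhs,
)
from edacircuit.model import Trajectory


class TestDeriveCoefficients:
    def test_published_parameter_set(self):
        rates = RateConstants(2e4, 1.8e4, 2.1e4)
        init = InitialConditions(x0=1.5e-4, a0=2.8e-4, c0=1.4e-4)
        c = derive_coefficients(rates, init)
        assert c.a1 == pytest.approx(5.6)
        assert c.c1 == pytest.approx(-2000.0)
        assert c.c2 == pytest.approx(-23000.0)
        assert c.b2 == pytest.approx(1.8e4 * 1.5e-4 + 2.1e4 * (1.4e-4 - 1.5e-4))
        assert c.K == pytest.approx(2.1e4 * 1e-5 / 1.5e4)

    def test_symmetric_rates_zero_c1(self):
        c = derive_coefficients(
            RateConstants(1.0, 1.0, 0.5), InitialConditions(x0=1.0, a0=1.0, c0=0.5)
        )
        assert c.c1 == 0.0
        assert c.c1x == 0.0

    def test_equal_loadings_zero_K(self):
        c = derive_coefficients(
            RateConstants(1.0, 1.0, 0.5), InitialConditions(x0=0.5, a0=1.0, c0=0.5)
        )
        assert c.K == 0.0

    def test_mode_controls_x_equation_sign(self, toy_rates, toy_init):
        lit = derive_coefficients(toy_rates, toy_init, PAPER_LITERAL)
        cor = derive_coefficients(toy_rates, toy_init, CORRECTED)
        assert lit.c1x == lit.c1
        assert cor.c1x == -cor.c1
        assert lit.c1 == cor.c1

    def test_degenerate_denominator(self):
        with pytest.raises(DegenerateParameterError):
            derive_coefficients(
                RateConstants(1.0, 1.0, 2.0), InitialConditions(x0=1.0, a0=1.0, c0=0.5)
            )

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError, match="k1"):
            RateConstants(-1.0, 1.0, 1.0)


class TestFullRhs:
    def test_single_term_evaluation(self):
        rates = RateConstants(1.0, 1.0, 1.0)
        state = np.array([1.0, 1.0, 0.0, 0.0, 1.0, 0.0, 0.0])
        assert np.array_equal(
            full_rhs(state, rates), np.array([-1.0, -1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        )

    def test_catalytic_terms_vanish_without_intermediate(self, toy_rates):
        state = np.array([0.7, 0.3, 0.0, 0.0, 0.5, 0.1, 0.1])
        d = full_rhs(state, toy_rates)
        assert d[4] == 0.0 and d[5] == 0.0 and d[6] == 0.0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.0, 10.0), min_size=7, max_size=7))
    def test_conservation_sums_cancel(self, values):
        """The linear conservation combinations have exactly zero derivative."""
        rates = RateConstants(1.3, 0.7, 2.2)
        d = full_rhs(np.array(values), rates)
        dx, da, dy, db, dc, dd, de = d
        scale = max(1.0, float(np.max(np.abs(d))))
        assert abs(dx + dy + de) <= 1e-12 * scale
        assert abs(da + dy) <= 1e-12 * scale
        assert abs(dc + de) <= 1e-12 * scale
        assert abs(dx + db) <= 1e-12 * scale


class TestReducedRhs:
    def test_hand_arithmetic(self, toy_rates, toy_init):
        c = derive_coefficients(toy_rates, toy_init)
        c = c.__class__(a1=1.0, b1=1.0, c1=0.0, b2=1.0, c2=0.0, k2=1.0,
                        k_sum=c.k_sum, K=c.K, mode=c.mode, c1x=0.0)
        assert np.array_equal(reduced_rhs(ReducedState(1.0, 1.0), c), [0.0, -1.0])

    @pytest.mark.parametrize("mode", [PAPER_LITERAL, CORRECTED])
    def test_origin_is_equilibrium(self, toy_rates, toy_init, mode):
        c = derive_coefficients(toy_rates, toy_init, mode)
        assert np.array_equal(reduced_rhs(ReducedState(0.0, 0.0), c), [0.0, 0.0])

    def test_corrected_mode_matches_projected_full_model(self, toy_rates, toy_init):
        """With consistent initialisation the corrected reduced model and the
        (x, y) projection of the full model follow the same path."""
        c = derive_coefficients(toy_rates, toy_init, CORRECTED)
        full0 = reconstruct_full(
            ReducedState(toy_init.x0, 0.0), toy_init
        ).as_array()
        t_full = integrate_ode(lambda z: full_rhs(z, toy_rates), full0, 1e-3, 10.0)
        t_red = integrate_ode(
            lambda z: reduced_rhs(z, c), [toy_init.x0, 0.0], 1e-3, 10.0
        )
        proj = t_full.states[:, [0, 2]]
        scale = np.max(np.abs(proj))
        assert np.max(np.abs(proj - t_red.states)) / scale < 1e-6

    def test_paper_literal_mode_diverges_from_full_model(self, toy_rates, toy_init):
        """The published x-equation sign is inconsistent with the full model
        whenever k1 != k_minus1: the discrepancy is real and measurable."""
        c = derive_coefficients(toy_rates, toy_init, PAPER_LITERAL)
        full0 = reconstruct_full(ReducedState(toy_init.x0, 0.0), toy_init).as_array()
        t_full = integrate_ode(lambda z: full_rhs(z, toy_rates), full0, 1e-3, 10.0)
        t_red = integrate_ode(
            lambda z: reduced_rhs(z, c), [toy_init.x0, 0.0], 1e-3, 10.0
        )
        proj = t_full.states[:, [0, 2]]
        assert np.max(np.abs(proj - t_red.states)) > 1e-4


class TestReconstructFull:
    def test_initial_point(self, toy_init):
        f = reconstruct_full(ReducedState(toy_init.x0, 0.0), toy_init)
        assert (f.a, f.b, f.c, f.d, f.e) == (toy_init.a0, 0.0, toy_init.c0, 0.0, 0.0)

    def test_fuel_exhausted(self, toy_init):
        f = reconstruct_full(ReducedState(toy_init.x0 - toy_init.c0, 0.0), toy_init)
        assert f.e == pytest.approx(toy_init.c0)
        assert f.c == pytest.approx(0.0)
        assert f.d == f.e

    def test_random_admissible_points_satisfy_identities_exactly(self, rng):
        # dyadic loadings and states keep the conservation sums exact in floats
        init = InitialConditions(x0=1.0, a0=0.5, c0=0.375)
        for _ in range(200):
            x = rng.integers(int((init.x0 - init.c0) * 256), 256) / 256.0
            y_max = min(init.a0, init.x0 - x)
            y = rng.integers(0, int(y_max * 256) + 1) / 256.0
            f = reconstruct_full(ReducedState(x, y), init)
            assert f.x + f.y + f.e == init.x0
            assert f.a + f.y == init.a0
            assert f.c + f.e == init.c0
            assert f.x + f.b == init.x0

    @pytest.mark.parametrize(
        "state, species",
        [
            ((0.5, 0.6), "a"),  # y > a0
            ((1.1, 0.1), "b"),  # x > x0
            ((0.1, 0.1), "c"),  # x + y < x0 - c0, so e > c0 and fuel goes negative
        ],
    )
    def test_inadmissible_point_names_species(self, toy_init, state, species):
        with pytest.raises(AdmissibilityError, match=f"'{species}'"):
            reconstruct_full(ReducedState(*state), toy_init)


class TestConservationResiduals:
    def test_exact_state_zero_residuals(self, toy_init):
        f = reconstruct_full(ReducedState(0.7, 0.2), toy_init).as_array()
        traj = Trajectory(
            times=np.array([0.0, 1.0]),
            states=np.vstack([f, f]),
            jump_counts=np.zeros(1, dtype=int),
            clamp_flags=np.zeros(1, dtype=bool),
        )
        res = conservation_residuals(traj, toy_init)
        for series in res.values():
            assert np.all(series == 0.0)

    def test_perturbed_catalyst_shows_in_catalyst_residual(self, toy_init):
        f = reconstruct_full(ReducedState(0.7, 0.2), toy_init).as_array()
        g = f.copy()
        g[1] += 1e-3
        traj = Trajectory(
            times=np.array([0.0, 1.0]),
            states=np.vstack([f, g]),
            jump_counts=np.zeros(1, dtype=int),
            clamp_flags=np.zeros(1, dtype=bool),
        )
        res = conservation_residuals(traj, toy_init)
        assert res["catalyst"][1] == pytest.approx(1e-3)
        assert res["substrate"][1] == 0.0


class TestInvariantRegion:
    def test_interior_point(self, toy_coeffs, toy_init):
        K = toy_coeffs.K
        assert invariant_region_contains(
            ReducedState(K / 4, K / 4), toy_coeffs, toy_init
        )

    def test_boundary_is_excluded(self, toy_coeffs, toy_init):
        K = toy_coeffs.K
        assert not invariant_region_contains(
            ReducedState(K / 2, K / 2), toy_coeffs, toy_init
        )

    def test_empty_region_raises(self):
        rates = RateConstants(1.0, 1.0, 0.5)
        init = InitialConditions(x0=0.4, a0=1.0, c0=0.5)  # x0 < c0 -> K < 0
        coeffs = derive_coefficients(rates, init)
        with pytest.raises(InvariantRegionError):
            invariant_region_contains(ReducedState(0.1, 0.1), coeffs, init)

    def test_corrected_region_is_forward_invariant(self, toy_rates, toy_init, rng):
        """Along corrected-mode trajectories, membership in
        {x, y > 0, x + y < x0 - c0} never flips to False."""
        coeffs = derive_coefficients(toy_rates, toy_init, CORRECTED)
        bound = toy_init.x0 - toy_init.c0
        for _ in range(10):
            s = rng.uniform(0.05, 0.45)
            frac = rng.uniform(0.1, 0.9)
            start = [s * frac, s * (1 - frac)]
            assert s < bound
            traj = integrate_ode(lambda z: reduced_rhs(z, coeffs), start, 1e-3, 5.0)
            for row in traj.states:
                assert invariant_region_contains(
                    ReducedState(row[0], row[1]), coeffs, toy_init, CORRECTED
                )


class TestIntegrateOde:
    def test_zero_rhs_constant(self):
        traj = integrate_ode(lambda z: np.zeros_like(z), [1.0, 2.0], 0.1, 1.0)
        assert np.all(traj.states == [1.0, 2.0])
        assert traj.times[0] == 0.0 and traj.times[-1] == pytest.approx(1.0)

    def test_exponential_decay_accuracy(self):
        traj = integrate_ode(lambda z: -z, [1.0], 1e-2, 1.0, method="rk4")
        assert traj.states[-1, 0] == pytest.approx(math.exp(-1.0), abs=1e-8)

    def test_rk4_fourth_order_convergence(self):
        errs = []
        for dt in (1e-2, 5e-3):
            traj = integrate_ode(lambda z: -z, [1.0], dt, 1.0, method="rk4")
            errs.append(abs(traj.states[-1, 0] - math.exp(-1.0)))
        ratio = errs[0] / errs[1]
        assert 12.0 < ratio < 20.0

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValidationError):
            integrate_ode(lambda z: z, [1.0], -0.1, 1.0)


class TestLyapunovV:
    def test_global_minimum(self):
        assert lyapunov_V(ReducedState(1.0, 1.0)) == 0.0

    def test_closed_form_value(self):
        assert lyapunov_V(ReducedState(math.e, 1.0)) == pytest.approx(math.e - 2.0)

    def test_nonnegative_on_positive_quadrant(self, rng):
        pts = np.exp(rng.uniform(-6, 6, size=(10_000, 2)))
        for x, y in pts:
            assert lyapunov_V((x, y)) >= 0.0

    def test_domain_error(self):
        with pytest.raises(ValidationError):
            lyapunov_V(ReducedState(0.0, 1.0))


class TestLvBoundC:
    def test_noise_free_closed_form(self, toy_rates, toy_init, toy_coeffs):
        c = lv_bound_C(toy_coeffs, toy_init, toy_rates, NoiseSpec())
        expected = (
            toy_rates.k1 * toy_init.a0
            + toy_rates.k_minus1 * toy_init.x0
            + toy_rates.k2 * (toy_init.c0 - toy_init.x0)
            + toy_coeffs.k_sum * toy_coeffs.K
        )
        assert c == pytest.approx(expected)

    def test_monotone_in_noise(self, toy_rates, toy_init, toy_coeffs):
        base = lv_bound_C(toy_coeffs, toy_init, toy_rates, NoiseSpec())
        more_sigma = lv_bound_C(
            toy_coeffs, toy_init, toy_rates, NoiseSpec(sigma=0.5)
        )
        more_delta = lv_bound_C(
            toy_coeffs, toy_init, toy_rates, NoiseSpec(delta=0.5, lambda_Y=1.0)
        )
        assert more_sigma > base
        assert more_delta > base

    def test_case3_hand_sum(self):
        """The five-term sum for the third published noise case, recomputed
        term by term."""
        rates = RateConstants(2e4, 1.8e4, 2.1e4)
        init = InitialConditions(x0=1.5e-4, a0=2.8e-4, c0=1.4e-4)
        noise = NoiseSpec(
            sigma=0.2, lambda_Y=1.0, mark=MarkLaw(type="constant", gamma=0.15),
            delta=0.2,
        )
        coeffs = derive_coefficients(rates, init)
        K = 2.1e4 * (1.5e-4 - 1.4e-4) / (2 * 1.8e4 - 2.1e4)
        terms = [
            2e4 * 2.8e-4,
            1.8e4 * 1.5e-4,
            2.1e4 * (1.4e-4 - 1.5e-4),
            (2e4 + 1.8e4 + 2.1e4) * K,
            0.2**2 * K**2,
            0.2**2 / 0.8**2 * 1.0,
        ]
        c = lv_bound_C(coeffs, init, rates, noise)
        assert c == pytest.approx(sum(terms))
        assert c > 0 and math.isfinite(c)
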