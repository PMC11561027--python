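"""Unit tests for the radially symmetric reduction."""

import numpy as np
import pytest

from avtumor import radial
from avtumor.radial import (
    RadialState,
    ReducedParams,
    eigenvalue_radial,
    eigenvalue_radial_eta,
    find_stationary,
    integrate_radial,
    oxygen_profile,
    pressure_profile,
    prop31_guaranteed_stable,
    radial_rhs,
    reduced_params,
    region_relations,
    solve_regions,
    stationary_from_eta,
)


class TestRadialState:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            RadialState(0.3, 0.2, 0.1)
        with pytest.raises(ValueError):
            RadialState(0.1, 0.2, 1.1)

    def test_degenerate_allowed(self):
        st = RadialState(0.0, 0.0, 0.3)
        assert st.as_tuple() == (0.0, 0.0, 0.3)


class TestOxygenProfile:
    def test_outer_dirichlet_value(self):
        st = RadialState(0.1, 0.2, 0.3)
        assert oxygen_profile(1.0, st, 1.15) == pytest.approx(1.0)

    def test_closed_form_at_rim(self):
        # uniform consuming disc, r_p = 0.3, lam = 1.15:
        # c(r_p) = 1 + (lam/2) r_p^2 ln r_p
        st = RadialState(0.0, 0.3, 0.3)
        expected = 1.0 + 0.575 * 0.09 * np.log(0.3)
        assert oxygen_profile(0.3, st, 1.15) == pytest.approx(expected)
        assert expected == pytest.approx(0.9377, abs=1e-4)

    def test_zero_consumption_is_flat(self):
        st = RadialState(0.1, 0.2, 0.3)
        r = np.linspace(0, 1, 50)
        assert np.allclose(oxygen_profile(r, st, 0.0), 1.0)

    def test_core_pinned_at_survival_threshold(self):
        st = RadialState(0.15, 0.2, 0.3)
        assert oxygen_profile(0.05, st, 1.15, kappa_death=0.93) == 0.93

    def test_continuity_across_rim(self):
        st = RadialState(0.1, 0.2, 0.3)
        lo = oxygen_profile(0.3 - 1e-9, st, 1.15)
        hi = oxygen_profile(0.3 + 1e-9, st, 1.15)
        assert lo == pytest.approx(hi, abs=1e-7)

    def test_rejects_r_beyond_domain(self):
        with pytest.raises(ValueError):
            oxygen_profile(1.5, RadialState(0.1, 0.2, 0.3), 1.0)

    def test_shooting_cross_check(self):
        """Independent oracle: integrate the radial two-point boundary-value
        problem for the oxygen equation and compare with the closed form."""
        from scipy.integrate import solve_ivp

        st = RadialState(0.0, 0.3, 0.3)
        lam = 1.15

        # integrate outward from the center: c'(0) = 0, unknown c(0) found
        # by matching c(1) = 1 (linear problem: solve for the offset)
        def rhs(r, y):
            c, dc = y
            sink = lam if r <= 0.3 else 0.0
            d2c = sink - (dc / r if r > 1e-12 else 0.0)
            return [dc, d2c]

        sol = solve_ivp(rhs, (1e-9, 1.0), [0.0, 0.0], rtol=1e-10, atol=1e-12,
                        dense_output=True)
        # homogeneous correction is a constant (regular at 0), so just shift
        shift = 1.0 - sol.y[0, -1]
        for r in (0.1, 0.25, 0.3, 0.6):
            num = sol.sol(r)[0] + shift
            assert num == pytest.approx(oxygen_profile(r, st, lam), abs=1e-7)


class TestRegionRelations:
    def test_reduced_parameter_arithmetic(self, pde_params):
        rp = reduced_params(pde_params)
        assert rp.K_prol == pytest.approx(4 * 0.06 / 1.15)
        assert rp.K_prol == pytest.approx(0.20870, abs=1e-5)
        assert rp.K_death == pytest.approx(4 * 0.07 / 1.15)

    def test_inverse_then_forward_roundtrip(self, pde_params):
        rp = reduced_params(pde_params)
        for r_p in (0.2, 0.3, 0.4, 0.5):
            st = solve_regions(rp.K_prol, rp.K_death, r_p)
            res_p, res_d = region_relations(st, pde_params.lam,
                                            pde_params.kappa_prol,
                                            pde_params.kappa_death)
            assert abs(res_p) < 1e-10
            assert abs(res_d) < 1e-10

    def test_interior_radii_match_oxygen_thresholds(self, pde_params):
        rp = reduced_params(pde_params)
        st = solve_regions(rp.K_prol, rp.K_death, 0.35)
        assert oxygen_profile(st.r_q, st, pde_params.lam) == pytest.approx(
            pde_params.kappa_prol, abs=1e-10)
        assert oxygen_profile(st.r_n + 1e-12, st, pde_params.lam) == pytest.approx(
            pde_params.kappa_death, abs=1e-8)

    def test_small_tumor_has_no_interior_zones(self, pde_params):
        rp = reduced_params(pde_params)
        st = solve_regions(rp.K_prol, rp.K_death, 0.05)
        assert st.r_n == 0.0
        assert st.r_q == 0.0

    def test_no_core_when_center_oxygen_sufficient(self, pde_params):
        rp = reduced_params(pde_params)
        st = solve_regions(rp.K_prol, rp.K_death, 0.25)
        if st.r_n == 0.0:
            center = oxygen_profile(0.0, st, pde_params.lam)
            assert center >= pde_params.kappa_death - 1e-12


class TestRadialRhs:
    def test_pure_growth_limit(self):
        assert radial_rhs(RadialState(0, 0, 0.3), 1.35) == pytest.approx(0.09)

    def test_zonated_arithmetic(self):
        val = radial_rhs(RadialState(0.1, 0.2, 0.3), 1.35)
        assert val == pytest.approx(-0.0135 - 0.04 + 0.09)
        assert val == pytest.approx(0.0365)

    def test_stationary_state_has_zero_rhs(self, stationary_state, pde_params):
        assert abs(radial_rhs(stationary_state, pde_params.mu_death)) < 1e-10


class TestFindStationary:
    def test_equilibrium_solves_all_relations(self, stationary_state, pde_params):
        res_p, res_d = region_relations(stationary_state, pde_params.lam,
                                        pde_params.kappa_prol,
                                        pde_params.kappa_death)
        assert abs(res_p) < 1e-10 and abs(res_d) < 1e-10
        assert abs(radial_rhs(stationary_state, pde_params.mu_death)) < 1e-10

    def test_equilibrium_radii_match_independent_solve(self, stationary_state):
        # frozen from an independent simultaneous root solve (scipy.fsolve
        # on the two zonation relations plus stationarity) of the standard
        # parameter set
        assert stationary_state.r_n == pytest.approx(0.128450, abs=2e-6)
        assert stationary_state.r_q == pytest.approx(0.276797, abs=2e-6)
        assert stationary_state.r_p == pytest.approx(0.314469, abs=2e-6)

    def test_death_rate_shrinks_equilibrium(self, pde_params):
        radii = []
        for mu in (1.0, 1.35, 2.0, 4.0):
            st = find_stationary(pde_params.with_(mu_death=mu))
            radii.append(st.r_p)
        assert all(a >= b - 1e-12 for a, b in zip(radii, radii[1:]))

    def test_radii_roundtrip_through_reduced_parameters(self, rng):
        """Pick radii, derive (K's, mu) that make them stationary, recover."""
        for _ in range(20):
            rn = rng.uniform(0.02, 0.2)
            rq = rng.uniform(rn + 0.01, 0.35)
            mu = rng.uniform(0.1, 3.0)
            rp = np.sqrt(mu * rn**2 + rq**2)
            if rp >= 0.9:
                continue
            x, y, z = rp**2, rq**2, rn**2
            K_prol = -x * np.log(x) + z * np.log(y) - y + x
            K_death = -x * np.log(x) + z * np.log(z) - z + x
            if K_prol > K_death:
                continue
            st = find_stationary(ReducedParams(K_prol, K_death, mu))
            assert st.r_p == pytest.approx(rp, abs=1e-8)
            assert st.r_n == pytest.approx(rn, abs=1e-7)
            assert st.r_q == pytest.approx(rq, abs=1e-7)


class TestEigenvalue:
    def test_frozen_example(self):
        # stationary by construction: 1.35*0.01 + 0.04 = 0.0535 = 0.23130^2
        st = RadialState(0.1, 0.2, 0.23130)
        assert radial_rhs(st, 1.35) == pytest.approx(0.0, abs=1e-4)
        assert eigenvalue_radial(st, 1.35) == pytest.approx(-1.03362, abs=2e-4)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_finite_difference_linearization(self, seed):
        """The closed form equals d(rhs)/d(r_p^2) of the slaved dynamics."""
        rng = np.random.default_rng(seed)
        checked = 0
        while checked < 30:
            eta = rng.uniform(0.05, 0.95)
            mu = 10 ** rng.uniform(-1.5, 1.0)
            r_p = rng.uniform(0.1, 0.6)
            rn, rq = stationary_from_eta(eta, mu, r_p)
            st = RadialState(float(rn), float(rq), r_p)
            x, y, z = r_p**2, float(rq) ** 2, float(rn) ** 2
            K_prol = -x * np.log(x) + z * np.log(y) - y + x
            K_death = -x * np.log(x) + z * np.log(z) - z + x
            if K_prol > K_death or K_prol <= 0:
                continue
            lam_closed = eigenvalue_radial(st, mu)

            def f(xx):
                s = solve_regions(K_prol, K_death, np.sqrt(xx))
                return radial_rhs(s, mu)

            hstep = 1e-5 * x  # small enough for the curvature, large
            # enough that the O(eps/h) roundoff stays below 1e-7 relative
            fd = (-f(x + 2 * hstep) + 8 * f(x + hstep)
                  - 8 * f(x - hstep) + f(x - 2 * hstep)) / (12 * hstep)
            assert lam_closed == pytest.approx(fd, rel=1e-6)
            checked += 1

    def test_no_core_limit(self):
        # r_n -> 0 gives the analytic limit 1 + 2 ln r_p
        st = RadialState(0.0, 0.3, 0.3)
        assert eigenvalue_radial(st, 1.0) == pytest.approx(1 + 2 * np.log(0.3))

    def test_eta_parametrization_agrees_with_direct_formula(self, rng):
        eta = rng.uniform(0.05, 0.95, size=50)
        mu = 10 ** rng.uniform(-2, 1.5, size=50)
        r_p = 0.3
        vec = eigenvalue_radial_eta(eta, mu, r_p)
        for e, m, v in zip(eta, mu, vec):
            rn, rq = stationary_from_eta(e, m, r_p)
            st = RadialState(float(rn), float(rq), r_p)
            assert v == pytest.approx(eigenvalue_radial(st, m), rel=1e-10)


class TestProp31:
    def test_small_equilibrium_guaranteed_stable(self):
        st = RadialState(0.1, 0.2, 0.23130)
        assert prop31_guaranteed_stable(st)
        assert eigenvalue_radial(st, 1.35) < 0

    def test_large_tumor_gives_no_conclusion(self):
        assert not prop31_guaranteed_stable(RadialState(0.1, 0.2, 0.5))

    def test_boundary_radius_included(self):
        st = RadialState(0.1, 0.2, float(np.exp(-1)))
        assert prop31_guaranteed_stable(st)


class TestPressureProfile:
    def test_rim_gradient_recovers_growth_velocity(self):
        st = RadialState(0.1, 0.2, 0.3)
        mu = 1.35
        eps = 1e-7
        dp = (pressure_profile(0.3 - eps, st, mu) - pressure_profile(0.3 - 2 * eps, st, mu)) / eps
        r_p_dot = radial_rhs(st, mu) / (2 * 0.3)
        assert -dp == pytest.approx(r_p_dot, abs=1e-5)
        assert r_p_dot == pytest.approx(0.06083, abs=1e-5)

    def test_c1_continuity_at_interfaces(self):
        st = RadialState(0.12, 0.22, 0.33)
        mu = 0.8
        for r0 in (0.12, 0.22):
            eps = 1e-8
            left = (pressure_profile(r0, st, mu) - pressure_profile(r0 - eps, st, mu)) / eps
            right = (pressure_profile(r0 + eps, st, mu) - pressure_profile(r0, st, mu)) / eps
            assert left == pytest.approx(right, abs=1e-5)

    def test_surface_tension_raises_rim_pressure(self):
        st = RadialState(0.0, 0.0, 0.3)
        base = pressure_profile(0.3 - 1e-12, st, 1.0, sigma=0.0)
        lifted = pressure_profile(0.3 - 1e-12, st, 1.0, sigma=0.003)
        assert lifted - base == pytest.approx(0.003 / 0.3)

    def test_empty_tumor_is_ambient(self):
        st = RadialState(0.0, 0.0, 0.0)
        assert pressure_profile(0.5, st, 1.0, p_ext=0.2) == pytest.approx(0.2)


class TestIntegrateRadial:
    def test_exponential_early_growth(self, pde_params):
        tr = integrate_radial(0.03, pde_params, 0.5,
                              t_eval=np.linspace(0, 0.5, 6))
        V = tr["r_p"] ** 2
        assert V[-1] / V[0] == pytest.approx(np.exp(0.5), rel=0.02)

    def test_converges_to_stationary_state(self, pde_params, stationary_state):
        tr = integrate_radial(0.1, pde_params, 60.0)
        assert tr["r_p"][-1] == pytest.approx(stationary_state.r_p, abs=1e-6)
        assert tr["r_n"][-1] == pytest.approx(stationary_state.r_n, abs=1e-5)

    def test_sigmoidal_volume_curve(self, pde_params):
        """Early exponential growth then a plateau (monotone after start)."""
        tr = integrate_radial(0.05, pde_params, 40.0,
                              t_eval=np.linspace(0, 40, 161))
        V = tr["r_p"] ** 2
        assert (np.diff(V) > -1e-9 * V.max()).all()
        early = (V[4] - V[0]) / V[0]
        late = (V[-1] - V[-5]) / V[-5]
        assert early > 50 * max(late, 1e-12)

    def test_monotone_when_death_free(self):
        rp = ReducedParams(K_prol=0.2, K_death=0.25, mu_death=0.0)
        tr = integrate_radial(0.1, rp, 5.0, t_eval=np.linspace(0, 5, 21))
        assert (np.diff(tr["r_p"]) >= -1e-12).all()

    def test_rejects_bad_initial_radius(self, pde_params):
        with pytest.raises(ValueError):
            integrate_radial(1.2, pde_params, 1.0)
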