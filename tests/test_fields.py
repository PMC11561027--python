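"""Unit tests for the stationary pressure and oxygen solvers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avtumor import radial
from avtumor.fields import (
    ModelParams,
    edge_flux,
    solve_oxygen,
    solve_pressure,
    spectral_rim_curvature,
)
from avtumor.grid import extract_boundary


class TestModelParams:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            ModelParams(kappa_prol=0.9, kappa_death=0.95)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(mu_death=-0.1)

    def test_with_updates_a_copy(self):
        p = ModelParams()
        q = p.with_(sigma=0.01)
        assert q.sigma == 0.01 and p.sigma == 0.0


class TestSolvePressure:
    def test_homogeneous_problem_is_flat(self, medium_grid):
        r = medium_grid.radii()
        tumor = r <= 0.3
        p = ModelParams(sigma=0.0, p_ext=0.0)
        f = solve_pressure(np.zeros(medium_grid.shape), tumor, medium_grid, p)
        assert np.nanmax(np.abs(f.values[tumor])) < 1e-12

    def test_matches_radial_closed_form(self, fine_grid):
        """Zonated source against the piecewise radial profile."""
        stz = radial.RadialState(0.1, 0.2, 0.3)
        mu = 1.35
        r = fine_grid.radii()
        src = np.zeros(fine_grid.shape)
        src[(r <= 0.3) & (r >= 0.2)] = 1.0
        src[r < 0.1] = -mu
        f = solve_pressure(src, r <= 0.3, fine_grid, ModelParams(mu_death=mu))
        i0 = fine_grid.shape[0] // 2
        rr = np.arange(0, 0.29, 0.02)
        num = np.array([f.values[i0 + int(round(x / fine_grid.h)), i0] for x in rr])
        exact = radial.pressure_profile(rr, stz, mu)
        # O(h) boundary-fitting error at the staircase rim
        assert np.abs(num - exact).max() < 10 * fine_grid.h * 0.1

    def test_surface_tension_constant_solution(self, medium_grid):
        """Source-free disc: p is the uniform Young-Laplace rim value."""
        r = medium_grid.radii()
        tumor = r <= 0.3
        p = ModelParams(sigma=0.003)
        f = solve_pressure(np.zeros(medium_grid.shape), tumor, medium_grid, p)
        expected = 0.003 / 0.3  # p_ext + sigma * (1/r_p)
        vals = f.values[tumor]
        assert np.nanmean(vals) == pytest.approx(expected, rel=0.1)
        assert np.nanstd(vals) < 0.2 * abs(expected)

    def test_empty_domain_rejected(self, coarse_grid):
        with pytest.raises(ValueError):
            solve_pressure(np.zeros(coarse_grid.shape),
                           np.zeros(coarse_grid.shape, dtype=bool),
                           coarse_grid, ModelParams())

    def test_field_solvers_converge_to_closed_forms(self):
        """Pressure and oxygen errors against the radial closed forms
        decrease with h at observed order >= 1 on symmetric fixtures."""
        from avtumor.grid import build_lattice

        stz = radial.RadialState(0.1, 0.2, 0.3)
        mu, lam = 1.35, 1.15
        p_errs, c_errs = [], []
        for h in (0.04, 0.02, 0.01):
            g = build_lattice(h, 1.0)
            r = g.radii()
            src = np.zeros(g.shape)
            src[(r <= 0.3) & (r >= 0.2)] = 1.0
            src[r < 0.1] = -mu
            f = solve_pressure(src, r <= 0.3, g, ModelParams(mu_death=mu))
            sel = (r <= 0.28) & np.isfinite(f.values)
            p_errs.append(np.abs(f.values - radial.pressure_profile(
                np.clip(r, 0, 1), stz, mu))[sel].max())
            # anti-aliased uniform-disc sink for the oxygen comparison
            sink = np.clip((0.3 - r) / h + 0.5, 0.0, 1.0)
            c = solve_oxygen(sink, g, ModelParams(lam=lam))
            st0 = radial.RadialState(0.0, 0.3, 0.3)
            cex = radial.oxygen_profile(np.clip(r, 0, 1), st0, lam)
            c_errs.append(np.abs(c.values - cex)[g.mask].max())
        for errs in (p_errs, c_errs):
            order = np.log2(errs[0] / errs[2]) / 2
            assert order >= 0.9, f"observed order {order:.2f} from {errs}"


class TestSolveOxygen:
    def test_no_sink_is_ambient(self, medium_grid):
        c = solve_oxygen(np.zeros(medium_grid.shape), medium_grid,
                         ModelParams(lam=1.0))
        assert np.nanmax(np.abs(c.values - 1.0)) == 0.0

    def test_zero_lambda_is_ambient(self, medium_grid):
        r = medium_grid.radii()
        c = solve_oxygen((r < 0.3).astype(float), medium_grid, ModelParams(lam=0.0))
        assert np.nanmax(np.abs(c.values - 1.0)) == 0.0

    def test_rim_value_closed_form(self, fine_grid):
        r = fine_grid.radii()
        sink = np.clip((0.3 - r) / fine_grid.h + 0.5, 0, 1)
        c = solve_oxygen(sink, fine_grid, ModelParams(lam=1.15))
        i0 = fine_grid.shape[0] // 2
        assert c.values[i0 + 30, i0] == pytest.approx(0.9377, abs=2e-3)

    def test_radially_nonincreasing_inward(self, medium_grid):
        r = medium_grid.radii()
        c = solve_oxygen((r <= 0.3).astype(float), medium_grid, ModelParams(lam=1.0))
        i0 = medium_grid.shape[0] // 2
        ray = c.values[i0, i0:]
        ray = ray[np.isfinite(ray)]
        assert (np.diff(ray) >= -1e-12).all()

    def test_mean_field_core_pinned_at_threshold(self, medium_grid, pde_params):
        """Strong consumption: the obstacle clamps the core at kappa_death
        and the concentration never falls below it where cells live."""
        r = medium_grid.radii()
        rho = (r <= 0.4).astype(float)
        c = solve_oxygen(rho, medium_grid, pde_params.with_(lam=3.0),
                         mean_field=True)
        assert c.clamped is not None and c.clamped.any()
        assert np.nanmin(c.values[rho > 0]) >= pde_params.kappa_death - 1e-9
        assert c.values[c.clamped] == pytest.approx(pde_params.kappa_death,
                                                    abs=1e-9)

    def test_mean_field_matches_unconditional_when_oxygen_ample(
            self, medium_grid, pde_params):
        r = medium_grid.radii()
        rho = (r <= 0.15).astype(float)
        c1 = solve_oxygen(rho, medium_grid, pde_params)
        c2 = solve_oxygen(rho, medium_grid, pde_params, mean_field=True)
        assert np.nanmax(np.abs(c1.values - c2.values)) < 1e-10


class TestEdgeFlux:
    def test_basic_values(self, coarse_grid):
        from avtumor.fields import ScalarField

        vals = np.zeros(coarse_grid.shape)
        vals[10, 10] = 1.0
        f = ScalarField(values=vals, grid=coarse_grid)
        assert edge_flux(f, (10, 10), (10, 11)) == 1.0
        assert edge_flux(f, (10, 11), (10, 10)) == -1.0
        assert edge_flux(f, (5, 5), (5, 6)) == 0.0

    def test_non_adjacent_rejected(self, coarse_grid):
        from avtumor.fields import ScalarField

        f = ScalarField(values=np.zeros(coarse_grid.shape), grid=coarse_grid)
        with pytest.raises(ValueError):
            edge_flux(f, (3, 3), (5, 3))

    @given(data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_antisymmetry(self, data, coarse_grid):
        from avtumor.fields import ScalarField

        n = coarse_grid.shape[0]
        i = data.draw(st.tuples(st.integers(1, n - 2), st.integers(1, n - 2)))
        d = data.draw(st.sampled_from([(0, 1), (1, 0), (0, -1), (-1, 0)]))
        j = (i[0] + d[0], i[1] + d[1])
        vals = np.arange(n * n, dtype=float).reshape(n, n) ** 1.5
        f = ScalarField(values=vals, grid=coarse_grid)
        assert edge_flux(f, i, j) == -edge_flux(f, j, i)


class TestDivergenceConsistency:
    def test_total_rim_flux_equals_source_strength(self, medium_grid):
        """Discrete divergence theorem: the pressure flux out of the tumor
        equals the integrated source."""
        r = medium_grid.radii()
        tumor = r <= 0.25
        src = np.where(r <= 0.15, 1.0, 0.0) * tumor
        f = solve_pressure(src, tumor, medium_grid, ModelParams())
        h = medium_grid.h
        total_out = 0.0
        ti, tj = np.nonzero(tumor)
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = ti + di, tj + dj
            outside = ~tumor[ni, nj]
            pv = f.values
            flux = (pv[ti, tj] - pv[ni, nj])[outside]
            total_out += np.nansum(flux)
        assert total_out == pytest.approx(src.sum() * h**2 / 1.0, rel=1e-6)


class TestSpectralCurvature:
    def test_circle(self, medium_grid):
        r = medium_grid.radii()
        cont = extract_boundary((r <= 0.25).astype(float), medium_grid, blur=1.5)
        pts = cont.vertices[::4]
        cv = spectral_rim_curvature(cont, pts)
        assert cv.mean() == pytest.approx(4.0, rel=0.05)

    def test_perturbed_circle_tracks_analytic_curvature(self, medium_grid):
        X, Y = medium_grid.coords()
        r = np.hypot(X, Y)
        th = np.arctan2(Y, X)
        ind = (r <= 0.25 * (1 + 0.05 * np.cos(4 * th))).astype(float)
        cont = extract_boundary(ind, medium_grid, blur=2.0)
        pts = cont.vertices[::3]
        cv = spectral_rim_curvature(cont, pts, k_max=8)
        vth = np.arctan2(pts[:, 1], pts[:, 0])
        rr = 0.25 * (1 + 0.05 * np.cos(4 * vth))
        rp = -0.25 * 0.05 * 4 * np.sin(4 * vth)
        rpp = -0.25 * 0.05 * 16 * np.cos(4 * vth)
        exact = (rr**2 + 2 * rp**2 - rr * rpp) / (rr**2 + rp**2) ** 1.5
        rms = np.sqrt(((cv - exact) ** 2).mean())
        assert rms < 0.15 * (exact.max() - exact.min())


class TestExportField:
    def test_tsv_roundtrip(self, coarse_grid, tmp_path):
        import pandas as pd

        r = coarse_grid.radii()
        c = solve_oxygen((r <= 0.3).astype(float), coarse_grid,
                         ModelParams(lam=1.0))
        from avtumor.fields import export_field

        path = tmp_path / "c.tsv"
        export_field(c, path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["index", "x", "y", "value"]
        assert len(df) == int(np.isfinite(c.values).sum())
        assert df.value.max() <= 1.0 + 1e-12

    def test_png_written(self, coarse_grid, tmp_path):
        from avtumor.fields import export_field

        r = coarse_grid.radii()
        c = solve_oxygen((r <= 0.3).astype(float), coarse_grid,
                         ModelParams(lam=1.0))
        path = tmp_path / "c.png"
        export_field(c, path, fmt="png")
        assert path.stat().st_size > 1000
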