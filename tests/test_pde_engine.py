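"""Tests for the spatial discretisation and the explicit-Euler integrator."""

import numpy as np
import pytest

from pax6rd.model import FieldState
from pax6rd.pde import (
    DomainMask2D,
    Grid1D,
    SolverSettings,
    StabilityBoundError,
    integrate,
    laplacian_1d,
    laplacian_2d_masked,
)


class TestLaplacian1D:
    def test_constant_field_is_flat(self):
        for bc in ("zero_flux", "periodic"):
            assert np.allclose(laplacian_1d(np.full(32, 3.7), 0.1, bc), 0.0)

    def test_periodic_eigenfunction(self):
        n, L = 128, 1.0
        dx = L / n
        x = (np.arange(n) + 0.5) * dx
        f = np.sin(2 * np.pi * x / L)
        expected = -((2 * np.pi / L) ** 2) * f
        assert np.abs(laplacian_1d(f, dx, "periodic") - expected).max() < 0.01 * (2 * np.pi / L) ** 2

    def test_neumann_eigenfunction(self):
        n, L = 128, 1.0
        dx = L / n
        x = (np.arange(n) + 0.5) * dx
        f = np.cos(np.pi * x / L)
        expected = -((np.pi / L) ** 2) * f
        assert np.abs(laplacian_1d(f, dx, "zero_flux") - expected).max() < 0.01 * (np.pi / L) ** 2

    def test_zero_flux_conserves_mass(self, rng):
        f = rng.random(50)
        assert abs(laplacian_1d(f, 0.2, "zero_flux").sum()) < 1e-11

    def test_too_short_field_rejected(self):
        with pytest.raises(ValueError):
            laplacian_1d(np.ones(2), 0.1, "zero_flux")


def _blob_mask(ny=9, nx=12):
    mask = np.zeros((ny, nx), bool)
    mask[2:7, 2:10] = True
    mask[1, 4:8] = True
    return mask


class TestLaplacian2DMasked:
    def test_constant_field_zero_inside(self):
        mask = _blob_mask()
        out = laplacian_2d_masked(np.full(mask.shape, 2.5), 0.1, mask)
        assert np.allclose(out, 0.0)

    def test_zero_outside_mask(self, rng):
        mask = _blob_mask()
        out = laplacian_2d_masked(rng.random(mask.shape), 0.1, mask)
        assert np.all(out[~mask] == 0.0)

    def test_mass_conserved(self, rng):
        mask = _blob_mask()
        out = laplacian_2d_masked(rng.random(mask.shape), 0.1, mask)
        assert abs(out[mask].sum()) < 1e-10

    def test_matches_dense_operator_matrix(self, rng):
        """Independent oracle: assemble the masked Neumann Laplacian densely."""
        mask = _blob_mask()
        dx = 0.3
        idx = {tuple(p): i for i, p in enumerate(np.argwhere(mask))}
        n = len(idx)
        A = np.zeros((n, n))
        for (r, c), i in idx.items():
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                j = idx.get((rr, cc))
                if j is not None:
                    A[i, j] += 1.0
                    A[i, i] -= 1.0
        A /= dx * dx
        f = rng.random(mask.shape)
        expected = A @ f[mask]
        out = laplacian_2d_masked(f, dx, mask)
        assert np.abs(out[mask] - expected).max() < 1e-12

    def test_disconnected_mask_rejected(self):
        mask = np.zeros((8, 8), bool)
        mask[1:3, 1:3] = True
        mask[5:7, 5:7] = True
        with pytest.raises(ValueError, match="connected"):
            laplacian_2d_masked(np.ones(mask.shape), 0.1, mask)


class TestIntegrate:
    def test_no_dynamics_preserves_state_exactly(self, simple_params):
        p = simple_params.replace(
            rho_P=0, sigma_P=0, rho_F=0, rho_T=0, delta_P=0, delta_F=0,
            delta_T=0, delta_C=0, k_on=0, k_off=0, k_b=0, k_u=0,
            D_F=0, D_T=0, D_C=0,
        )
        grid = Grid1D(n_points=16, dx=0.1)
        init = FieldState.uniform([1.0, 0.5, 0.25, 0.1, 0.05], grid.shape)
        init.P += np.linspace(0, 0.1, 16)
        res = integrate(p, init, grid, settings=SolverSettings(t_end=1.0, dt=0.01))
        assert np.array_equal(res.final_state.stack(), init.stack())

    def test_pure_diffusion_relaxes_to_mean_and_conserves_mass(self, simple_params, rng):
        p = simple_params.replace(
            rho_P=0, sigma_P=0, rho_F=0, rho_T=0, delta_P=0, delta_F=0,
            delta_T=0, delta_C=0, k_on=0, k_off=0, k_b=0, k_u=0, D_F=0.5,
        )
        grid = Grid1D(n_points=32, dx=0.1)
        f0 = rng.random(32)
        init = FieldState(np.zeros(32), f0.copy(), np.zeros(32), np.zeros(32), np.zeros(32))
        res = integrate(p, init, grid, settings=SolverSettings(t_end=50.0))
        final = res.final_state.F
        assert abs(final.sum() - f0.sum()) < 1e-8 * f0.sum()
        assert np.abs(final - f0.mean()).max() < 1e-4

    def test_masked_diffusion_conserves_mass(self, simple_params, rng):
        p = simple_params.replace(
            rho_P=0, sigma_P=0, rho_F=0, rho_T=0, delta_P=0, delta_F=0,
            delta_T=0, delta_C=0, k_on=0, k_off=0, k_b=0, k_u=0,
        )
        mask = _blob_mask()
        geo = DomainMask2D(mask=mask, dx=0.1)
        F0 = np.where(mask, rng.random(mask.shape), 0.0)
        init = FieldState(*(np.zeros(mask.shape) if i != 1 else F0 for i in range(5)))
        res = integrate(p, init, geo, settings=SolverSettings(t_end=5.0))
        assert res.final_state.F[mask].sum() == pytest.approx(F0.sum(), rel=1e-10)

    def test_stability_bound_enforced(self, simple_params):
        grid = Grid1D(n_points=16, dx=0.05)
        init = FieldState.uniform([1, 0, 0, 0, 0], grid.shape)
        # dx^2/(4*D_C) = 0.000625 with D_C=1
        with pytest.raises(StabilityBoundError):
            integrate(
                simple_params, init, grid,
                settings=SolverSettings(t_end=1.0, dt=0.01),
            )

    def test_determinism_hash_equality(self, simple_params):
        grid = Grid1D(n_points=24, dx=0.2)
        rng = np.random.default_rng(7)
        init = FieldState.uniform([1.0, 0.3, 0.3, 0.1, 0.2], grid.shape)
        init.P *= 1 + 0.05 * rng.uniform(-1, 1, 24)
        settings = SolverSettings(t_end=2.0, snapshot_interval=0.5, rng_seed=7)
        r1 = integrate(simple_params, init, grid, settings=settings)
        r2 = integrate(simple_params, init.copy(), grid, settings=settings)
        assert r1.content_hash() == r2.content_hash()

    def test_snapshots_timestamped_and_first_equals_ic(self, simple_params):
        grid = Grid1D(n_points=16, dx=0.2)
        init = FieldState.uniform([1.0, 0.3, 0.3, 0.1, 0.2], grid.shape)
        res = integrate(
            simple_params, init, grid,
            settings=SolverSettings(t_end=1.0, snapshot_interval=0.25),
        )
        assert np.all(np.diff(res.times) > 0)
        assert np.array_equal(res.snapshots[0], init.stack())
        assert res.times[0] == 0.0

    def test_receptor_conservation_is_structural(self, simple_params):
        """B stays in [0, R_tot]: free + bound receptors always total R_tot."""
        grid = Grid1D(n_points=16, dx=0.2)
        init = FieldState.uniform([2.0, 0.1, 2.0, 0.0, 0.0], grid.shape)
        res = integrate(simple_params, init, grid, settings=SolverSettings(t_end=20.0))
        B = res.snapshots[:, 4]
        assert B.min() >= 0.0
        assert B.max() <= simple_params.R_tot + 1e-9

    def test_mass_action_closure_without_sources(self, simple_params):
        """With production/decay off, F+C and T+C+B are conserved pointwise."""
        p = simple_params.replace(
            rho_P=0, sigma_P=0, rho_F=0, rho_T=0,
            delta_P=0, delta_F=0, delta_T=0, delta_C=0,
            D_F=0, D_T=0, D_C=0,
        )
        grid = Grid1D(n_points=8, dx=0.2)
        rng = np.random.default_rng(3)
        init = FieldState(
            np.ones(8), rng.random(8), rng.random(8), 0.1 * rng.random(8), 0.2 * rng.random(8)
        )
        res = integrate(p, init, grid, settings=SolverSettings(t_end=10.0, dt=1e-3))
        f0 = init.F + init.C
        t0 = init.T + init.C + init.B
        fin = res.final_state
        assert np.abs((fin.F + fin.C) - f0).max() < 1e-6 * f0.max()
        assert np.abs((fin.T + fin.C + fin.B) - t0).max() < 1e-6 * t0.max()


class TestGeometryTypes:
    def test_grid_length(self):
        g = Grid1D(n_points=50, dx=0.2)
        assert g.length == pytest.approx(10.0)

    def test_bad_boundary_rejected(self):
        with pytest.raises(ValueError):
            Grid1D(n_points=10, dx=0.1, boundary="dirichlet")

    def test_mask_must_be_connected(self):
        mask = np.zeros((6, 6), bool)
        mask[0:2, 0:2] = True
        mask[4:6, 4:6] = True
        with pytest.raises(ValueError, match="connected"):
            DomainMask2D(mask=mask, dx=0.1)


class TestBoundaryConditionEquivalence:
    def test_interior_pattern_agrees_between_zero_flux_and_periodic(self, reference_params):
        """A perturbation far from the edges of a large domain evolves
        identically (to tolerance) under zero-flux and periodic boundaries."""
        from pax6rd.model import homogeneous_steady_state

        ss = homogeneous_steady_state(reference_params, variant="B")
        n, L = 192, 7.44
        values = [float(np.asarray(getattr(ss, s))[0]) for s in "PFTCB"]
        x = (np.arange(n) + 0.5) * (L / n)
        bump = 0.05 * np.exp(-((x - L / 2) ** 2) / 0.05)
        finals = {}
        for bc in ("zero_flux", "periodic"):
            grid = Grid1D(n_points=n, dx=L / n, boundary=bc)
            init = FieldState.uniform(values, grid.shape)
            init.P = init.P * (1 + bump)
            res = integrate(
                reference_params, init, grid, variant="B",
                settings=SolverSettings(t_end=30.0, snapshot_interval=30.0),
            )
            finals[bc] = res.final_state.stack()
        interior = slice(n // 4, 3 * n // 4)
        diff = np.abs(finals["zero_flux"][:, interior] - finals["periodic"][:, interior]).max()
        assert diff < 1e-6 * np.abs(finals["periodic"][:, interior]).max()
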