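"""Magnetostatic interaction kernel and self-consistent magnetization solve."""

import numpy as np
import pytest

import mearray as m
from mearray.geometry import build_array
from mearray.magnetostatics import (
    ConvergenceError,
    assemble_interaction,
    build_grid,
    dipole_field_tensor,
    flux_concentration_ratio,
    mean_flux_density,
    prism_field_tensor,
    solve_magnetization,
)
from mearray.sources import MU0


def _numeric_prism_field(Mvec, half, pt, n=200):
    """Brute-force oracle: surface-charge integration over the six faces
    of a uniformly magnetized prism."""
    H = np.zeros(3)
    for ax in range(3):
        if Mvec[ax] == 0:
            continue
        axes = [k for k in range(3) if k != ax]
        u = np.linspace(-half[axes[0]], half[axes[0]], n + 1)
        v = np.linspace(-half[axes[1]], half[axes[1]], n + 1)
        u = 0.5 * (u[1:] + u[:-1])
        v = 0.5 * (v[1:] + v[:-1])
        dA = (2 * half[axes[0]] / n) * (2 * half[axes[1]] / n)
        U, V = np.meshgrid(u, v, indexing="ij")
        for s, pos in ((1.0, half[ax]), (-1.0, -half[ax])):
            src = np.zeros((n, n, 3))
            src[..., axes[0]] = U
            src[..., axes[1]] = V
            src[..., ax] = pos
            d = pt[None, None, :] - src
            r = np.linalg.norm(d, axis=-1, keepdims=True)
            H += (s * Mvec[ax] / (4 * np.pi) * d / r**3 * dA).sum(axis=(0, 1))
    return H


class TestKernel:
    def test_cube_self_term_is_one_third(self):
        K = prism_field_tensor(np.zeros((1, 3)), (0.5, 0.5, 0.5))[0]
        np.testing.assert_allclose(K, -np.eye(3) / 3, atol=1e-14)

    def test_trace_is_minus_one_inside(self):
        # point-demagnetizing tensor has unit trace anywhere inside
        K = prism_field_tensor(np.array([[0.1, -0.2, 0.05]]), (0.5, 0.4, 0.3))[0]
        assert np.trace(K) == pytest.approx(-1.0, abs=1e-12)

    def test_trace_is_zero_outside(self):
        K = prism_field_tensor(np.array([[1.5, 0.3, -0.2]]), (0.5, 0.4, 0.3))[0]
        assert np.trace(K) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "d,M",
        [
            ((0.0, 0.0, 0.0), (1.0, 0.0, 0.0)),
            ((0.3, 0.1, 0.8), (0.2, -1.0, 0.5)),
            ((1.2, -0.7, 0.4), (1.0, 1.0, 1.0)),
        ],
    )
    def test_against_numeric_integration_oracle(self, d, M):
        half = (0.5, 0.35, 0.25)
        K = prism_field_tensor(np.array([d]), half)[0]
        H_numeric = _numeric_prism_field(np.array(M), np.array(half), np.array(d), n=400)
        np.testing.assert_allclose(K @ np.array(M), H_numeric, rtol=2e-4, atol=2e-5)

    def test_far_field_matches_point_dipole(self):
        # flat MS-like cell probed at 20x its largest edge
        half = np.array([0.5e-3, 0.15e-3, 10e-6])
        d = np.array([[20e-3, 8e-3, 5e-3]])
        Kp = prism_field_tensor(d, half)[0]
        Kd = dipole_field_tensor(d, float(np.prod(2 * half)))[0]
        M = np.array([1.0, 0.4, -0.2])
        rel = np.linalg.norm((Kp - Kd) @ M) / np.linalg.norm(Kp @ M)
        assert rel < 1e-3

    def test_symmetric_in_displacement(self):
        half = (0.5e-3, 0.15e-3, 10e-6)
        d = np.array([[3e-3, -2e-3, 1e-3]])
        K1 = prism_field_tensor(d, half)[0]
        K2 = prism_field_tensor(-d, half)[0]
        np.testing.assert_allclose(K1, K2, rtol=1e-9)


class TestOperator:
    def test_zero_magnetization_gives_zero_field(self):
        layout = build_array(1, 2, 5e-3)
        grid = build_grid(layout, (4, 2, 1))
        op = assemble_interaction(grid)
        np.testing.assert_array_equal(op.apply(np.zeros((grid.n_cells, 3))), 0.0)

    def test_coincident_centers_rejected(self):
        layout = build_array(1, 1, 5e-3)
        grid = build_grid(layout, (4, 2, 1))
        from dataclasses import replace

        bad = replace(grid, centers=np.vstack([grid.centers, grid.centers[:1]]),
                      chi=np.append(grid.chi, 1.0),
                      layer_of=np.append(grid.layer_of, 0))
        with pytest.raises(ValueError, match="coincident"):
            assemble_interaction(bad)

    def test_hybrid_far_kernel_close_to_exact(self):
        layout = build_array(1, 2, 10e-3)
        grid = build_grid(layout, (6, 2, 1))
        exact = assemble_interaction(grid).matrix
        hybrid = assemble_interaction(grid, dipole_cutoff=8.0).matrix
        # identical near-field, tiny far-field perturbation
        assert np.abs(hybrid - exact).max() / np.abs(exact).max() < 1e-4


class TestSolve:
    def test_sphere_recovers_analytic_demagnetizing_factor(self):
        """A chi-susceptible discretized sphere in a uniform field must
        recover mean M = 3 chi/(3+chi) H (demagnetizing factor 1/3),
        with the error shrinking under grid refinement."""
        chi = 4.0
        exact = 3 * chi / (3 + chi)
        errs = {}
        for n in (6, 12):
            size = 2.0 / n
            g = (np.arange(n) + 0.5) * size - 1.0
            c = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
            c = c[np.linalg.norm(c, axis=1) <= 1.0]
            from mearray.magnetostatics import MagnetizationGrid

            grid = MagnetizationGrid(
                centers=c,
                half=np.full(3, size / 2),
                chi=np.full(len(c), chi),
                layer_of=np.zeros(len(c), dtype=int),
                labels=("sphere",),
                resolution=(n, n, n),
            )
            sol = solve_magnetization(grid, lambda p: np.tile([1.0, 0.0, 0.0], (len(p), 1)))
            errs[n] = abs(sol.M[:, 0].mean() / exact - 1)
        assert errs[12] < 0.02
        assert errs[12] < errs[6]

    def test_chi_zero_reproduces_applied_field(self):
        layout = build_array(2, 2, 5e-3)
        grid = build_grid(layout, (6, 2, 1)).with_chi(0.0)
        sol = solve_magnetization(grid, lambda p: np.tile([1.0, 0.0, 0.0], (len(p), 1)))
        np.testing.assert_allclose(sol.B, MU0 * np.tile([1.0, 0, 0], (grid.n_cells, 1)), rtol=1e-15)
        assert mean_flux_density(sol, "S_1,1", "x") == pytest.approx(1.2566e-6, rel=1e-4)

    def test_distant_neighbor_barely_perturbs(self):
        def mean_bx(cols):
            layout = build_array(1, cols, 50e-3)
            sol = solve_magnetization(
                layout, lambda p: np.tile([1.0, 0.0, 0.0], (len(p), 1)), resolution=(12, 3, 1)
            )
            return mean_flux_density(sol, "S_1,1", "x")

        assert abs(mean_bx(2) / mean_bx(1) - 1) < 0.01

    def test_solution_linear_in_source(self):
        layout = build_array(1, 2, 5e-3)
        grid = build_grid(layout, (6, 2, 1))
        op = assemble_interaction(grid)
        s1 = solve_magnetization(grid, lambda p: np.tile([1.0, 0, 0], (len(p), 1)), operator=op)
        s2 = solve_magnetization(grid, lambda p: np.tile([2.0, 0, 0], (len(p), 1)), operator=op)
        np.testing.assert_allclose(s2.M, 2 * s1.M, rtol=1e-12)
        np.testing.assert_allclose(s2.B, 2 * s1.B, rtol=1e-12)

    def test_fixed_point_agrees_with_direct(self):
        layout = build_array(1, 2, 5e-3)
        grid = build_grid(layout, (6, 2, 1)).with_chi(50.0)
        op = assemble_interaction(grid)
        field = lambda p: np.tile([1.0, 0, 0], (len(p), 1))
        d = solve_magnetization(grid, field, operator=op)
        fp = solve_magnetization(grid, field, operator=op, method="fixed_point", tol=1e-12)
        np.testing.assert_allclose(fp.M, d.M, rtol=1e-6)

    def test_fixed_point_non_convergence_reports_residual(self):
        layout = build_array(1, 2, 5e-3)
        grid = build_grid(layout, (6, 2, 1))
        op = assemble_interaction(grid)
        with pytest.raises(ConvergenceError) as err:
            solve_magnetization(
                grid,
                lambda p: np.tile([1.0, 0, 0], (len(p), 1)),
                operator=op,
                method="fixed_point",
                max_iter=3,
            )
        assert err.value.residual > 0

    def test_non_finite_applied_field_rejected(self):
        layout = build_array(1, 1, 5e-3)
        with pytest.raises(ValueError, match="finite"):
            solve_magnetization(
                layout, lambda p: np.full((len(p), 3), np.inf), resolution=(4, 2, 1)
            )


@pytest.fixture(scope="module")
def solved_pair():
    layout = build_array(1, 1, 5e-3)
    grid = build_grid(layout, (8, 2, 1))
    op = assemble_interaction(grid)
    field = lambda p: np.tile([1.0, 0.0, 0.0], (len(p), 1))
    sensor = solve_magnetization(grid, field, operator=op)
    airref = solve_magnetization(grid.with_chi(0.0), field, operator=op)
    return sensor, airref


class TestObservables:
    def test_zero_applied_field_means_zero(self):
        layout = build_array(1, 1, 5e-3)
        sol = solve_magnetization(
            layout, lambda p: np.zeros((len(p), 3)), resolution=(4, 2, 1)
        )
        assert mean_flux_density(sol, "S_1,1", "x") == 0.0

    def test_unknown_layer_rejected(self, solved_pair):
        with pytest.raises(KeyError):
            mean_flux_density(solved_pair[0], "S_9,9")

    def test_concentration_unity_for_air(self, solved_pair):
        _, airref = solved_pair
        assert flux_concentration_ratio(airref, airref, "S_1,1") == pytest.approx(1.0)

    def test_concentration_monotone_in_chi(self):
        layout = build_array(1, 1, 5e-3)
        grid = build_grid(layout, (8, 2, 1))
        op = assemble_interaction(grid)
        field = lambda p: np.tile([1.0, 0.0, 0.0], (len(p), 1))
        airref = solve_magnetization(grid.with_chi(0.0), field, operator=op)
        ratios = [
            flux_concentration_ratio(
                solve_magnetization(grid.with_chi(chi), field, operator=op), airref, "S_1,1"
            )
            for chi in (10.0, 100.0, 1000.0)
        ]
        assert ratios[0] > 1.0
        assert ratios[0] < ratios[1] < ratios[2]

    def test_mismatched_grids_rejected(self, solved_pair):
        sensor, _ = solved_pair
        layout = build_array(1, 1, 5e-3)
        other = solve_magnetization(
            layout, lambda p: np.tile([1.0, 0, 0], (len(p), 1)), resolution=(4, 2, 1)
        )
        with pytest.raises(ValueError, match="grids"):
            flux_concentration_ratio(sensor, other, "S_1,1")
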