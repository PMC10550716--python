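"""Finite-difference solver: oracles, conservation, limits, averaging."""

import numpy as np
import pytest

import morphogrid as mg
from morphogrid.fd_solver import assemble_operator, grid_coordinates

from conftest import dense_reference_solution


def small_config(**kw):
    base = dict(
        n_source_cols=1, n_pattern_cols=2, n_rows=3, delta_x=5.0, delta_y=5.0,
        n_realizations=4, seed=42,
    )
    base.update(kw)
    return mg.make_config(base)


class TestOracleEquivalence:
    @pytest.mark.parametrize(
        "kw",
        [
            {},
            {"bc_y": "periodic"},
            {"alpha": 2.5},
            {"delta_y": 2.0, "bc_y": "periodic", "alpha": 0.4},
            {"n_rows": 1},
            {"n_source_cols": 2, "n_pattern_cols": 3, "n_rows": 5},
        ],
        ids=["zero-flux", "periodic", "orthotropic", "anisotropic-cells", "single-row", "5x5"],
    )
    def test_sparse_solve_matches_dense_brute_force(self, kw):
        cfg = small_config(**kw)
        kin = mg.sample_kinetics(cfg, 1)
        field = mg.solve_steady_state(cfg, kin)
        ref = dense_reference_solution(cfg, kin)
        assert np.allclose(field.grid_values.ravel(), ref, rtol=1e-10, atol=0.0)

    def test_one_dimensional_tridiagonal_oracle(self):
        # single grid row: operator must equal the hand-built 1D stencil
        cfg = small_config(n_rows=1, points_per_cell=1, n_pattern_cols=6)
        kin = mg.sample_kinetics(cfg, 0)
        A, b = assemble_operator(cfg, kin)
        n = cfg.n_cols
        h = cfg.delta_x
        ref = np.zeros((n, n))
        rhs = np.zeros(n)
        for i in range(n):
            ref[i, i] = kin.d[0, i]
            if i < cfg.n_source_cols:
                rhs[i] = kin.p[0, i]
            for ii in (i - 1, i + 1):
                if 0 <= ii < n:
                    w = 2 * kin.D[0, i] * kin.D[0, ii] / (kin.D[0, i] + kin.D[0, ii]) / h**2
                    ref[i, i] += w
                    ref[i, ii] -= w
        assert np.allclose(A.toarray(), ref)
        assert np.array_equal(b, rhs)

    @pytest.mark.parametrize("bc_y", ["zero-flux", "periodic"])
    def test_diffusion_conserves_mass(self, bc_y):
        # pure-diffusion row sums vanish: A @ 1 = degradation coefficients
        cfg = small_config(n_rows=4, bc_y=bc_y)
        kin = mg.sample_kinetics(cfg, 2)
        A, _ = assemble_operator(cfg, kin)
        m = cfg.points_per_cell
        d_grid = np.repeat(np.repeat(kin.d, m, axis=0), m, axis=1).ravel()
        assert np.allclose(A @ np.ones(A.shape[0]), d_grid, rtol=1e-12)


class TestDeterministicLimit:
    def test_matches_analytic_cosh_profile(self, noise_free_config):
        cfg = noise_free_config
        field = mg.solve_steady_state(cfg, mg.sample_kinetics(cfg, 0))
        avgs = field.cell_averages[cfg.middle_row, cfg.n_source_cols:]
        ana = mg.analytic_steady_state(cfg, cfg.pattern_cell_centers)
        assert np.max(np.abs(avgs / ana - 1)) < 0.01

    def test_grid_refinement_reduces_error(self):
        errs = []
        for ppc in (3, 6):
            cfg = mg.make_config(cv_p=0.0, cv_d=0.0, cv_D=0.0, points_per_cell=ppc)
            field = mg.solve_steady_state(cfg, mg.sample_kinetics(cfg, 0))
            avgs = field.cell_averages[0, cfg.n_source_cols:]
            # compare against the analytic profile averaged over the same cells
            xc = cfg.pattern_cell_centers
            ana = np.array(
                [
                    np.mean(mg.analytic_steady_state(cfg, x + np.linspace(-2.5, 2.5, 201)))
                    for x in xc
                ]
            )
            errs.append(np.max(np.abs(avgs / ana - 1)))
        assert errs[1] < errs[0]

    def test_source_plateau_approaches_production_balance(self):
        # deep inside a long source, C -> p/d
        cfg = mg.make_config(
            n_source_cols=30, n_pattern_cols=5, cv_p=0.0, cv_d=0.0, cv_D=0.0
        )
        field = mg.solve_steady_state(cfg, mg.sample_kinetics(cfg, 0))
        assert field.cell_averages[0, 0] == pytest.approx(cfg.mu_p / cfg.mu_d, rel=1e-3)

    @pytest.mark.parametrize("bc_y", ["zero-flux", "periodic"])
    def test_transverse_invariance(self, bc_y):
        cfg = mg.make_config(n_rows=4, cv_p=0.0, cv_d=0.0, cv_D=0.0, bc_y=bc_y)
        field = mg.solve_steady_state(cfg, mg.sample_kinetics(cfg, 0))
        assert np.ptp(field.grid_values, axis=0).max() < 1e-10 * field.grid_values.max()

    def test_bc_choice_irrelevant_without_noise(self):
        fields = []
        for bc in ("zero-flux", "periodic"):
            cfg = mg.make_config(n_rows=4, cv_p=0.0, cv_d=0.0, cv_D=0.0, bc_y=bc)
            fields.append(mg.solve_steady_state(cfg, mg.sample_kinetics(cfg, 0)))
        assert np.allclose(fields[0].grid_values, fields[1].grid_values)


class TestSolverProperties:
    @pytest.mark.parametrize("index", [0, 1, 2])
    def test_positivity(self, index):
        cfg = small_config(n_rows=4, n_pattern_cols=5)
        field = mg.solve_steady_state(cfg, mg.sample_kinetics(cfg, index))
        assert field.grid_values.min() > 0

    def test_amplitude_scale_equivariance(self):
        cfg1 = small_config(n_pattern_cols=5)
        cfg2 = cfg1.with_overrides(mu_p=10.0 * cfg1.mu_p)
        f1 = mg.solve_steady_state(cfg1, mg.sample_kinetics(cfg1, 1))
        f2 = mg.solve_steady_state(cfg2, mg.sample_kinetics(cfg2, 1))
        assert np.allclose(f2.grid_values, 10.0 * f1.grid_values, rtol=1e-9)

    def test_cg_matches_direct(self):
        cfg = small_config(n_rows=2, n_pattern_cols=4)
        kin = mg.sample_kinetics(cfg, 3)
        direct = mg.solve_steady_state(cfg, kin, method="direct")
        cg = mg.solve_steady_state(cfg, kin, method="cg")
        assert np.allclose(direct.grid_values, cg.grid_values, rtol=1e-7)

    def test_kinetics_shape_mismatch_raises(self):
        cfg = small_config()
        kin = mg.sample_kinetics(small_config(n_rows=2), 0)
        with pytest.raises(ValueError, match="shape"):
            mg.solve_steady_state(cfg, kin)


class TestCellAverage:
    def test_constant_field(self):
        cfg = small_config(n_rows=2)
        grid = np.full((6, 9), 3.7)
        assert np.allclose(mg.cell_average(grid, cfg), 3.7)

    def test_linear_field_equals_center_column(self):
        # 3x3 blocks are symmetric about the cell center
        cfg = small_config(n_rows=1)
        x, _ = grid_coordinates(cfg)
        grid = np.tile(2.0 * x + 1.0, (3, 1))
        centers = cfg.x_cell_edges[:-1] + cfg.delta_x / 2
        assert np.allclose(mg.cell_average(grid, cfg), 2.0 * centers + 1.0)

    def test_cosh_field_matches_explicit_summation(self):
        cfg = small_config(n_rows=2, n_pattern_cols=4)
        x, y = grid_coordinates(cfg)
        grid = np.cosh((50.0 - x[None, :]) / 17.0) * (1.0 + 0.1 * y[:, None])
        avg = mg.cell_average(grid, cfg)
        m = cfg.points_per_cell
        for r in range(cfg.n_rows):
            for c in range(cfg.n_cols):
                block = [
                    grid[r * m + jj, c * m + ii] for jj in range(m) for ii in range(m)
                ]
                assert avg[r, c] == pytest.approx(sum(block) / len(block))
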