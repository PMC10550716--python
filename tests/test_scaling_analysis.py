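"""Sweep orchestration, square-root law fitting, and scenario configs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import morphogrid as mg
from morphogrid.scaling_analysis import _derive_seed


class TestFitSqrtLaw:
    def test_exact_recovery(self):
        x = np.array([1.0, 2.0, 4.0, 9.0, 16.0])
        fit = mg.fit_sqrt_law(x, 0.03 / np.sqrt(x), with_intercept=True)
        assert fit.prefactor == pytest.approx(0.03, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_without_intercept(self):
        x = np.array([1.0, 4.0, 16.0])
        fit = mg.fit_sqrt_law(x, 1.2 / np.sqrt(x), with_intercept=False)
        assert fit.prefactor == pytest.approx(1.2, abs=1e-12)
        assert fit.intercept == 0.0

    def test_weighted_fit_matches_on_exact_data(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        y = 0.5 / np.sqrt(x) + 0.01
        fit = mg.fit_sqrt_law(x, y, weights=np.array([1.0, 2.0, 3.0, 4.0]))
        assert fit.prefactor == pytest.approx(0.5, abs=1e-10)

    def test_degenerate_design_raises(self):
        with pytest.raises(ValueError):
            mg.fit_sqrt_law([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            mg.fit_sqrt_law([1.0, 2.0], [1.0, 0.7])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        a=st.floats(min_value=1e-3, max_value=10.0),
        c=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_recovers_arbitrary_parameters_from_exact_data(self, a, c):
        x = np.array([1.0, 3.0, 7.0, 12.0, 30.0])
        fit = mg.fit_sqrt_law(x, a / np.sqrt(x) + c)
        assert fit.prefactor == pytest.approx(a, rel=1e-9, abs=1e-9)
        assert fit.intercept == pytest.approx(c, rel=1e-9, abs=1e-9)


class TestWidthSweep:
    def test_noise_free_sweep_is_exactly_reproducible(self):
        base = mg.make_config(cv_p=0.0, cv_d=0.0, cv_D=0.0, n_realizations=2)
        sweep = mg.run_width_sweep(base, widths=(1,), targets=(3.0,), n_boot=50)
        rec = sweep.records[0]
        assert rec["cv_lambda"] == 0.0
        assert rec["sigma_x"] == 0.0

    def test_widths_must_ascend(self, default_config):
        with pytest.raises(ValueError):
            mg.run_width_sweep(default_config, widths=(4, 2))

    def test_cv_halves_per_quadrupled_width(self):
        """1/sqrt(Ny): widening 1 -> 4 -> 16 halves CV_lambda each step."""
        base = mg.make_config(n_realizations=120, seed=6)
        sweep = mg.run_width_sweep(base, widths=(1, 4, 16), targets=(), n_boot=100)
        cv = sweep.to_frame().set_index("n_rows")["cv_lambda"]
        assert cv[1] / cv[4] == pytest.approx(2.0, rel=0.25)
        assert cv[4] / cv[16] == pytest.approx(2.0, rel=0.3)


class TestAspectAndAnisotropy:
    def test_unit_ratio_reproduces_base_geometry(self):
        base = mg.make_config(n_rows=4, n_pattern_cols=20, n_realizations=10, seed=2)
        sweep, _ = mg.run_aspect_ratio_sweep(base, "fixed-dx", (1.0,), targets=(3.0,))
        rec = sweep.records[0]
        assert rec["delta_x"] == rec["delta_y"] == base.delta_x
        assert rec["n_rows"] == base.n_rows

    def test_invalid_mode_and_ratio(self, default_config):
        with pytest.raises(ValueError):
            mg.run_aspect_ratio_sweep(default_config, "fixed-Ly", (1.0,))
        with pytest.raises(ValueError):
            mg.run_aspect_ratio_sweep(default_config, "fixed-dx", (-1.0,))

    def test_single_row_is_alpha_independent(self):
        """With one cell row, kinetics are y-uniform, so alpha cannot matter."""
        for alpha in (1.0, 7.0):
            cfg = mg.make_config(n_rows=1, n_pattern_cols=20, alpha=alpha, seed=4)
            field = mg.solve_steady_state(cfg, mg.sample_kinetics(cfg, 0))
            if alpha == 1.0:
                ref = field.grid_values
            else:
                assert np.allclose(field.grid_values, ref, rtol=1e-9)

    def test_alpha_values_validated(self, default_config):
        with pytest.raises(ValueError):
            mg.run_anisotropy_sweep(default_config, (0.0, 1.0))


class TestWingDisc:
    def test_config_relations(self):
        cfg = mg.wing_disc_config(100.0, n_rows=10)
        assert cfg.delta_x == pytest.approx(5.1 - 1.2)
        assert cfg.mean_decay_length == pytest.approx(11.0)
        # cell counts tile the prescribed source and pouch lengths
        assert cfg.n_pattern_cols == round(100.0 / cfg.delta_x)
        assert cfg.n_source_cols == round(16.0 / cfg.delta_x)
        assert cfg.delta_y == cfg.delta_x

    def test_oversized_pouch_rejected(self):
        with pytest.raises(mg.ConfigurationError):
            mg.wing_disc_config(500.0, n_rows=1)


def test_derived_seeds_are_distinct_and_bounded():
    seeds = {_derive_seed(0, k) for k in range(200)}
    assert len(seeds) == 200
    assert all(0 <= s < 2**31 for s in seeds)


def test_sweep_tables_written(tmp_path):
    base = mg.make_config(cv_p=0.0, cv_d=0.0, cv_D=0.0, n_realizations=2)
    sweep = mg.run_width_sweep(base, widths=(1, 2, 3), targets=(3.0,), n_boot=20)
    fits = {"cv_lambda": mg.fit_width_scaling(sweep, "cv_lambda")}
    from morphogrid.scaling_analysis import write_sweep_tables

    write_sweep_tables(sweep, tmp_path, fits)
    assert (tmp_path / "sweep_n_rows.csv").exists()
    assert (tmp_path / "scaling_fits_n_rows.json").exists()
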