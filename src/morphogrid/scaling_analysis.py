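"""Ensemble sweeps and square-root scaling-law fits.

Runs full sample -> solve -> fit -> readout pipelines over ensembles of
noisy gradients and sweeps the tissue geometry: the number of cell rows
Ny, the cell aspect ratio delta_x/delta_y (at fixed delta_x or fixed
cell area), and the diffusion orthotropy alpha = Dy/Dx. Gradient
variability and positional error follow inverse-square-root laws in
these variables; ``fit_sqrt_law`` fits y = a / sqrt(x) + c and reports
the prefactor with standard errors.

A scenario runner parameterizes the growing Drosophila wing-disc pouch,
where the Dpp gradient and source scale with the patterning domain
(decay length 0.11 Lp, source length 0.16 Lp, cell diameter shrinking
as 5.1 um - 0.012 Lp) and the readout sits at 40% of the pouch length.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .fd_solver import solve_steady_state
from .gradient_fit import (
    EnsembleStats,
    GradientFitResult,
    ensemble_gradient_stats,
    fit_row_profile,
)
from .readout_stats import (
    PositionalErrorStats,
    ReadoutResult,
    choose_threshold,
    deterministic_cell_profile,
    find_readout_position,
    positional_error,
)
from .tissue_model import ConfigurationError, SimulationConfig, make_config, sample_kinetics

__all__ = [
    "DEFAULT_WIDTHS",
    "DEFAULT_TARGETS",
    "EnsembleResult",
    "SweepResult",
    "ScalingFit",
    "run_ensemble",
    "run_width_sweep",
    "fit_sqrt_law",
    "fit_width_scaling",
    "run_aspect_ratio_sweep",
    "run_anisotropy_sweep",
    "wing_disc_config",
    "run_wing_disc_scenario",
    "write_sweep_tables",
]

logger = logging.getLogger(__name__)

# log-spaced width grid resolving both the power-law regime and saturation
DEFAULT_WIDTHS: tuple[int, ...] = (1, 2, 3, 4, 6, 8, 10, 14, 20, 28, 40)
DEFAULT_TARGETS: tuple[float, ...] = (3.0, 6.0, 9.0)


@dataclass(frozen=True)
class EnsembleResult:
    """Statistics of one ensemble of noisy gradients."""

    config: SimulationConfig
    gradient_stats: EnsembleStats | None
    positional: dict[float, PositionalErrorStats]
    thresholds: dict[float, float]
    fits: list[GradientFitResult] = field(default_factory=list, repr=False)
    readouts: dict[float, list[ReadoutResult]] = field(default_factory=dict, repr=False)


@dataclass(frozen=True)
class SweepResult:
    """Per-point ensemble statistics of a geometry or kinetics sweep."""

    variable: str
    values: tuple
    records: list[dict]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


@dataclass(frozen=True)
class ScalingFit:
    """Least-squares fit of y = a / sqrt(x) + c."""

    prefactor: float
    intercept: float
    se_prefactor: float
    se_intercept: float


def _derive_seed(base_seed: int, index: int) -> int:
    """Independent per-sweep-point root seed (kept below 2**31)."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_ensemble(
    config: SimulationConfig,
    targets: tuple[float, ...] = DEFAULT_TARGETS,
    n_boot: int = 1000,
    fit_gradients: bool = True,
    keep_tables: bool = False,
    crossing_rule: str = "interpolate",
) -> EnsembleResult:
    """Run the full pipeline for one configuration.

    For each of ``config.n_realizations`` realizations: draw a kinetic
    field, solve the steady state, fit the cosh profile to the middle
    row (optional), and locate threshold crossings for every readout
    target (in units of the mean decay length). Thresholds are
    calibrated once on the deterministic profile.
    """
    mid = config.middle_row
    thresholds: dict[float, float] = {}
    if targets:
        det_profile = deterministic_cell_profile(config)
        thresholds = {t: choose_threshold(config, t, profile=det_profile) for t in targets}
    fits: list[GradientFitResult] = []
    readouts: dict[float, list[ReadoutResult]] = {t: [] for t in targets}
    for i in range(config.n_realizations):
        kin = sample_kinetics(config, i)
        fld = solve_steady_state(config, kin)
        if fit_gradients:
            fits.append(fit_row_profile(fld, config, mid))
        row = fld.cell_averages[mid, config.n_source_cols :]
        for t, c_theta in thresholds.items():
            readouts[t].append(find_readout_position(row, c_theta, config, crossing_rule))
    gstats = (
        ensemble_gradient_stats(fits, n_boot=n_boot, seed=config.seed) if fit_gradients else None
    )
    pstats = {
        t: positional_error(r, config, n_boot=n_boot, seed=config.seed)
        for t, r in readouts.items()
    }
    if fit_gradients and gstats is not None and gstats.n_failed:
        logger.info("excluded %d non-converged fits", gstats.n_failed)
    for t, s in pstats.items():
        if s.n_flagged:
            logger.info("target %g: excluded %d zero-crossing realizations", t, s.n_flagged)
    return EnsembleResult(
        config=config,
        gradient_stats=gstats,
        positional=pstats,
        thresholds=thresholds,
        fits=fits if keep_tables else [],
        readouts=readouts if keep_tables else {},
    )


def _records_for(result: EnsembleResult, variable: str, value) -> list[dict]:
    cfg = result.config
    base = {
        variable: value,
        "n_rows": cfg.n_rows,
        "delta_x": cfg.delta_x,
        "delta_y": cfg.delta_y,
        "alpha": cfg.alpha,
        "bc_y": cfg.bc_y,
        "n_realizations": cfg.n_realizations,
    }
    g = result.gradient_stats
    if g is not None:
        base.update(
            cv_lambda=g.cv_lambda,
            cv_c0=g.cv_c0,
            sem_cv_lambda=g.sem_cv_lambda,
            sem_cv_c0=g.sem_cv_c0,
        )
    records = []
    if result.positional:
        for t, s in result.positional.items():
            rec = dict(base)
            rec.update(
                target=t,
                threshold=result.thresholds[t],
                mu_x=s.mu_x,
                sigma_x=s.sigma_x,
                sigma_x_over_delta=s.sigma_x_over_delta,
                sem_sigma_x=s.sem_sigma_x,
                n_used=s.n_used,
            )
            records.append(rec)
    else:
        records.append(base)
    return records


def run_width_sweep(
    base_config: SimulationConfig,
    widths: tuple[int, ...] = DEFAULT_WIDTHS,
    targets: tuple[float, ...] = DEFAULT_TARGETS,
    n_boot: int = 1000,
    fit_gradients: bool = True,
) -> SweepResult:
    """Sweep the tissue width Ny with independent ensembles per point."""
    if not widths or list(widths) != sorted(widths):
        raise ValueError("widths must be a non-empty ascending sequence")
    records: list[dict] = []
    for k, ny in enumerate(widths):
        cfg = replace(base_config, n_rows=int(ny), seed=_derive_seed(base_config.seed, k))
        logger.info("width sweep: Ny=%d (n=%d)", ny, cfg.n_realizations)
        res = run_ensemble(cfg, targets=targets, n_boot=n_boot, fit_gradients=fit_gradients)
        records.extend(_records_for(res, "n_rows_swept", ny))
    return SweepResult(variable="n_rows", values=tuple(widths), records=records)


def fit_sqrt_law(
    x_values: np.ndarray,
    y_values: np.ndarray,
    with_intercept: bool = True,
    weights: np.ndarray | None = None,
) -> ScalingFit:
    """Least-squares fit of y = a / sqrt(x) (+ c).

    The model is linear in (a, c), so the fit is an ordinary (or, with
    ``weights`` = 1/SEM, weighted) linear least squares on the regressor
    1/sqrt(x); standard errors come from the residual variance and the
    normal-equations covariance.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need at least 3 (x, y) points")
    if np.ptp(x) == 0:
        raise ValueError("all x values are equal: degenerate design")
    cols = [1.0 / np.sqrt(x)]
    if with_intercept:
        cols.append(np.ones_like(x))
    X = np.column_stack(cols)
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        Xw, yw = X * w[:, None], y * w
    else:
        Xw, yw = X, y
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("degenerate design matrix")
    resid = yw - Xw @ beta
    dof = max(x.size - X.shape[1], 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.diag(cov))
    return ScalingFit(
        prefactor=float(beta[0]),
        intercept=float(beta[1]) if with_intercept else 0.0,
        se_prefactor=float(se[0]),
        se_intercept=float(se[1]) if with_intercept else 0.0,
    )


def fit_width_scaling(
    sweep: SweepResult,
    quantity: str,
    target: float | None = None,
    with_intercept: bool = True,
) -> ScalingFit:
    """Fit the square-root law to one statistic of a width sweep.

    ``quantity`` is a column of the sweep frame ("cv_lambda", "cv_c0",
    "sigma_x_over_delta", ...). For positional quantities, ``target``
    selects the readout position.
    """
    frame = sweep.to_frame()
    if target is not None and "target" in frame:
        frame = frame[frame["target"] == target]
    frame = frame.drop_duplicates(subset=["n_rows"]).sort_values("n_rows")
    return fit_sqrt_law(
        frame["n_rows"].to_numpy(), frame[quantity].to_numpy(), with_intercept=with_intercept
    )


def run_aspect_ratio_sweep(
    base_config: SimulationConfig,
    mode: str,
    ratios: tuple[float, ...],
    targets: tuple[float, ...] = DEFAULT_TARGETS,
    n_boot: int = 1000,
    fit_gradients: bool = False,
) -> tuple[SweepResult, dict[float, ScalingFit]]:
    """Sweep the cell aspect ratio r = delta_x / delta_y.

    In "fixed-dx" mode delta_x is held while delta_y = delta_x / r
    varies; in "fixed-area" mode the cell area A = delta_x * delta_y is
    held while both diameters vary. Either way the tissue's physical
    width Ly and patterning length Lp of the base configuration are
    preserved (cell counts are re-derived by rounding). The relative
    positional error follows sigma_x / delta_x = a sqrt(delta_y /
    delta_x); the returned fits give the prefactor a per readout
    target.
    """
    if mode not in ("fixed-dx", "fixed-area"):
        raise ValueError("mode must be 'fixed-dx' or 'fixed-area'")
    if not ratios or any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    ly = base_config.length_y
    lp = base_config.length_pattern
    ls = base_config.length_source
    area = base_config.delta_x * base_config.delta_y
    records: list[dict] = []
    for k, r in enumerate(ratios):
        if mode == "fixed-dx":
            dx = base_config.delta_x
            dy = dx / r
        else:
            dx = float(np.sqrt(area * r))
            dy = float(np.sqrt(area / r))
        cfg = make_config(
            {
                **{
                    f: getattr(base_config, f)
                    for f in ("mu_p", "mu_d", "mu_D", "cv_p", "cv_d", "cv_D", "alpha",
                              "bc_y", "points_per_cell", "rel_tol", "n_realizations")
                },
                "delta_x": dx,
                "delta_y": dy,
                "n_rows": max(1, round(ly / dy)),
                "n_pattern_cols": max(1, round(lp / dx)),
                "n_source_cols": max(1, round(ls / dx)),
                "seed": _derive_seed(base_config.seed, k),
            }
        )
        logger.info("aspect sweep (%s): r=%g dx=%.3g dy=%.3g Ny=%d", mode, r, dx, dy, cfg.n_rows)
        res = run_ensemble(cfg, targets=targets, n_boot=n_boot, fit_gradients=fit_gradients)
        records.extend(_records_for(res, "aspect_ratio", r))
    sweep = SweepResult(variable="aspect_ratio", values=tuple(ratios), records=records)
    fits: dict[float, ScalingFit] = {}
    if len(ratios) >= 3:
        frame = sweep.to_frame()
        for t in targets:
            sub = frame[frame["target"] == t]
            # sigma_x/dx = a sqrt(dy/dx) = a / sqrt(r)
            fits[t] = fit_sqrt_law(
                sub["aspect_ratio"].to_numpy(),
                sub["sigma_x_over_delta"].to_numpy(),
                with_intercept=False,
            )
    return sweep, fits


def run_anisotropy_sweep(
    base_config: SimulationConfig,
    alphas: tuple[float, ...],
    targets: tuple[float, ...] = DEFAULT_TARGETS,
    n_boot: int = 1000,
    fit_gradients: bool = True,
) -> SweepResult:
    """Sweep the diffusion orthotropy alpha = Dy / Dx.

    Transverse smoothing strengthens with alpha; for wide tissues the
    variabilities and positional error scale as 1 / sqrt(alpha * Ny).
    The effect requires transverse neighbors (Ny > 1).
    """
    if not alphas or any(a <= 0 for a in alphas):
        raise ValueError("alphas must be positive")
    records: list[dict] = []
    for k, a in enumerate(alphas):
        cfg = replace(base_config, alpha=float(a), seed=_derive_seed(base_config.seed, k))
        logger.info("anisotropy sweep: alpha=%g", a)
        res = run_ensemble(cfg, targets=targets, n_boot=n_boot, fit_gradients=fit_gradients)
        records.extend(_records_for(res, "alpha_swept", a))
    return SweepResult(variable="alpha", values=tuple(alphas), records=records)


def wing_disc_config(
    pouch_length: float,
    n_rows: int,
    n_realizations: int = 1000,
    seed: int = 0,
) -> SimulationConfig:
    """Configuration for the wing-disc pouch at a given length Lp (um).

    The gradient and tissue scale with the pouch: mean decay length
    0.11 Lp, source length 0.16 Lp, and isotropic cell diameter
    5.1 um - 0.012 Lp (interpreted with Lp in micrometres), which
    shrinks as the pouch grows. Cell counts are rounded to tile the
    prescribed lengths.
    """
    dx = 5.1 - 0.012 * pouch_length
    if dx <= 0:
        raise ConfigurationError(
            f"pouch length {pouch_length} um implies non-positive cell diameter"
        )
    lam = 0.11 * pouch_length
    return make_config(
        n_source_cols=max(1, round(0.16 * pouch_length / dx)),
        n_pattern_cols=max(1, round(pouch_length / dx)),
        n_rows=n_rows,
        delta_x=dx,
        delta_y=dx,
        mu_p=1.0,
        mu_d=1.0,
        mu_D=lam * lam,
        n_realizations=n_realizations,
        seed=seed,
    )


def run_wing_disc_scenario(
    pouch_lengths: tuple[float, ...],
    widths: tuple[int, ...] = (1, 10),
    n_realizations: int = 1000,
    seed: int = 0,
    target_fraction: float = 0.4,
    n_boot: int = 1000,
) -> SweepResult:
    """Positional error of the scaling Dpp gradient readout.

    For each pouch length and tissue width, computes sigma_x at the
    readout position ``target_fraction`` * Lp (the L2 vein position at
    40% of the anterior domain).
    """
    records: list[dict] = []
    k = 0
    for lp in pouch_lengths:
        for ny in widths:
            cfg = wing_disc_config(lp, ny, n_realizations, seed=_derive_seed(seed, k))
            k += 1
            target = target_fraction * cfg.length_pattern / cfg.mean_decay_length
            res = run_ensemble(cfg, targets=(target,), n_boot=n_boot, fit_gradients=False)
            for rec in _records_for(res, "pouch_length", lp):
                rec["target_x_um"] = target_fraction * cfg.length_pattern
                records.append(rec)
    return SweepResult(variable="pouch_length", values=tuple(pouch_lengths), records=records)


def write_sweep_tables(
    sweep: SweepResult, out_dir: str | Path, fits: dict | None = None
) -> None:
    """Write a sweep's records as CSV and optional scaling fits as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sweep.to_frame().to_csv(out / f"sweep_{sweep.variable}.csv", index=False)
    if fits:
        payload = {str(k): asdict(v) for k, v in fits.items()}
        with open(out / f"scaling_fits_{sweep.variable}.json", "w") as fh:
            json.dump(payload, fh, indent=2)
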