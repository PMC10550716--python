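"""Per-realization gradient-shape fitting and ensemble variability.

Each realization's middle cell row yields a noisy 1D concentration
profile. The deterministic homogeneous steady state in the patterning
domain, C(x) = C0 cosh((Lp - x)/lambda) / cosh(Lp/lambda), is fitted to
the log-transformed cell averages by nonlinear least squares; far from
the distal boundary this reduces to the exponential C0 exp(-x/lambda),
but the cosh form also captures the flattening that the zero-flux
boundary at x = Lp imposes. Across an ensemble of realizations the
fitted decay lengths and amplitudes give the gradient variability
CV_lambda = sd(lambda)/mean(lambda) and CV_0 = sd(C0)/mean(C0), with
standard errors from a nonparametric bootstrap over realizations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .fd_solver import ConcentrationField
from .tissue_model import SimulationConfig

__all__ = [
    "EnsembleError",
    "GradientFitResult",
    "EnsembleStats",
    "fit_row_profile",
    "ensemble_gradient_stats",
    "write_fit_table",
    "write_stats_json",
]

# abort thresholds: silently dropping failed fits would bias the CVs
MAX_FAILURE_FRACTION = 0.01


class EnsembleError(RuntimeError):
    """Raised when ensemble statistics cannot be trusted or computed."""


@dataclass(frozen=True)
class GradientFitResult:
    """Fitted (lambda, C0) for one row-slice of one realization."""

    lam: float
    c0: float
    row_index: int
    rss: float  # residual sum of squares on the log scale
    converged: bool = True


@dataclass(frozen=True)
class EnsembleStats:
    """Gradient variability over an ensemble of realizations."""

    cv_lambda: float
    cv_c0: float
    sem_cv_lambda: float
    sem_cv_c0: float
    n_used: int
    n_failed: int
    mean_lambda: float
    mean_c0: float


def _log_cosh(z: np.ndarray) -> np.ndarray:
    """Overflow-safe log(cosh(z))."""
    z = np.abs(z)
    return z + np.log1p(np.exp(-2.0 * z)) - np.log(2.0)


def fit_row_profile(
    field: ConcentrationField,
    config: SimulationConfig,
    row_index: int | None = None,
) -> GradientFitResult:
    """Fit the cosh steady-state profile to one cell row's averages.

    The fit is performed on log concentrations against the
    patterning-domain cell centers. lambda is initialized from the
    log-slope between the first and last patterning cells and bounded
    in (0.1 delta_x, 10 Lp); C0 enters as log C0 and is unbounded.
    A non-converged optimizer result is returned flagged rather than
    raised, so callers can count and exclude it.
    """
    if row_index is None:
        row_index = config.middle_row
    if not 0 <= row_index < config.n_rows:
        raise ValueError(f"row_index {row_index} outside [0, {config.n_rows})")
    avgs = np.asarray(field.cell_averages[row_index, config.n_source_cols :], dtype=float)
    if np.any(avgs <= 0):
        raise ValueError("cell averages must be strictly positive for the log-scale fit")
    x = config.pattern_cell_centers
    y_log = np.log(avgs)
    lp = config.length_pattern
    lam_lo, lam_hi = 0.1 * config.delta_x, 10.0 * lp

    def residuals(theta: np.ndarray) -> np.ndarray:
        lam, log_c0 = theta
        return log_c0 + _log_cosh((lp - x) / lam) - _log_cosh(lp / lam) - y_log

    slope = (y_log[0] - y_log[-1]) / (x[-1] - x[0])
    lam0 = 1.0 / slope if slope > 0 else config.mean_decay_length
    lam0 = float(np.clip(lam0, 1.01 * lam_lo, 0.99 * lam_hi))
    res = least_squares(
        residuals,
        x0=[lam0, float(y_log[0])],
        bounds=([lam_lo, -np.inf], [lam_hi, np.inf]),
        method="trf",
    )
    lam, log_c0 = res.x
    return GradientFitResult(
        lam=float(lam),
        c0=float(np.exp(log_c0)),
        row_index=row_index,
        rss=float(2.0 * res.cost),
        converged=bool(res.success),
    )


def _cv(values: np.ndarray, axis: int | None = None) -> np.ndarray:
    return values.std(ddof=1, axis=axis) / values.mean(axis=axis)


def _bootstrap_sem(values: np.ndarray, n_boot: int, rng: np.random.Generator) -> float:
    """SE of the CV from nonparametric resampling of the realizations."""
    n = values.size
    idx = rng.integers(0, n, size=(n_boot, n))
    return float(np.std(_cv(values[idx], axis=1), ddof=1))


def ensemble_gradient_stats(
    fits: list[GradientFitResult],
    n_boot: int = 1000,
    seed: int = 0,
) -> EnsembleStats:
    """Gradient variability (CV_lambda, CV_0) with bootstrap SEs.

    Non-converged fits are excluded and counted; the ensemble is
    rejected outright if more than 1% failed, since silent exclusion
    would bias the coefficients of variation.
    """
    good = [f for f in fits if f.converged]
    n_failed = len(fits) - len(good)
    if len(fits) and n_failed > MAX_FAILURE_FRACTION * len(fits):
        raise EnsembleError(f"{n_failed}/{len(fits)} gradient fits failed to converge")
    if len(good) < 2:
        raise EnsembleError("at least 2 converged fits are required")
    lams = np.array([f.lam for f in good])
    c0s = np.array([f.c0 for f in good])
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    return EnsembleStats(
        cv_lambda=float(_cv(lams)),
        cv_c0=float(_cv(c0s)),
        sem_cv_lambda=_bootstrap_sem(lams, n_boot, rng),
        sem_cv_c0=_bootstrap_sem(c0s, n_boot, rng),
        n_used=len(good),
        n_failed=n_failed,
        mean_lambda=float(lams.mean()),
        mean_c0=float(c0s.mean()),
    )


def write_fit_table(fits: list[GradientFitResult], path: str | Path) -> None:
    """Write per-realization fits as (realization, row, lambda, C0, rss) CSV."""
    pd.DataFrame(
        {
            "realization": np.arange(len(fits)),
            "row": [f.row_index for f in fits],
            "lambda": [f.lam for f in fits],
            "C0": [f.c0 for f in fits],
            "rss": [f.rss for f in fits],
            "converged": [f.converged for f in fits],
        }
    ).to_csv(path, index=False)


def write_stats_json(stats, path: str | Path) -> None:
    """Serialize an ensemble-statistics dataclass to JSON."""
    with open(path, "w") as fh:
        json.dump(asdict(stats), fh, indent=2)
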