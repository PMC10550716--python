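"""Tissue geometry and stochastic per-cell kinetic parameter fields.

The tissue is a regular rectangular lattice of cells. Patterning occurs
along the x axis: ``n_source_cols`` columns of morphogen-producing cells
occupy x < 0 and ``n_pattern_cols`` columns form the patterning domain
x >= 0, with ``n_rows`` cell rows stacked in the transverse (y)
direction. Every cell carries its own production rate p, degradation
rate d and diffusivity D, drawn independently from log-normal
distributions specified by a linear-scale mean and coefficient of
variation. This cell-to-cell kinetic variability is the only source of
noise in the model; one draw of the full parameter field represents one
tissue (one "embryo"), and ensembles of draws are evaluated
statistically downstream.

Absolute kinetic scales are immaterial for the dimensionless outputs
(CVs of gradient parameters, positional error in cell diameters): the
defaults use mu_d = 1 per unit time, mu_D = mu_lambda**2 so that the
mean gradient decay length mu_lambda = sqrt(mu_D/mu_d) equals four cell
diameters, and mu_p = mu_d so concentrations are reported in units of
mu_p/mu_d.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "KineticField",
    "make_config",
    "load_config",
    "sample_kinetics",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid."""


_BC_Y_CHOICES = ("zero-flux", "periodic")

_POSITIVE_INT = ("n_source_cols", "n_pattern_cols", "n_rows", "points_per_cell", "n_realizations")
_POSITIVE_FLOAT = ("delta_x", "delta_y", "mu_p", "mu_d", "mu_D", "alpha", "rel_tol")
_NONNEG_FLOAT = ("cv_p", "cv_d", "cv_D")


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one ensemble of noisy 2D gradients.

    Lengths are in micrometres; rates in inverse time units; the
    diffusivity in um^2 per time unit. The patterning axis spans
    x in [-Ls, Lp] with the source occupying x < 0.
    """

    n_source_cols: int = 5
    n_pattern_cols: int = 50
    n_rows: int = 1
    delta_x: float = 5.0
    delta_y: float = 5.0
    mu_p: float = 1.0
    mu_d: float = 1.0
    mu_D: float = 400.0
    cv_p: float = 0.3
    cv_d: float = 0.3
    cv_D: float = 0.3
    alpha: float = 1.0
    bc_y: str = "zero-flux"
    points_per_cell: int = 3
    rel_tol: float = 1e-10
    n_realizations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in _POSITIVE_INT:
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        for name in _POSITIVE_FLOAT:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ConfigurationError(f"{name} must be strictly positive, got {v!r}")
        for name in _NONNEG_FLOAT:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be non-negative, got {v!r}")
        if self.bc_y not in _BC_Y_CHOICES:
            raise ConfigurationError(f"bc_y must be one of {_BC_Y_CHOICES}, got {self.bc_y!r}")
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool) or self.seed < 0:
            raise ConfigurationError(f"seed must be a non-negative integer, got {self.seed!r}")

    # -- derived geometry ------------------------------------------------
    @property
    def n_cols(self) -> int:
        """Total cell columns Nx (source + patterning)."""
        return self.n_source_cols + self.n_pattern_cols

    @property
    def length_source(self) -> float:
        """Source-domain length Ls = n_source_cols * delta_x (um)."""
        return self.n_source_cols * self.delta_x

    @property
    def length_pattern(self) -> float:
        """Patterning-domain length Lp = n_pattern_cols * delta_x (um)."""
        return self.n_pattern_cols * self.delta_x

    @property
    def length_x(self) -> float:
        return self.length_source + self.length_pattern

    @property
    def length_y(self) -> float:
        return self.n_rows * self.delta_y

    @property
    def mean_decay_length(self) -> float:
        """Mean gradient decay length mu_lambda = sqrt(mu_D / mu_d) (um)."""
        return float(np.sqrt(self.mu_D / self.mu_d))

    @property
    def x_cell_edges(self) -> np.ndarray:
        """x coordinates of the n_cols + 1 cell boundaries, source first."""
        return -self.length_source + self.delta_x * np.arange(self.n_cols + 1)

    @property
    def pattern_cell_centers(self) -> np.ndarray:
        """x coordinates of patterning-cell centers, (i + 1/2) * delta_x."""
        return (np.arange(self.n_pattern_cols) + 0.5) * self.delta_x

    @property
    def middle_row(self) -> int:
        """Cell-row index used for single-row statistics (y = Ly/2)."""
        return self.n_rows // 2

    def with_overrides(self, **overrides) -> "SimulationConfig":
        return make_config({**{f.name: getattr(self, f.name) for f in fields(self)}, **overrides})


def make_config(overrides: Mapping | None = None, **kwargs) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from the defaults plus overrides.

    The defaults describe the standard tissue: 5 source columns and 50
    patterning columns of isotropic 5 um cells (Ls = 25 um,
    Lp = 250 um), CVk = 0.3 for all three kinetic parameters, isotropic
    diffusion, mean decay length 20 um, zero-flux boundaries, 3x3 grid
    points per cell, and n = 1000 realizations.

    Raises
    ------
    ConfigurationError
        If an override names an unknown field or an out-of-range value.
    """
    merged = dict(overrides or {})
    merged.update(kwargs)
    valid = {f.name for f in fields(SimulationConfig)}
    unknown = set(merged) - valid
    if unknown:
        raise ConfigurationError(f"unknown configuration field(s): {sorted(unknown)}")
    return SimulationConfig(**merged)


def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML key-value config file; all fields optional."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"config file {path} must contain a key/value mapping")
    return make_config(data)


@dataclass(frozen=True)
class KineticField:
    """Per-cell kinetic parameters for one tissue realization.

    Arrays have shape (n_rows, n_cols). Production ``p`` is stored for
    every cell but is only applied within the source columns (the
    Heaviside factor H(-x) lives in the solver).
    """

    p: np.ndarray
    d: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        if not (self.p.shape == self.d.shape == self.D.shape):
            raise ValueError("p, d, D must share one (n_rows, n_cols) shape")
        for name in ("p", "d", "D"):
            if not np.all(getattr(self, name) > 0):
                raise ValueError(f"kinetic field {name} must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.p.shape


def _lognormal(rng: np.random.Generator, mean: float, cv: float, shape) -> np.ndarray:
    """Log-normal draws with the given linear-scale mean and CV.

    sigma_log^2 = ln(1 + CV^2) and m_log = ln(mean) - sigma_log^2 / 2 is
    the unique parameterization matching both moments; CV = 0 degenerates
    to the constant field.
    """
    if cv == 0:
        return np.full(shape, float(mean))
    sigma2 = np.log1p(cv * cv)
    m_log = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=m_log, sigma=np.sqrt(sigma2), size=shape)


def sample_kinetics(config: SimulationConfig, realization_index: int) -> KineticField:
    """Draw one per-cell kinetic parameter field (one tissue realization).

    Each realization uses an independent random substream spawned from
    ``config.seed`` keyed by ``realization_index``, so draws are
    reproducible per (seed, index) and statistically independent across
    indices.
    """
    if not 0 <= realization_index < config.n_realizations:
        raise ValueError(
            f"realization_index {realization_index} outside [0, {config.n_realizations})"
        )
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(realization_index,))
    rng = np.random.default_rng(ss)
    shape = (config.n_rows, config.n_cols)
    # draw order is part of the reproducibility contract
    p = _lognormal(rng, config.mu_p, config.cv_p, shape)
    d = _lognormal(rng, config.mu_d, config.cv_d, shape)
    D = _lognormal(rng, config.mu_D, config.cv_D, shape)
    return KineticField(p=p, d=d, D=D)
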