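# Methods

## Model

`morphogrid` studies how cell-to-cell molecular noise limits the
spatial precision of morphogen-gradient patterning in two-dimensional
epithelia. The tissue is a regular rectangular lattice of cells of
diameter δx along the patterning axis and δy across it: `n_source_cols`
columns of morphogen-producing cells occupy x ∈ [−Ls, 0) and
`n_pattern_cols` columns form the patterning domain x ∈ [0, Lp], with
Ny = `n_rows` cell rows stacked transversally. The morphogen
concentration C(x, y) obeys the steady-state reaction–diffusion
equation

    0 = ∇·(D ∇C) + p H(−x) − d C,     D = diag(D, αD),

where production p, degradation d and diffusivity D are constant
within each cell but vary from cell to cell, and α = Dy/Dx is the
degree of diffusion orthotropy. Each tissue realization draws its
per-cell (p, d, D) independently from log-normal distributions with
linear-scale means (μp, μd, μD) and coefficients of variation
CVk = 0.3 for all three parameters — the physiological noise level
for this class of models. The deterministic (CVk = 0) solution in the
patterning domain is the two-domain steady state
C(x) = C0 cosh[(Lp − x)/λ]/cosh(Lp/λ) with decay length λ = √(D/d),
which reduces to the exponential C0 e^(−x/λ) away from the distal
zero-flux boundary.

Two ensemble statistics quantify precision:

- **Gradient variability.** The cosh profile is fitted (nonlinear
  least squares on the log scale) to the cell-averaged concentration
  of the middle cell row of each realization, giving per-realization
  (λ, C0). CVλ = sd(λ)/mean(λ) and CV0 = sd(C0)/mean(C0) are computed
  across realizations, with standard errors from a nonparametric
  bootstrap over realizations.
- **Positional error.** A threshold Cθ is calibrated on the
  deterministic cell-averaged profile so that the mean readout
  position lands at a prescribed distance from the source (3, 6 or 9
  mean decay lengths by default). Per realization, every crossing of
  the middle row's step profile through Cθ is located; the readout
  position xθ is the mean of all crossings (noisy 2D profiles need not
  be monotonic). σx = sd(xθ) across realizations is the positional
  error, reported both in μm and in units of δx.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `n_source_cols` / `n_pattern_cols` | 5 / 50 | source and patterning columns (Ls = 25 μm, Lp = 250 μm) |
| `n_rows` (Ny) | 1 | tissue width in cell rows; swept 1–40 |
| `delta_x`, `delta_y` | 5 μm | cell diameters (isotropic by default) |
| `mu_p`, `mu_d`, `mu_D` | 1, 1, 400 | kinetic means; μλ = √(μD/μd) = 20 μm = 4 δ |
| `cv_p`, `cv_d`, `cv_D` | 0.3 | cell-to-cell kinetic variability |
| `alpha` | 1 | transverse/longitudinal diffusivity ratio |
| `bc_y` | zero-flux | transverse boundary, or periodic (tubular tissue) |
| `points_per_cell` | 3 | fine-grid points per cell per axis |
| `rel_tol` | 1e-10 | linear-system relative residual bound |
| `n_realizations` | 1000 | ensemble size |

Only μλ/δ and the CVs matter for the dimensionless outputs: CVλ, CV0,
σx/δx and all readout positions are invariant under rescaling of μp
(amplitude units) and of the absolute time scale. The defaults μd = 1
and μp = μd therefore fix conventions, not physics; concentrations are
reported in units of μp/μd (the far-from-boundary source plateau).

## Numerics

**Discretization.** Each cell carries a 3×3 block of fine-grid points
placed cell-centered (at fractions 1/6, 1/2, 5/6 of the cell
diameter), so the grid spacing is δ/3 per axis and the default Ny = 40
tissue is a 165×120-point system. The five-point stencil is written in
divergence (flux) form: the flux between two adjacent grid points uses
the harmonic mean of their cells' diffusivities, which enforces
discrete continuity of concentration and flux across cell interfaces
and makes the scheme exactly mass-conserving (pure-diffusion operator
rows sum to zero — a tested invariant). With discontinuous per-cell
diffusivities the non-conservative form D∇²C can only be approximated;
the flux form is the approximation chosen here because conservation is
testable. A non-conservative point-coefficient variant was compared
during development and changes the ensemble statistics by far less
than the sampling error. Zero-flux boundaries drop the boundary flux
(mirror ghost points); the transverse boundary may wrap (periodic).

**Solver.** The system matrix (weighted graph Laplacian plus positive
diagonal) is symmetric positive definite and is solved by sparse LU
with minimum-degree ordering; the relative residual is verified
against `rel_tol`, and solutions are checked finite and positive
(discrete maximum principle). A Jacobi-preconditioned conjugate-
gradient path is available and uses `rel_tol` as its termination
criterion. Sparse solves are validated against a dense brute-force
assembly on small lattices, and against the analytic cosh profile in
the zero-noise limit (relative error ≈ 0.5% at 3 points per cell,
decreasing under grid refinement).

**Profile fitting.** log C(x) = log C0 + log cosh[(Lp − x)/λ] −
log cosh(Lp/λ) is fitted to the log cell averages at the patterning
cell centers with `scipy.optimize.least_squares` (overflow-safe
log-cosh). λ is initialized from the end-to-end log slope and bounded
in (0.1 δx, 10 Lp); log C0 is free. Non-converged fits are excluded
and counted; an ensemble aborts if more than 1% fail (silent exclusion
would bias the CVs). Sample standard deviations use the n−1
denominator throughout.

**Threshold calibration and crossing location.** Cθ is obtained by
log-linear interpolation of the deterministic cell-average profile at
the target position — reproducible and independent of any noisy
ensemble; the realized ensemble-mean readout then lands within one
cell diameter of the target (a tested self-consistency). Crossings of
the noisy step profile are located by log-linear interpolation between
cell centers (sub-cell resolution). A `cell-boundary` rule that snaps
crossings to cell interfaces is also provided; it quantizes readout to
the cell lattice and inflates σx noticeably in wide tissues where the
residual noise is small (≈ 0.33 vs ≈ 0.23 cell diameters at Ny = 40,
3 μλ), so interpolation is the default. Realizations whose profile
never crosses Cθ are flagged and excluded, with the same 1% abort
rule.

**Random numbers.** One root seed; realization i uses the substream
`SeedSequence(entropy=seed, spawn_key=(i,))`, so ensembles are
reproducible per (seed, index) and embarrassingly parallel. Sweep
points derive independent root seeds the same way.

**Square-root fits.** CV(Ny) = a/√Ny + c and σx(Ny) = a/√Ny are
linear in (a, c) and fitted by unweighted linear least squares (an
SEM-weighted option exists); standard errors come from the residual
variance. Note that with a saturating curve the fitted prefactor
depends mildly on the design points: the 11-point log-spaced grid
{1, 2, 3, 4, 6, 8, 10, 14, 20, 28, 40} yields aλ ≈ 0.032, while the
full integer grid 1..40 yields aλ ≈ 0.031 from the same underlying
curve. The acceptance script fits over all integer widths.

## What the synthetic tissue does and does not emulate

The generator reproduces the stochastic tissue of the study
conditions: rectangular cell lattice, per-cell i.i.d. log-normal
kinetics, steady-state continuum transport. It does not emulate
variable cell sizes or irregular cell packings, readout/downstream
signaling noise, pre-steady-state dynamics, low-copy-number
(particulate) effects, or 3D architecture. Passing tests therefore
demonstrate properties of this model class, not of any measured
tissue.

## Results the package reproduces, and chosen problem sizes

With the defaults above the pipeline reproduces the headline numbers
of the 2D noisy-gradient analysis: σx/δ ≈ 0.23 (target 3 μλ) and
≈ 0.29 (target 9 μλ) for the 50×40-cell tissue at n = 1000;
width-scaling prefactors aλ ≈ 0.031 and a0 ≈ 0.20 (integer grid,
n = 400 per width). The test suite runs the same pipelines at n = 250
(tolerances widened ∝ 1/√n) except where a configuration is cheap
(n = 1000–4000).

Specific choices where the problem left latitude, made once and
documented here:

- **Middle row.** Row index ⌊Ny/2⌋ (0-based), unambiguous for even Ny;
  bulk rows are statistically exchangeable.
- **Width grid.** Log-spaced 11 points for exploratory sweeps (resolves
  both the power-law regime and the saturation); all integers 1–40 for
  the definitive scaling fits.
- **Log-log slope check.** The σx ∝ Ny^(−1/2) slope for Ny ≤ 10 is
  evaluated at the far readout target (9 μλ), where absolute errors are
  largest and relative discretization effects smallest.
- **Sub-cellular precision at Ny = 2.** The value at target 9 μλ is
  ≈ 0.99 cell diameters — genuinely below one but close; the test uses
  n = 4000 so the estimate resolves the bound.
- **Wing-disc scenario.** The pouch is parameterized by its length Lp:
  μλ = 0.11 Lp, Ls = 0.16 Lp, δx = δy = 5.1 μm − 0.012·Lp (Lp in μm;
  cells shrink as the pouch grows), readout at 0.4 Lp. The
  width-benefit ratio σx(Ny=1)/σx(Ny=10) grows with Lp because λ/δx
  grows (≈ 3.0 at Lp = 100 μm, ≈ 3.2 at Lp = 250 μm, the
  representative late-development geometry used in the tests).

## Known limitations

- **Saturation of the width benefit.** Transverse diffusion averages
  noise over a window of order the decay length. Once Ny δy exceeds
  that window (about ten cells at the defaults), CVλ, CV0 and σx
  flatten; the 1/√Ny law holds only below it. Consequently the
  benefit of faster transverse diffusion is also bounded: at Ny = 40,
  quadrupling α reduces σx by ~α^(1/4) (consistent with the cell-area
  law σx ∝ √(δxδy) applied to the √α-rescaled transverse coordinate),
  not by the unsaturated 1/√α asymptote.
- The fitted scaling prefactors are estimands of a specific fit design
  (grid, weighting); comparisons must fix these conventions.
- At 3 grid points per cell the deterministic discretization error is
  ~0.5%; ensemble statistics inherit a same-order systematic that is
  shared with the reference study conditions (also 3 points per cell).
- Threshold readout assumes a single fixed Cθ per target; receptor-
  level or downstream noise is outside the model.
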