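# morphogrid

Precision of noisy 2D morphogen gradients on cellular lattices.

Morphogen gradients pattern developing tissues: cells read a local
concentration C(x) ≈ C0 e^(−x/λ) and adopt fates where it crosses a
threshold Cθ (the French flag picture). Because the kinetic parameters
— production p, degradation d, diffusivity D — vary from cell to cell,
gradients differ between embryos, the fitted (λ, C0) fluctuate, and
the fate boundary lands at different positions xθ = λ ln(C0/Cθ) in
different individuals. The **positional error** σx = sd[xθ] measures
that patterning imprecision.

`morphogrid` simulates ensembles of such gradients in *two dimensions*:
a rectangular lattice of cells (source columns at x < 0, patterning
columns at x ≥ 0, Ny cell rows across), per-cell log-normal kinetics
with coefficient of variation CVk, and the steady state of

    0 = ∇·(D ∇C) + p H(−x) − d C,      D = diag(D, αD),

solved by a conservative five-point finite-difference scheme (3×3 grid
points per cell). From n independent tissue realizations it computes
the gradient variability CVλ = σλ/μλ and CV0 = σC0/μC0 (cosh-profile
fits to the middle cell row), the positional error σx at calibrated
readout positions, bootstrap standard errors, and the square-root
scaling laws that transverse diffusion induces:

    CVλ, CV0 ≈ a/√Ny + CV(∞),     σx/δ ≈ ax/√Ny,
    σx/δx ≈ a·√(δy/δx),           σx ≈ a·√(δx·δy),

i.e. wider tissues and narrower cells pattern more precisely, until
the benefit saturates at widths of roughly ten cells. It is written
for quantitative/developmental biologists and modelers who want to
reproduce, probe, or extend these scaling results.

## Worked example

One ensemble of 200 noisy tissues, ten cell rows wide, with the
standard geometry (5 source + 50 patterning columns of 5 μm cells,
μλ = 20 μm, CVk = 0.3):

```sh
morphogrid simulate --ny 10 --n 200 --seed 42 --targets 3,9 --out demo-out
```

prints

```
CV_lambda = 0.0105 +- 0.0005
CV_0      = 0.0665 +- 0.0031
target 3 mu_lambda: mu_x = 58.69 um, sigma_x/delta = 0.289 +- 0.015
target 9 mu_lambda: mu_x = 175.83 um, sigma_x/delta = 0.449 +- 0.021
```

Read: across 200 simulated tissues the fitted decay length varies by
only ~1% and the amplitude by ~7%; a fate boundary targeted at three
decay lengths from the source (60 μm) lands on average at 58.7 μm and
wanders by just 0.29 cell diameters between tissues — sub-cellular
precision — and even at nine decay lengths the error is 0.45 cell
diameters. (A one-row "1D" tissue gives ≈ 0.9 and ≈ 1.3 at the same
targets: transverse diffusion is what buys the precision.) The run
also writes per-realization fit and readout tables (CSV) and the
ensemble statistics (JSON) into `demo-out/`.

Other entry points: `morphogrid sweep-width` (scaling fits over Ny),
`sweep-aspect` (cell aspect ratio at fixed δx or fixed area),
`sweep-alpha` (diffusion anisotropy), `wing-disc` (the growing
*Drosophila* wing-pouch scenario, where the Dpp gradient scales with
the domain), and `inspect` (write one solved concentration field).
Every command accepts a YAML config file mirroring the
`SimulationConfig` fields; the same pipelines are available as library
functions (`morphogrid.run_ensemble`, `run_width_sweep`, ...).

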