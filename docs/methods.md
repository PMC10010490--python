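# Methods

## Scope and data model

The package implements a seed-vigor analysis pipeline for single-seed
visible/NIR reflectance spectra (384–1034 nm as acquired, 400–1000 nm
after edge trimming). The central container is `SpectralDataset`: one
mean reflectance spectrum per seed plus its aging group (A0 unaged to
A4 = 96 h accelerated aging), a binary viability label from an 8-day
germination test (germ length > 1.5 cm), and measured SOD activity in
U/g fresh weight. Hyperspectral tray images are handled as
rows × cols × bands `Hypercube` arrays with ENVI-style text-header +
raw-binary I/O (BSQ written; BSQ/BIL read).

## Synthetic study generator

Because the original seed images are not redistributable, every stage is
exercised against a generator that emulates the study's structure. For a
seed in group *g* with standard-normal latent vigor deviate *e*:

- **Viability** is the indicator `e > −Φ⁻¹(p_g)`, so the group
  germination probability equals `p_g` exactly. Defaults are the
  observed 8-day germination rates of the five aging groups
  (0.9625, 0.85, 0.65, 0.3875, 0.225).
- **Clean spectrum** = group baseline − absorption dips. The baseline is
  a broadband level increasing with aging (0.38 → 0.54 reflectance,
  step 0.04) plus a 0.20 upward tilt from blue to NIR, reflecting the
  loss of absorbing storage compounds in aged seeds. Dips are Gaussians
  at 450, 550, 920 and 970 nm (pigment, soluble sugar, protein, O–H
  overtone; base depths 0.08/0.06/0.06/0.09, widths 18–22 nm) scaled by
  group multipliers decreasing 1.0 → 0.4 with aging.
- **Latent coupling.** The scaled deviate `u = 0.35·e` perturbs the dip
  multipliers per feature: weakly at the pigment/sugar features
  (coupling 0.15) and strongly at the 920/970 nm protein/O–H features
  (coupling 0.6). SOD activity is
  `sod_mean_g + 0.5·u + N(0, 0.08²)` with group means
  (3.2, 2.7, 2.2, 1.7, 1.2) — unaged above 3, aged below 3, decreasing
  with aging time. Because viability and SOD are functions of the same
  latent that sets the NIR dip depths, spectra carry recoverable signal
  for both tasks, and because the group means of both the dip
  multipliers and SOD are linear sequences, SOD is (up to noise) a
  single linear functional of the dip-depth pair — which is what makes
  linear PLSR recovery mechanistically meaningful rather than a
  memorized group lookup. An earlier design with one uniform coupling
  was discarded: after MSC removes the baseline offsets that identify
  the group, a target with different between- and within-group slopes
  against dip depth is not linearly identifiable.
- **Measurement model**: per-seed multiplicative gain
  `exp(0.05·N(0,1))`, additive offset `N(0, 0.01²)`, and per-band white
  noise `N(0, 0.004²)`. Instrument noise magnitudes are not published
  for this class of camera at the per-seed-mean level; these values give
  group curves that are separable but overlapping, matching the
  qualitative appearance of real aging-gradient spectra.
- **Germination records**: each seed germinates with its group
  probability; germination day is a discretized normal around the group
  mean day (defaults = the observed mean germination times 2.78 → 7.21,
  sd 1.0), truncated to the 8-day window. Seedling (root) mass S is
  lognormal around group means 1.52–1.77 g (implied by published VI/GI
  ratios; S itself is never tabulated), cv 0.10.
- **Tray images**: elliptical seed regions, one per tray cell, on dark
  (0.02 reflectance) cardboard, with per-pixel noise; masks are disjoint
  by construction and ordered row-major. Layouts whose cells cannot hold
  the seed ellipses are rejected.

Determinism: a `SimConfig` (including its seed) fully determines every
output; spectra, cube and germination draws use independent RNG streams
so one stage's sample count does not perturb another's.

What the generator does **not** emulate: camera radiometry (12-bit
quantization, slit/smile effects), spatial texture within a seed,
wavelength-correlated (pink) noise, and any real biochemical
nonlinearity between reflectance and enzyme activity. Passing recovery
tests therefore demonstrates that the pipeline's statistics are
implemented correctly and can extract this class of signal — not that
real peanut spectra contain signal of this strength.

The noise-free degeneracy check (spectra equal the five group mean
curves) requires switching off all four per-seed variance sources:
`noise_sd`, `scatter_sd`, `offset_sd` *and* `vigor_sd` — the latent
spread is a first-class generator parameter, not measurement noise.

## Numerical conventions

- **Black/white correction** is elementwise
  `(Sample − dark)/(White − dark)` with an error on any zero
  denominator; single-row reference frames broadcast along the scan
  axis. The correction is invariant under affine re-scaling of all three
  cubes (tested).
- **Savitzky–Golay**: default window 11, polyorder 3, derivative 0 — a
  common chemometrics default at ~2.5 nm sampling; edges are handled by
  evaluating the edge-window polynomial (scipy's `mode="interp"`), so
  the filter stays exact on polynomials up to the fitted order.
- **MSC**: per-spectrum least-squares fit `x ≈ a + b·ref`, returning
  `(x − a)/b`. The reference is the calibration-set mean and is frozen
  there; prediction spectra are corrected against the same reference to
  avoid leakage. Fitted slope 0 raises.
- **Median filter**: window 5 along the spectral axis only, reflected
  edge padding. Idempotent on monotone spectra.
- **Band ranking**: 500 trees, depth 6, learning rate 0.1 for both
  flavors; gain-based (total loss reduction) importances,
  sum-normalized, rounded to 12 decimals to absorb float jitter, top-15
  kept with ties broken by ascending wavelength. The "catboost-style"
  ranker is XGBoost's histogram GBM; the contract is the ranking
  procedure, not the brand. Ranking is fitted on the calibration set
  only by default (`select_on="all"` reproduces the leakier variant).
  Band subsets are returned in ascending-wavelength order so the
  dataset's monotone-grid invariant holds; downstream models are
  insensitive to column order.
- **Split**: stratified 7:3 with a fixed seed; 400 seeds → 280/120.
- **Classifiers**: library defaults with fixed seeds and single-threaded
  training; SVM uses an RBF kernel with C = 1 and
  gamma = 1/(n_bands·Var(X)). Accuracy is reported on the 0–100 scale
  with 2 decimals.
- **PLSR**: mean-centered (no variance scaling), NIPALS-equivalent.
  When the component count is not given it is chosen by 5-fold
  cross-validated RMSE on the calibration set, capped at 15 (the
  selected-band count); ties go to the smaller count. At full rank the
  fit reproduces OLS predictions (tested to 1e-8).
- **Vigor indices**: 1-based day numbering; MGT is flagged undefined
  (NaN) when nothing germinates. SVI uses GP as a fraction
  (SVI = GP/100 · S): published SVI magnitudes (0.32–1.63 with masses
  near 1.5 g) are only consistent with the fraction convention. Records
  transcribed from summary tables may carry totals only; indices whose
  inputs are missing come back NaN.
- **SOD activity** follows the standard 50 %-inhibition NBT unit:
  `inhibition · V_T / (½ · (A₀−A_b) · W · V_s)`.
- **Correlation**: Pearson over the five group rows; with n = 5 these
  are descriptive only and the API emits a warning saying so. Constant
  columns are flagged and set to NaN off-diagonal.

## Problem sizes

Recovery checks run at the study's own scale: 400 seeds (80 per group)
for classification and 100 seeds (20 per group, the SOD assay subset)
for regression; unit tests of the rankers use reduced grids of 16–64
bands. The default wavelength grid is 256 evenly spaced bands over
384–1034 nm (≈2.5 nm spacing, close to the instrument's listed band
spacing); after trimming to 400–1000 nm, 235 bands remain.

## Known limitations

- Segmentation is a single-band global threshold plus connected
  components — adequate for bright seeds on black cardboard, not for
  touching seeds or textured backgrounds; an `expected` count mismatch
  is logged rather than auto-repaired.
- The n = 5 group-level correlation cannot support inference; a
  per-seed variant is available by passing per-seed columns directly to
  `pearson_matrix`.
- CV-based PLSR component choice can be unstable on very small
  calibration sets (< ~20 seeds); pass `n_components` explicitly there.
- Boosted-tree hyperparameters are fixed, not tuned; the grid compares
  preprocessing and band selection under a constant modelling budget.
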