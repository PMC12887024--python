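# Methods

## Scope and shape

`palmspec` reimplements a machine-learning-assisted Raman workflow for
crude palm oil quality as a library of scikit-learn-style estimators:
preprocessing transformers, `SelectorMixin` wavelength selectors, and
`RegressorMixin` models, orchestrated by an experiment pipeline. The
module-level functions (`savgol`, `cars_select`, `fit_pls`, …) are thin
wrappers over these estimators, so both functional and pipeline-composed
use are first-class.

## Synthetic data: what it emulates

The original market samples are not publicly deposited, so the generator
stands in for them. Each of the five market profiles carries the reported
PV/IV range, mean and SD. Draws are truncated normals realised by
rejection sampling (no probability atoms at the range edges). Two details
deserve note:

* **Moment calibration.** The reported (range, SD) pairs are mutually
  infeasible for a truncated normal — e.g. the AGB PV range has width
  6.72, whose maximum achievable SD (uniform limit) is 1.94, below the
  reported 2.08. Truncating N(mean, sd) to such an asymmetric range also
  shifts the mean by up to ~0.5 meq O₂/kg. The generator therefore solves
  for the parent-normal location whose *truncated* mean equals the
  reported mean (Brent root-find on `scipy.stats.truncnorm`), keeps the
  parent sd at the reported value, and accepts that the realised SD is
  somewhat attenuated. Means are exact in expectation; ranges are hard.
* **PV–IV independence.** PV and IV are drawn independently by default; a
  Gaussian-copula `pv_iv_correlation` parameter (default 0) is available
  because the inverse PV–IV relationship seen in real oils has no
  reported correlation coefficient to calibrate against.

Spectra are sums of pseudo-Voigt bands (default 70 % Gaussian — a standard
Raman lineshape; no lineshape is reported for the instrument) at 893,
1156, 1287, 1442, 1524, 1602, 1657, 1748 and 1800 cm⁻¹. Band amplitude is
`base + pv_coupling·PV + iv_coupling·IV`: the carbonyl/oxidation bands
(1748, 1800 cm⁻¹) couple to PV and the unsaturation bands (1287, 1602,
1657 cm⁻¹) to IV. Couplings (0.006–0.045 amplitude units per reference
unit) are sized so each parameter's population span moves its bands by a
few tenths of the main CH₂ band height — dominant over measurement noise,
small against the fluorescence background, as in real crude palm oil at
785 nm.

The background is a fixed low-order polynomial plus a broad fluorescence
hump (centre 1100 cm⁻¹, FWHM 900 cm⁻¹, emulating the carotenoid
background) plus, per sample, four random broad pseudo-Voigt humps
(centres uniform on the grid, FWHM 200–500 cm⁻¹, amplitudes scaled by
`baseline_jitter`, default 0.25). The random humps make the background
differ in *shape*, not just level, between samples — the fluorophore mix
of market oils varies — and they are what derivative preprocessing exists
to remove: with them, raw-spectrum PLS degrades sharply while derivative
models are nearly unaffected, reproducing the qualitative preprocessing
ranking on real data. With a fixed-shape background, a linear model can
project the single confound direction out and raw spectra would
(unrealistically) win.

White noise (sd 0.01 intensity units) is added per replicate and the mean
of 3 replicates is returned, mirroring the acquisition protocol; the
replicate-averaged noise variance is sd²/3.

`n_per_market` defaults to 40 (200 samples total). The acquisition
description is internally inconsistent (50 per market yet 200 total); the
200 figure is what the 2:1 partition arithmetic (133/67) and all model
tables rely on, so it wins.

**What passing tests do and do not show.** The synthetic problem is, by
construction, affine in PV/IV with additive smooth confounds. Linear PLS
is therefore near-oracle on it and outperforms random forests, whereas on
the real market data the nonlinear ensemble dominated. Results on this
generator validate the *machinery* (selection concentrates on the coupled
bands, models recover the known chemistry, metrics are self-consistent),
not instrument-specific performance, and not the real-data model ranking.

## Preprocessing

* Savitzky–Golay: window 15, polyorder 3 (typical for 1024-channel Raman;
  unreported in the source protocol), `mode="interp"` edge handling so the
  channel count is preserved. Derivatives are scaled by the grid spacing
  (units per (cm⁻¹)^order). Derivatives are applied to raw spectra by
  default — the derivative itself removes smooth baselines — with a
  `baseline_first` switch.
* Wavelet denoising: `sym8`, level 4, universal threshold
  σ̂·√(2 ln n) with σ̂ = MAD(finest details)/0.6745, soft by default.
* Baseline: asymmetric least squares (λ = 1e5, p = 0.01, 10 reweighting
  iterations). The source names no baseline algorithm; AsLS is the
  standard choice for fluorescence-dominated Raman.
* Normalisation: vector (default), area (trapezoid over the grid), or
  min–max.

## Wavelength selection

All selectors operate on calibration rows only (the pipeline enforces
this), are seeded, and break ties by lowest variable index.

* **CARS** (50 iterations, Monte-Carlo fraction 0.8, 5-fold CV): per
  iteration a PLS fit on a random 80 % subset ranks variables by |b|;
  forced retention keeps the top ⌈r_i·p⌉ where r_i = a·e^(−k·i) with
  r₁ = 1 and r_N = 2/p; adaptive reweighted sampling then draws survivors
  with probability ∝ |b|. The subset with minimal 5-fold RMSECV wins.
* **UVE**: appends p noise columns at amplitude 1e-10, fixes the
  latent-variable count once by CV on the augmented matrix, collects
  jackknifed coefficient vectors (leave-one-out for n ≤ 150, else
  10-fold), computes reliability c_j = mean(b_j)/sd(b_j), and cuts real
  variables at the largest noise-column |c_j|. Choosing the component
  count once (rather than per refit) keeps the stability statistic
  well-defined — this is the classical formulation.
* **GA** (population 64, 100 generations, 5 runs, uniform crossover 0.5,
  bit-flip mutation 0.01, elitism 1, sparse initialisation 10 %): fitness
  is −RMSECV of PLS on the active genes, cached by chromosome. Each run's
  best chromosome gets one backward-elimination pass — genes whose removal
  does not worsen the CV RMSE are pruned in ascending index order —
  because bit-flip mutation continually injects near-neutral genes that
  hitchhike on fit chromosomes; pruning them is standard in GA wavelength
  selection and typically halves the subset's RMSECV. A variable is
  selected when it appears in ≥ 3/5 of the pruned per-run bests.

Band concentration is quantified by a hypergeometric tail: the probability
of at least the observed number of selected channels falling inside a
target band when drawing |selection| channels without replacement from the
grid.

## Regression models

* **PLS**: an internal SIMPLS engine (mean-centring only; spectra share
  units, so autoscaling would inflate noise channels) that returns every
  nested component count from one non-iterative pass. This makes the
  ~10⁵ small CV fits inside the selectors affordable and makes
  CV-choosing the latent-variable count (≤ 10, ties to the smaller count)
  free. The engine is cross-checked in the tests against
  `sklearn.cross_decomposition.PLSRegression` and against ordinary least
  squares at full rank.
* **SVR**: per-variable scaling of training spectra to [−1, 1]
  (zero-variance channels map to 0 with a warning), PCA keeping 95 % of
  variance, ε-SVR with RBF kernel on a standardised target (ε = 0.1 in
  target-SD units; unreported in the source). Tuning: exhaustive 5-fold CV
  over C ∈ 2⁻⁴…2¹⁰, γ ∈ 2⁻¹⁰…2⁴ (ties to smallest C then γ), then one
  local refinement pass (geometric 5-point grid over a factor-2 bracket)
  so non-power-of-two optima are expressible. The scaling + PCA pipeline
  is treated as SVR-specific; PLS and RF see the preprocessed spectra
  directly.
* **RF**: 250 bootstrap trees, minimum leaf 10, mtry = max(1, ⌊p/3⌋)
  (the regression default), seeded.

## Partitioning and metrics

Kennard–Stone (maximin Euclidean distance on the raw spectra, after a
canonical sort by sample id so the split is invariant to row order) with
calibration size ⌊2n/3⌋; a seeded random split is available. Rc/Rp are
Pearson correlations; RMSEC/RMSEP are plain root-mean-square errors;
RPD = sd(prediction-set references, n−1)/RMSEP, classified ≥3 excellent,
2–3 acceptable, <2 limited. RPD = sd/RMSEP is enforced as an identity on
every report (the published tables are not mutually consistent with any
single such definition; this implementation does not try to
reverse-engineer theirs).

## Pipeline and reproducibility

`run_experiment` partitions once, preprocesses (second derivative by
default), runs each selector once per parameter on calibration data, fits
the {full, CARS, UVE, GA} × {PLS, SVM, RF} grid on the shared partition,
and emits the model table plus JSON artifacts (selections with
diagnostics, SVR optima, per-sample predictions) from which every table
cell is recomputable. Stage seeds derive from the master seed via
`SeedSequence` keyed by CRC32 of stage tags, so runs are byte-reproducible
and individual stages are independently reseedable. A failed row is
recorded and skipped; remaining rows still run.

Problem sizes used by the test suite: unit tests run on 40–60-sample,
64–256-channel datasets; the end-to-end acceptance tests and
`scripts/acceptance.py` use the full default conditions (200 samples,
1024 channels, all selector defaults including the GA's 64 × 100 × 5
search). One full 12-model study for both parameters takes roughly 4–5
minutes on a single CPU.

## Known limitations

* Affine band–chemistry coupling: no saturation, peak shifts, or
  temperature effects; RF's real-data advantages are invisible here.
* No cosmic-ray spikes, detector nonlinearity, or radiometric units.
* The GA's backward-elimination pass is greedy and single-pass; it prunes
  hitchhikers but does not guarantee a minimal subset.
* UVE's +∞ reliability sentinel (zero coefficient spread) retains the
  variable and warns rather than modelling the degenerate case.
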