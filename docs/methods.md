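# Methods

This note documents the models and procedures implemented in bananachem,
the synthetic data they are validated on, and the numerical and design
choices a user should know before trusting or extending the results.

## The measurement model

A push-broom VIS/NIR imager records counts per pixel and band. Reflectance
is recovered by black/white correction,

    R = (I_raw − I_dark) / (I_white − I_dark),

computed per pixel and band after averaging the reference frames over scan
rows (one reference spectrum per detector column — standard push-broom
practice; `calibrate` also accepts full-cube references and reduces them
the same way). Any averaged `white − dark ≤ 0` is an error, not a warning:
it indicates a saturated or occluded reference. A sample's spectrum is the
arithmetic mean of its region-of-interest pixels, trimmed to the closed
400–1000 nm interval. Models consume absorbance `A = log10(1/R)` with a
reflectance floor of 1e−6 guarding the logarithm.

## Pretreatments

All pretreatments act row-wise on the n×p spectra matrix, preserve
(n, p) and the wavelength axis, and append to the dataset's provenance:

* **MSC** — OLS fit `x ≈ a + b·ref` against a reference (default: the
  column-mean spectrum), corrected to `(x − a)/b`; removes per-spectrum
  affine distortions exactly. Slopes |b| < 1e−12 are an error.
* **SNV** — per-row standardization; the spread uses the n−1 (sample)
  denominator by convention, configurable via `ddof`.
* **Savitzky–Golay** — smoothing (deriv 0) or 1st/2nd derivative, default
  window 15 / polyorder 3, derivative scale per band-index step. Edges use
  the fitted polynomial (`mode="interp"`), so p is preserved. The window
  should track the physical band spacing: 15 points ≈ ±19 nm on a 225-band
  axis; on a 60-band axis the same physical width is a 5-point window, and
  a 15-point window there would flatten features only ~1.5 samples wide.
* **Mean centering** — column means are returned so the calibration-set
  means can be applied to new data.

## Partitioning and models

**SPXY** normalizes the pairwise Euclidean X-distances and y-distances
each by their maximum, sums them, seeds with the most distant pair and
grows the calibration set by max–min selection (ties to the smallest
index). It is deterministic; the calibration size is `round(n·f)` with
f = 2/3 by default. For classification the y-distance uses the
integer-coded class.

**PLS** is NIPALS PLS1 on centered data; for a single response the
per-component weight is closed-form, so the decomposition is exact and
fast, and components are nested — one decomposition yields predictions at
every smaller component count, which the cross-validation exploits. The
latent-variable count minimizes venetian-blind (interleaved) k-fold RMSECV
over 1..max_lv, ties to the smaller count; the model is refit on all
calibration rows at that count. The regression vector in band space is
`b = W(PᵀW)⁻¹q`; scores are orthogonal and the coefficient route equals
the latent route to 1e−8 (both are asserted in tests, and the vector is
cross-checked against an independent loop-coded NIPALS and against
scikit-learn's PLSRegression).

**PLS-DA** one-hot encodes the classes and fits PLS2 (iterative NIPALS,
500-iteration / 1e−10 convergence guard); the predicted class is the
argmax of the continuous prediction, exact ties to the lower class index.
The component count maximizes cross-validated accuracy by default
(RMSECV-based selection is available), ties again to the smaller count.

**Random forest** is the scikit-learn ensemble (500 trees, √p features
per split, Gini, seeded) behind the package's fit/predict surface.

Metrics: `R² = 1 − SS_res/SS_tot` (not squared correlation — the choice is
recorded in every report), `RMSE = sqrt(mean((y−ŷ)²))`, accuracy in
percent.

## Wavelength selection

**CARS** runs N sampling rounds over a shrinking variable pool. Round i:
(1) fit PLS on a Monte-Carlo draw of 80 % of the calibration rows
(without replacement) restricted to the pool; (2) force-retain the top
`round(r_i·p)` variables by |coefficient| with the exponential schedule
`r_i = a·e^(−k·i)`, `a = (p/2)^(1/(N−1))`, `k = ln(p/2)/(N−1)` — pinned so
r_1 = 1 (keep everything) and the final round keeps exactly 2; (3)
adaptive reweighted sampling: draw that many variables with replacement
with probability ∝ |coefficient| and retain the unique draws; (4) score
the survivors by k-fold RMSECV on all calibration rows. The subset with
the smallest criterion across rounds is selected. For classification the
criterion is `1 − CV accuracy`, recorded in the trace.

**Random frog** walks over subsets: the proposal size is
`round(Normal(Q_current, θ·Q_current))` clamped to [1, p] (θ = 0.3);
shrinking drops the weakest variables by |PLS coefficient| on the current
subset, growing ranks a superset of the current subset plus a random pool
of twice the deficit; a worse candidate is accepted with probability
`η·(score_old/score_new)` (η = 0.1). A band's selection probability is the
fraction of iterations whose accepted subset contained it; bands above the
0.1 threshold are selected. Two implementation details matter:

* *Scoring folds.* The walk's CV scoring uses 3 venetian folds by
  default. With many small folds the CV error of oversized subsets is
  underestimated and the chain drifts toward bloated selections; three
  large folds keep the equilibrium subset parsimonious.
* *Canonical column order.* The sampler runs in a canonical order obtained
  by sorting columns lexicographically by their values, and maps
  probabilities back at the end. Index draws are therefore tied to band
  content, not band position, making the selection probabilities exactly
  equivariant under band permutation.

Both selectors are stochastic; `cars_select_repeated` (best of R chains
by the criterion) and `frog_select_averaged` (probabilities pooled over R
chains, then thresholded) are the recommended stabilizations, mirroring
the common practice of running the frog many times and pooling.

## Synthetic data: what it emulates and what it does not

Each sample's ideal absorbance is

    A(λ) = A₀ + Σ_c amp_c · s_c · G(λ; μ_c, σ_c) + (b₀ + b₁·t)
           + δ·1[800 ≤ λ ≤ 850]·1[imported],

with Gaussian features for SSC (μ = 840.3 nm), K (641.51 nm), chlorophyll
(680 nm) and water (960 nm); s_c is the analyte concentration min–max
scaled to [0, 1] against its configured range (SSC 15.23–23.23 %,
K 80–200 mg/100 g), chlorophyll and water carry fixed unit strength, and
t is the normalized wavelength. The observation is `m·A + ε` with
`m ~ N(1, scatter_sd)` and iid band noise `ε ~ N(0, noise_sd)`; stored
reflectance is `10^(−A)`. Ground truth records the bands within one
feature width of each analyte center and all bands in the class window.

Default condition values: 99 samples, 225 bands over 400–1000 nm, 60 %
imported, analyte amplitudes 0.025 AU (features σ = 15 nm), chlorophyll
0.35 / water 0.25 AU, baseline 0.05 + 0.10·t, scatter_sd 0.01,
class offset 0.007 AU, noise_sd 0.002 AU. The amplitudes are deliberately
subtle — real sugar/mineral signatures ride on a much larger
pigment-and-water background — and were set jointly so that (i) the
planted SSC feature still dominates the variance at its own band
(raw-absorbance correlation with SSC ≈ 0.83–0.89), (ii) full-spectrum PLS
at the default noise lands in the realistically achievable range
(R²p ≈ 0.85–0.95) rather than a near-noiseless ceiling, leaving wavelength
selection measurable headroom, and (iii) the class offset is strong enough
for ≥ 90 % held-out discrimination yet does not swamp the SSC band it
overlaps. Noise is drawn from a seed-derived child stream and scaled by
`noise_sd`, so raising the noise level under a fixed seed rescales one
fixed realization — this makes "more noise never helps" a well-posed,
testable statement.

What the generator does **not** emulate: real banana biochemistry,
wavelength-dependent scatter, instrument point-spread functions, band-wise
correlated noise, or any nonlinearity between concentration and
absorbance. Passing tests therefore demonstrate that the algorithms
recover planted structure under the stated noise model — not field
performance on real fruit.

The cube generator plants one generated spectrum in an elliptical
foreground on a flat 0.05-reflectance background, with single-line dark
(100 counts) and white (4000 counts) reference frames constructed so that
calibration recovers the planted reflectance in expectation, exactly when
noise is zero.

## Problem sizes used by the test suite and acceptance script

Recovery and discrimination experiments run at 60 bands × 99 samples with
CARS at 50 runs / 10 folds (5 repeated chains) and random frog at 1000 –
2000 iterations (3–5 chains), 10 seeds — sizes chosen so the full
protocol, including the repeat-stabilized selectors, completes in a few
minutes while keeping the calibration set at the study scale (66 samples).
On the 60-band axis the Savitzky–Golay window is 5 (see above). The
acceptance script reports one seed-controlled replicate of each
experiment; the test suite asserts the across-seed regularities.

## Numerical choices and degenerate inputs

* NIPALS stops early (fewer components) when X deflates below 1e−12 of
  its norm; extracting zero components is an error.
* RMSECV folds that cannot support the requested component count
  contribute predictions at their largest achievable count.
* Ties: RMSECV/accuracy ties go to the smaller component count; argmax
  class ties to the lower class index; SPXY candidate ties to the smaller
  sample index; coefficient-ranking ties resolve by stable sort.
* Constant rows (SNV), near-zero MSC slopes, zero-variance responses,
  single-class label sets, empty ROIs, non-increasing wavelength axes and
  inconsistent ENVI headers all raise typed errors naming the offender.
* The frog threshold is allowed up to 1.0; selection uses a strict
  inequality, so a threshold of exactly 1.0 selects nothing.
* `restrict_dataset` records the retained fraction in percent (e.g.
  69/225 → 30.67 %) in the provenance of every reduced dataset.

## Known limitations

* PLS2/PLS-DA handles its one-hot response by iterative NIPALS; for
  two-class problems the response is effectively rank one and converges in
  a single pass, but many-class problems with near-collinear codes may hit
  the convergence guard.
* CARS' trace records the forced-retention schedule as `kept_count_per_run`
  (provably non-increasing, ends at 2); the post-resampling subsets in
  `subset_per_run` fluctuate below it.
* The ENVI reader supports BSQ/BIL/BIP with the common numeric dtypes and
  requires a wavelength list; esoteric header features (BIL with header
  offsets into foreign files, spectral libraries) are out of scope.
* Selection improves held-out accuracy *on average* under the default
  conditions, but not in every replicate — single-split R²p on 33
  prediction samples carries sampling noise of a few hundredths.
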