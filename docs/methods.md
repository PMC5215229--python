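# Methods

This package pre-processes Raman imaging data sets — an `m × n` matrix `X`
of `m` spectra over `n` wavenumber channels — by removing the two
contaminants that corrupt micro-Raman mapping measurements: smooth additive
baseline drifts (sample/background fluorescence, CCD thermal effects) and
narrow, strictly positive cosmic-ray spikes. Both stages use only the
spectral features of the data set itself; no instrument model or user-tuned
threshold is required.

## Baseline correction

Each spectrum `x` is decomposed as `x = x* + z`, with `z` a smooth baseline
obtained by minimising

```
Q(z) = Σᵢ wᵢ (xᵢ − zᵢ)² + λ ‖D z‖²
```

where `D` is the finite-difference matrix of order `diff_order` and `λ`
(`lambda_smooth`, default 1e7) sets the stiffness. For fixed weights the
minimiser solves the banded symmetric system `(W + λ DᵀD) z = W x`
(Whittaker smoothing), implemented with a banded Cholesky factorisation
(LAPACK `pbsv`; the penalty bands are cached per `(n, order)`), with a
sparse-LU fallback for systems that are not numerically positive definite.
A dense solve of the same system is the test oracle; the two agree to
≤ 1e−8 relative on random instances up to `n = 200`.

The weights adapt iteratively (`w⁰ = 1`): after each smooth fit, channels
with `xᵢ ≥ zᵢ` are treated as peak territory and get weight 0; channels
below keep `wᵢ = exp(t·(xᵢ − zᵢ)/|dᵗ|₁) ∈ (0, 1]`, where `dᵗ` collects the
negative residuals of iteration `t`. Iteration stops at `max_iter`
(default 20) or when `|dᵗ|₁ < term_ratio · ‖x‖₁` (default ratio 0.001). The
reported weight vector is the assignment implied by the final baseline, so
`wᵢ = 0 ⇔ xᵢ ≥ zᵢ` holds for the returned fit. Non-convergence is reported,
never raised, and corrected intensities are not clipped: negative values
are a display concern.

Two numerical choices matter and are this package's own:

* **Difference order defaults to 2.** The order-1 penalty at `λ = 1e7` has
  an effective smoothing length `√λ ≈ 3000` channels — over a typical
  1000-channel spectrum the fit collapses to a near-constant and cannot
  follow a drifting baseline at all (measured: < 35 % of peak-free channels
  within 3 noise σ on quadratic drifts). The order-2 penalty has an affine
  null space, so arbitrary tilts are free and low-order curvature is
  shrunk by only `~λ(π/n)⁴ ≈ 1e−3` — it tracks smooth drifts essentially
  exactly at the same λ. Order 1 remains available via `diff_order=1` for
  spectra where a stiff, nearly flat background is actually wanted.
* **Edge anchoring** (`edge_anchor`, default 0.02): during reweighting the
  first and last 2 % of channels keep weight 1. At a boundary the order-2
  penalty exerts no curvature cost, so once edge channels are down-weighted
  the fit can tilt away from the data there (sags of tens of counts over
  hundreds of channels were observed). Anchoring pins the ends; the
  fraction is small enough that, for the band layout modelled here, no
  Raman band sits in the anchored margins. Set 0 to disable.

## Spike removal

Spikes are found by comparing each baseline-corrected spectrum (BCS) with
its most similar spectrum (MSS) elsewhere in the data set:

1. **Features.** The channel–channel Pearson correlation matrix `R` of the
   corrected data is eigendecomposed (`numpy.linalg.eigh`; eigenvalues
   sorted descending, clipped at 0 against rounding). The proportion of
   variance `PRₖ = λₖ/Σλ` determines the retained count `q`: the smallest
   number of components whose cumulative proportion reaches
   `variance_threshold` (default 0.85). Scores are the standardized columns
   (population σ; zero-variance channels map to 0) projected on the first
   `q` eigenvectors — consistent with the correlation-matrix formulation.
   An independent SVD route and scikit-learn's PCA serve as test oracles.
   Zero-variance channels get correlation 0 — including the diagonal, so a
   dead channel contributes no variance share; this arises only in
   synthetic edge cases, not in real CCD data.
2. **MSS.** Squared Euclidean distances between score rows; the MSS of
   spectrum `i` is the argmin over other rows, ties broken toward the
   smaller index. Self-matches are excluded (a spectrum is trivially
   closest to itself).
3. **Affine fit and residual.** `y ≈ a·y* + b` by closed-form least
   squares absorbs scale/offset differences between a spectrum and its
   MSS; the residual `e = y − y_re` is divided by its own population
   standard deviation (no mean-centering — the division alone makes the
   detection independent of the intensity scale, and multiplying the data
   set by any constant leaves the spike mask unchanged). A constant MSS
   leaves the slope undefined; `a = 0, b = mean(y)` is returned with a
   warning.
4. **Thresholds.** The standardized residual rows are stacked into `E₀`;
   per channel, the positive entries (spikes are unidirectional) are
   sorted descending and a consecutive drop steeper than `deriv_threshold`
   (default −1) marks the boundary between spike outliers and normal
   residuals. When several drops qualify, the deepest rank is used so that
   spikes of different amplitude in the same channel are all flagged. Two
   guards apply:
   * channels with no qualifying drop get threshold +∞ (nothing flagged);
   * the anchoring entry must reach `residual_floor` (default 5.0). For
     small data sets (m ~ 100) consecutive gaps > 1 occur regularly between
     ordinary Gaussian order statistics (≈ 9 % of pure-noise columns at
     m = 100), and the bare derivative rule would flag them. Spikes are, by
     premise, far outside the normal residual range: a ≥ 10 σ spike
     standardizes to ≳ 8, while the expected maximum of pure Gaussian
     residuals over a 100 × 500 matrix is ≈ 4.2. The floor of 5 sits
     between the two; it is inactive at imaging scale (m ≳ 10⁴), where
     noise gaps are far below 1 anyway.
5. **Replacement.** Every super-threshold channel is a spike centre; a
   window of `spike_window` channels (default 41, odd) centred on it —
   clipped at the spectrum edges, merged when overlapping — is replaced by
   the fitted MSS model `y_re`. The window is deliberately much wider than
   the spikes themselves so that all affected wings are covered; outside
   the mask the spectrum is returned bit-identical.

If a chosen MSS's own candidate zones overlap the spectrum's candidate
zones, the repair would copy a spike into the gap; a provisional detection
pass therefore flags candidates first, and colliding references are demoted
to the next-nearest neighbour (up to `min(m−1, 5)` fallbacks, then the best
available is accepted). Data sets with fewer than 3 spectra are refused —
reference-based repair is meaningless there and single-spectrum filters are
the right tool — and a warning is logged below 10 spectra, where a close
spike-free reference may not exist.

**Two passes.** A spike occupying the same channel in a spectrum *and* its
MSS cancels in the residual and survives pass 1. The pass changes the data
(every other spectrum is repaired), and with it the similarity structure,
so the repeat pass (default `passes = 2`) sees the coincident spike against
a different or now-clean reference and removes it. The constructed
adversarial fixture (`coincident_spike_dataset`) demonstrates exactly this:
one pass leaves at least one of the coincident spikes, two passes repair
both.

## Synthetic data

The generator emulates the measurement this pipeline targets and supplies
exact ground truth (`observed = clean + baseline + noise + spikes`,
component-wise):

* **Signal**: Lorentzian/Gaussian bands at the poplar cell-wall positions
  (1095–2940 cm⁻¹; cellulose, hemicellulose, lignin) plus a broad D₂O band
  at 2490 cm⁻¹. Widths (12–160 cm⁻¹ FWHM) and relative amplitudes
  (200–900 counts) are generator choices typical of 532 nm excitation on
  wood sections. Default axis: 977 channels over 250–3100 cm⁻¹.
* **Baseline**: smooth positive shapes (linear, quadratic, exponential,
  sigmoid) with coefficients drawn per spectrum, scaled by
  `baseline_scale` (default 1500 counts — fluorescence comparable to or
  larger than the strongest band, as in lignified tissue).
* **Noise**: additive i.i.d. Gaussian per channel (CCD read-noise proxy),
  σ = 10 counts by default (SNR ≈ 100). Shot noise is deliberately not
  modelled so the additive truth stays exact.
* **Spikes**: with probability `spike_rate` (default 0.05) per spectrum, a
  triangular, strictly positive spike of width 1–5 channels and amplitude
  500–5000 counts — deliberately far narrower than the 41-channel
  replacement window.
* **Spatial structure**: per-pixel multiplicative amplitude jitter
  (σ = 5 %) plus an optional pattern modulating the lignin bands
  (`two_region`, `gradient`), so PCA score maps have recoverable structure.
  Pixels are emitted row-major (top row first, left to right); the mapping
  between scan order and image is configuration, not physics.

What passing tests on this generator do **not** show: behaviour under shot
noise and detector nonlinearity, correlated (striped) noise, wavenumber
calibration drift across the map, or genuinely overlapping band structure
changes — real cell-wall data have all of these. The generator's role is
to make each algorithmic contract falsifiable, not to simulate optics.

## Evaluation metrics

On synthetic truth, `evaluate` reports: baseline RMSE (estimated vs true
baselines); spike recall — a spike counts as recalled when at least half of
its injected channels are masked; precision and the channel false-positive
rate use an attribution radius of half a replacement window around each
true spike, because replacing a wide window around a real spike is the
intended behaviour, not a false positive. On spike-free truth the
false-positive rate reduces to the plain mask density. `pca_score_maps`
reshapes per-pixel scores of the leading components onto the imaging grid
(score maps, not loading vectors — a per-position image is by construction
a score); degenerate components (no supporting variance) are flagged
rather than guessed.

## Problem sizes and tolerances

The test suite and the acceptance script run on desk-scale problems:
spectra of 200–977 channels, maps of up to 100 × 500, 10 seeds for the
stochastic checks. Key tolerances: banded-vs-dense solver agreement
≤ 1e−8 relative with instance λ ≤ 1e6 (beyond that the dense oracle's own
rounding, cond ≈ 1e9, exceeds the level being certified); baseline
recovery within 3 noise σ on ≥ 95 % of peak-free channels; closed-form
regression vs normal equations ≤ 1e−12; detection recall ≥ 0.95 with
channel false-positive rate ≤ 0.01. Determinism: every stochastic path is
driven by `numpy.random.Generator` seeded explicitly; imaging data sets
spawn one child stream per pixel, so a data set is reproducible
bit-for-bit from `(arguments, seed)`.

## Known limitations

* The MSS search is O(m²) in the number of spectra; the distance matrix is
  retained in results only up to m = 2000.
* Very small data sets (m < 10) lack reliable references; the despiker
  warns and results may distort (m < 3 is refused).
* Baselines with step-like transitions (sigmoid with a short transition)
  exceed what an order-2 penalty at λ = 1e7 can follow; recovery there is
  partial, and a smaller λ trades smoothness for tracking.
* Spike zones wider than `spike_window` (instrument-dependent) would need a
  wider window; the width is a configuration knob, not adaptive.
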