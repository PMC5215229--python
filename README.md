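# apri — automatic pre-processing of Raman imaging data

Micro-Raman mapping of biological samples (here: poplar wood cell walls)
produces a matrix **X** of *m* spectra × *n* wavenumber channels that is
corrupted by two contaminants before any chemometric analysis can start:

* **baseline drifts** — smooth additive backgrounds from sample and
  background fluorescence and CCD thermal effects;
* **cosmic spikes** — narrow, strictly positive, high-intensity artifacts
  from cosmic rays hitting the detector.

`apri` removes both automatically, using only the spectral features of the
data set itself:

1. **Baseline correction** by adaptive iteratively reweighted penalized
   least squares: per spectrum, the baseline **z** minimises
   `Σᵢ wᵢ(xᵢ−zᵢ)² + λ‖Dz‖²` (Whittaker smoothing, banded sparse solve),
   with weights adapted iteratively — channels above the current baseline
   candidate are peak territory and get weight 0, channels below keep
   `exp(t·(xᵢ−zᵢ)/|dᵗ|₁)` — until `|dᵗ|₁ < 0.001·‖x‖₁` or 20 iterations.
2. **Despiking** by most-similar-spectrum (MSS) comparison in PCA space:
   the correlation matrix of the corrected channels is eigendecomposed,
   components are kept up to 85 % cumulative variance, and each spectrum is
   regressed (`y ≈ a·y* + b`) on its nearest neighbour in score space. The
   standardized residuals, rank-sorted per channel, exhibit an abrupt drop
   (derivative < −1) where spike outliers end; everything above that point
   is a spike centre, and a 41-channel window around each centre is
   replaced by the fitted reference model. A second pass (default) catches
   spikes that coincide in a spectrum and its reference.

The package also ships a synthetic-data generator with exact per-component
ground truth (clean poplar-like signal, baseline, noise, spikes), evaluation
metrics (baseline RMSE, spike recall/precision, channel false-positive
rate), and PCA score maps as a correction-quality diagnostic.
See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
import apri

# synthetic 10 x 10 pixel map: poplar-like bands + fluorescence baseline
# + Gaussian noise (sigma = 10 counts) + cosmic spikes in ~5% of spectra
ds, truth = apri.generate_imaging_dataset(
    rows=10, cols=10, axis=apri.default_axis(500), spike_rate=0.05, seed=1)

clean, reports = apri.apri(ds)          # 2 passes: baseline + despike

mask = np.zeros(ds.shape, dtype=bool)
for rep in reports:
    mask |= rep.despike.spike_mask
report = apri.evaluate(clean, truth, mask)
```

Running `python examples/03_full_pipeline.py` (the script above) prints:

```
spectra x channels:       100 x 500
injected spikes:          6
spike recall:             1.00
channel false positives:  0.0000
RMSE vs clean truth:      raw 1057.9 -> corrected 22.0 counts
```

All six injected spikes are found (recall 1.00) with no channel falsely
flagged, and the corrected matrix sits at roughly the noise floor
(~2 σ) instead of ~1000 counts of baseline away from the clean truth.
The other scripts in `examples/` walk through each capability: single-
spectrum baseline fitting, despiking mechanics, the generator's ground
truth and PCA score maps.

A thin CLI wraps the same functions:

```sh
apri simulate raw.csv --rows 20 --cols 20 --spike-rate 0.05 --seed 42 --truth truth.mat
apri run raw.csv clean.csv --passes 2 --mask mask.csv --report report.json
apri evaluate clean.csv --truth truth.mat --mask mask.csv
apri maps clean.csv --grid 20x20 -k 5 --out maps/
```

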