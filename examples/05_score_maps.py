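"""PCA score maps as a correction-quality diagnostic.

On a two-region sample (lignin-rich left half, lignin-poor right half) the
leading principal component of the corrected data should separate the two
regions cleanly; on the raw data the baseline drift dominates the variance
and blurs the chemistry.
"""

import numpy as np

import apri

ds, _ = apri.generate_imaging_dataset(
    rows=8, cols=12, axis=apri.default_axis(400),
    spatial_pattern="two_region", contrast=0.8,
    spike_rate=0.05, seed=3,
)

clean, _ = apri.apri(ds)


def separation(dataset, k):
    maps = apri.pca_score_maps(dataset, k).maps[k - 1]
    left, right = maps[:, :6], maps[:, 6:]
    return abs(left.mean() - right.mean()) / max(left.std(), right.std())


for k in (1, 2, 3):
    print(f"PC{k} region separation:  raw {separation(ds, k):6.2f}   "
          f"corrected {separation(clean, k):6.2f}")

# Separation is the between-region mean score difference in units of the
# within-region spread; > 3 means that component's image shows the two
# chemical regions clearly. The lignin contrast concentrates in one leading
# component (here PC2 — PC1 carries the global per-pixel intensity
# variation), and pre-processing preserves that spatial structure while
# removing the contaminants.
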