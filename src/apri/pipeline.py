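"""The full two-stage pre-processing pipeline.

One pass = baseline correction of every spectrum followed by PCA-based
despiking of the corrected matrix. A second pass (the default) repeats the
whole procedure on the output: spikes that coincide in a spectrum and its
most similar reference cancel in the first pass's residuals, but the pass
changes the data (and therefore the similarity structure), so the repeat
pass sees them against a different reference and removes them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .baseline import BaselineFitResult, correct_baseline_dataset
from .config import APRIConfig
from .dataset import SpectralImageDataset
from .despike import DespikeResult, despike_dataset

__all__ = ["PassReport", "apri"]


@dataclass
class PassReport:
    """Diagnostics of one pipeline pass: per-spectrum baseline fits and the despike result."""

    baseline_fits: list[BaselineFitResult]
    despike: DespikeResult


def apri(
    ds: SpectralImageDataset, cfg: APRIConfig | None = None
) -> tuple[SpectralImageDataset, list[PassReport]]:
    """Run ``cfg.passes`` rounds of baseline correction + despiking.

    Returns the cleaned data set (axis/grid metadata preserved) and one
    :class:`PassReport` per pass.
    """
    if cfg is None:
        cfg = APRIConfig()
    current = ds
    reports: list[PassReport] = []
    for _ in range(cfg.passes):
        corrected, fits = correct_baseline_dataset(current, cfg)
        result = despike_dataset(corrected.intensities, cfg)
        reports.append(PassReport(baseline_fits=fits, despike=result))
        current = ds.with_intensities(result.corrected)
    return current, reports
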