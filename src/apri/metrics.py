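"""Quantitative evaluation against synthetic ground truth, and PCA score maps.

The evaluation scores three things: how well the estimated baselines match
the true ones (RMSE), how well injected spikes were found (recall /
precision / channel false-positive rate), and how close the final output is
to the clean truth (residual RMSE). A spike counts as recalled when at least
half of its injected channels are masked. Because the repair deliberately
replaces a window much wider than the spike itself, masked channels within
half a window of a true spike are attributed to that spike; precision and
the false-positive rate are computed on that attribution.

PCA score maps reshape the per-pixel scores of the leading principal
components onto the imaging grid — the diagnostic used to compare the
spatial structure of raw versus corrected data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dataset import SpectralImageDataset
from .despike import pca_features, standardize_columns
from .exceptions import ValidationError
from .synthetic import SyntheticTruth

__all__ = ["EvaluationReport", "ScoreMaps", "evaluate", "pca_score_maps"]


@dataclass
class EvaluationReport:
    """Correction-quality summary on synthetic data with known truth."""

    baseline_rmse_per_spectrum: Optional[np.ndarray]
    baseline_rmse_mean: Optional[float]
    spike_recall: float
    spike_precision: float
    channel_false_positive_rate: float
    residual_to_truth_rmse: float
    n_spikes_true: int
    n_spikes_recalled: int


def evaluate(
    corrected: SpectralImageDataset | np.ndarray,
    truth: SyntheticTruth,
    mask: np.ndarray,
    estimated_baselines: Optional[np.ndarray] = None,
    spike_window: int = 41,
) -> EvaluationReport:
    """Score a corrected data set against its generator ground truth.

    ``mask`` is the boolean spike mask produced by despiking (union over
    passes, if several). ``estimated_baselines`` — the per-spectrum baselines
    subtracted by the pipeline — enables the baseline RMSE; pass None to skip
    it. ``spike_window`` sets the attribution radius for precision and the
    channel false-positive rate.
    """
    X = corrected.intensities if isinstance(corrected, SpectralImageDataset) else np.asarray(corrected, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if X.shape != truth.clean.shape or mask.shape != truth.clean.shape:
        raise ValidationError(
            f"shape mismatch: corrected {X.shape}, mask {mask.shape}, "
            f"truth {truth.clean.shape}"
        )
    m, n = X.shape
    half = spike_window // 2

    # per-spike recall: >= half of the injected channels masked
    spike_channels = truth.spikes > 0
    n_true = len(truth.spike_positions)
    n_recalled = 0
    attribution = np.zeros((m, n), dtype=bool)  # within half-window of any true spike
    recalled_zone = np.zeros((m, n), dtype=bool)
    for row, center, _amp, width in truth.spike_positions:
        left = (width - 1) // 2
        right = width // 2
        lo = max(0, center - left)
        hi = min(n, center + right + 1)
        injected = np.flatnonzero(spike_channels[row, lo:hi]) + lo
        if injected.size == 0:
            continue
        zone = slice(max(0, center - left - half), min(n, center + right + half + 1))
        attribution[row, zone] = True
        if mask[row, injected].sum() >= 0.5 * injected.size:
            n_recalled += 1
            recalled_zone[row, zone] = True
    recall = n_recalled / n_true if n_true else 1.0

    n_masked = int(mask.sum())
    if n_masked:
        precision = float((mask & recalled_zone).sum() / n_masked)
    else:
        precision = 1.0

    outside = ~attribution
    denom = int(outside.sum())
    fpr = float((mask & outside).sum() / denom) if denom else 0.0

    if estimated_baselines is not None:
        est = np.asarray(estimated_baselines, dtype=float)
        if est.shape != truth.baselines.shape:
            raise ValidationError("estimated_baselines shape mismatch")
        per_spectrum = np.sqrt(((est - truth.baselines) ** 2).mean(axis=1))
        baseline_mean = float(per_spectrum.mean())
    else:
        per_spectrum = None
        baseline_mean = None

    residual_rmse = float(np.sqrt(((X - truth.clean) ** 2).mean()))
    return EvaluationReport(
        baseline_rmse_per_spectrum=per_spectrum,
        baseline_rmse_mean=baseline_mean,
        spike_recall=float(recall),
        spike_precision=precision,
        channel_false_positive_rate=fpr,
        residual_to_truth_rmse=residual_rmse,
        n_spikes_true=n_true,
        n_spikes_recalled=n_recalled,
    )


@dataclass
class ScoreMaps:
    """Per-pixel principal-component scores reshaped onto the imaging grid.

    ``maps[k]`` is the rows × cols image of component k's scores; ``valid[k]``
    is False for degenerate components (no variance to support them).
    """

    maps: np.ndarray  # k x rows x cols
    valid: np.ndarray  # k booleans
    eigenvalues: np.ndarray


def pca_score_maps(ds: SpectralImageDataset, k: int) -> ScoreMaps:
    """Score images of the first ``k`` principal components of a mapped data set.

    Requires grid metadata. Pixels are assumed row-major (row 0 = top image
    row, left to right), matching the generator's emission order.
    """
    if ds.grid is None:
        raise ValidationError("pca_score_maps requires grid metadata")
    if k < 0 or k > min(ds.m, ds.n):
        raise ValidationError(f"k must lie in [0, min(m, n)] = [0, {min(ds.m, ds.n)}]")
    rows, cols = ds.grid.rows, ds.grid.cols
    if k == 0:
        return ScoreMaps(
            maps=np.empty((0, rows, cols)),
            valid=np.empty(0, dtype=bool),
            eigenvalues=np.empty(0),
        )
    X = ds.intensities
    centered = X - X.mean(axis=0)
    col_var = (centered**2).mean(axis=0)
    if not np.any(col_var > 0):
        # constant data set: no component is defined
        return ScoreMaps(
            maps=np.zeros((k, rows, cols)),
            valid=np.zeros(k, dtype=bool),
            eigenvalues=np.zeros(k),
        )
    model = pca_features(X, variance_threshold=1.0)
    scores = standardize_columns(X) @ model.eigenvectors[:, :k]
    total = model.eigenvalues.sum()
    valid = model.eigenvalues[:k] > 1e-12 * max(total, 1.0)
    return ScoreMaps(
        maps=scores.T.reshape(k, rows, cols),
        valid=valid,
        eigenvalues=model.eigenvalues[:k],
    )
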