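"""Cosmic-spike removal by most-similar-spectrum comparison in PCA space.

Cosmic rays hitting the CCD leave narrow, strictly positive, high-intensity
spikes in individual spectra. Because an imaging data set contains many
near-replicates of each spectrum, a spike can be recognised — and repaired —
by comparing each baseline-corrected spectrum (BCS) with its most similar
spectrum (MSS) elsewhere in the data set:

1. the channel–channel correlation matrix of the corrected data is
   eigendecomposed; the leading components that together explain
   ``variance_threshold`` of the variance become low-dimensional spectral
   features (scores);
2. the MSS of each spectrum is the one at minimal squared Euclidean distance
   in score space;
3. an affine fit ``y ≈ a·y* + b`` of the spectrum on its MSS absorbs scale
   and offset differences; the residual, divided by its own standard
   deviation, is scale-free;
4. stacking all standardized residuals row-wise gives a matrix whose columns
   are rank-sorted (descending, positive entries only — spikes are
   unidirectional); a drop steeper than ``deriv_threshold`` in a sorted
   column marks the boundary between spike outliers and normal residuals and
   sets that channel's threshold;
5. every super-threshold channel becomes a spike centre; a window of
   ``spike_window`` channels around each centre (merged when overlapping,
   clipped at the spectrum edges) is replaced by the fitted MSS model.

If a chosen MSS has spike candidates overlapping the spectrum's own
candidate zones it is demoted to the next-nearest reference (a few
fallbacks, then the best available is accepted).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .config import APRIConfig
from .exceptions import NumericalError, ValidationError

__all__ = [
    "PCAFeatureModel",
    "DespikeResult",
    "correlation_matrix",
    "standardize_columns",
    "pca_features",
    "pairwise_sq_distances",
    "find_mss",
    "linear_fit",
    "standardize_residual",
    "threshold_vector",
    "locate_and_replace",
    "despike_dataset",
]

logger = logging.getLogger(__name__)

# above this many spectra the m x m distance array is dropped from the result
_DISTANCE_KEEP_LIMIT = 2000
_MAX_MSS_FALLBACKS = 5


@dataclass
class PCAFeatureModel:
    """Eigenstructure of the channel correlation matrix.

    ``eigenvalues`` are sorted descending; ``proportions`` are the shares of
    total variance; ``retained_q`` is the smallest count whose cumulative
    proportion reaches the variance threshold; ``scores`` projects the
    standardized columns on the first ``retained_q`` eigenvectors.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # n x n, column k = k-th eigenvector
    proportions: np.ndarray
    retained_q: int
    scores: np.ndarray  # m x retained_q


@dataclass
class DespikeResult:
    """Outcome of despiking an ``m × n`` corrected matrix.

    ``corrected`` equals the input bit-exactly wherever ``spike_mask`` is
    False. ``mss_index``, ``reg_a`` and ``reg_b`` record, per spectrum, the
    reference used and the affine fit on it; ``residual_matrix`` stacks the
    standardized residual rows; ``threshold`` is the per-channel cut (+inf
    where no abrupt change was found); ``distances`` is the squared-distance
    array in score space, omitted (None) for very large data sets.
    """

    corrected: np.ndarray
    spike_mask: np.ndarray
    mss_index: np.ndarray
    reg_a: np.ndarray
    reg_b: np.ndarray
    residual_matrix: np.ndarray
    threshold: np.ndarray
    pca: PCAFeatureModel
    distances: Optional[np.ndarray] = None


def correlation_matrix(Xc: np.ndarray) -> np.ndarray:
    """Pearson correlation between the columns (channels) of ``Xc``.

    A zero-variance channel cannot be correlated with anything; its whole
    row/column (diagonal included) is set to 0 with a logged warning, so a
    dead channel carries no variance share in the eigendecomposition.
    """
    X = _check_matrix(Xc, min_rows=2)
    m, n = X.shape
    centered = X - X.mean(axis=0)
    std = np.sqrt((centered**2).mean(axis=0))
    valid = std > 0
    if not valid.all():
        logger.warning(
            "correlation_matrix: %d zero-variance channel(s); correlations set to 0",
            int((~valid).sum()),
        )
    R = np.zeros((n, n))
    if valid.any():
        Z = centered[:, valid] / std[valid]
        block = (Z.T @ Z) / m
        np.clip(block, -1.0, 1.0, out=block)
        idx = np.flatnonzero(valid)
        R[np.ix_(idx, idx)] = block
        R[idx, idx] = 1.0
    return R


def standardize_columns(Xc: np.ndarray) -> np.ndarray:
    """Columns centred and scaled to unit population variance (dead channels -> 0)."""
    X = _check_matrix(Xc, min_rows=2)
    centered = X - X.mean(axis=0)
    std = np.sqrt((centered**2).mean(axis=0))
    out = np.zeros_like(centered)
    valid = std > 0
    out[:, valid] = centered[:, valid] / std[valid]
    return out


def pca_features(Xc: np.ndarray, variance_threshold: float = 0.85) -> PCAFeatureModel:
    """Principal components of the channel correlation matrix.

    Components are sorted by descending eigenvalue; the first ``q`` with
    cumulative variance proportion ≥ ``variance_threshold`` are retained and
    the standardized columns are projected on them to give the ``m × q``
    feature (score) matrix.
    """
    X = _check_matrix(Xc, min_rows=2)
    if X.shape[1] < 2:
        raise ValidationError("need at least 2 channels for PCA")
    if not (0 < variance_threshold <= 1):
        raise ValidationError("variance_threshold must lie in (0, 1]")
    R = correlation_matrix(X)
    try:
        eigenvalues, eigenvectors = np.linalg.eigh(R)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            f"eigendecomposition failed (matrix norm {np.linalg.norm(R):.3g}, "
            f"shape {R.shape}): {exc}"
        ) from exc
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    eigenvectors = eigenvectors[:, order]
    total = eigenvalues.sum()
    if total <= 0:
        raise NumericalError(
            "correlation matrix has no variance (all channels constant)"
        )
    proportions = eigenvalues / total
    cumulative = np.cumsum(proportions)
    q = int(np.searchsorted(cumulative, variance_threshold - 1e-12) + 1)
    q = min(q, eigenvalues.size)
    scores = standardize_columns(X) @ eigenvectors[:, :q]
    return PCAFeatureModel(
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        proportions=proportions,
        retained_q=q,
        scores=scores,
    )


def pairwise_sq_distances(scores: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance between every pair of feature rows."""
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[1] < 1:
        raise ValidationError("scores must be a 2-D matrix with >= 1 column")
    D = squareform(pdist(S, metric="sqeuclidean"))
    np.fill_diagonal(D, 0.0)
    return D


def find_mss(D: np.ndarray, i: int, excluded: Iterable[int] = ()) -> int:
    """Index of the most similar spectrum to row ``i``.

    The candidate with minimal ``D[i, j]`` over ``j ∉ excluded ∪ {i}`` wins;
    ties break toward the smallest index. Raises if no candidate remains, in
    which case the caller should fall back to single-spectrum filtering.
    """
    D = np.asarray(D, dtype=float)
    m = D.shape[0]
    mask = np.ones(m, dtype=bool)
    mask[i] = False
    for e in excluded:
        mask[e] = False
    if not mask.any():
        raise ValidationError(
            "no reference spectrum remains after exclusions; "
            "use single-spectrum filtering for this case"
        )
    candidates = np.flatnonzero(mask)
    return int(candidates[np.argmin(D[i, candidates])])


def linear_fit(y_star, y) -> tuple[float, float, np.ndarray, float]:
    """Closed-form least squares of ``y`` on ``y_star``: ``y ≈ a·y* + b``.

    Returns ``(a, b, y_re, S)`` with ``y_re = a·y_star + b`` and ``S`` the
    sum of squared errors. A constant ``y_star`` leaves the slope undefined;
    ``a = 0, b = mean(y)`` is returned with a warning.
    """
    ys = np.asarray(y_star, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if ys.size != yv.size or ys.size < 2:
        raise ValidationError("vectors must share a length of at least 2")
    ys_mean = ys.mean()
    var = float(((ys - ys_mean) ** 2).sum())
    if var == 0.0:
        warnings.warn(
            "linear_fit: constant reference spectrum; slope undefined, using a=0",
            RuntimeWarning,
            stacklevel=2,
        )
        a, b = 0.0, float(yv.mean())
    else:
        a = float(((ys - ys_mean) * (yv - yv.mean())).sum() / var)
        b = float(yv.mean() - a * ys_mean)
    y_re = a * ys + b
    S = float(((yv - y_re) ** 2).sum())
    return a, b, y_re, S


def standardize_residual(e) -> np.ndarray:
    """Residual divided by its population standard deviation (0 if constant).

    Division by σ only — no mean-centering — which makes the result
    independent of the numerical range of the spectral intensities.
    """
    e = np.asarray(e, dtype=float).ravel()
    if e.size < 2:
        raise ValidationError("residual needs at least 2 entries")
    sigma = float(np.sqrt(((e - e.mean()) ** 2).mean()))
    if sigma == 0.0:
        return np.zeros_like(e)
    return e / sigma


def threshold_vector(
    E0: np.ndarray,
    deriv_threshold: float = -1.0,
    residual_floor: float = 5.0,
) -> np.ndarray:
    """Per-channel spike threshold from the standardized residual matrix.

    For each channel the positive residuals are sorted descending; where a
    consecutive drop steeper than ``deriv_threshold`` occurs, everything
    ranked at or above the deepest such drop is spike territory and the
    threshold is set to the residual value at that rank. Channels with no
    abrupt change get +inf (nothing flagged).

    ``residual_floor`` requires the anchoring entry itself to be an outlier
    (spikes sit far outside the normal residual range): in small data sets
    consecutive sorted-gap > |deriv_threshold| events occur between ordinary
    Gaussian order statistics, and without the floor they would be mistaken
    for spikes. See :class:`~apri.config.APRIConfig` for the sizing rationale.
    """
    E0 = _check_matrix(E0, min_rows=3)
    if not deriv_threshold < 0:
        raise ValidationError("deriv_threshold must be negative")
    if residual_floor < 0:
        raise ValidationError("residual_floor must be non-negative")
    m, n = E0.shape
    t = np.full(n, np.inf)
    for j in range(n):
        col = E0[:, j]
        pos = np.sort(col[col > 0])[::-1]
        if pos.size < 2:
            continue
        drops = np.diff(pos)  # negative steps between consecutive ranks
        qualifying = np.flatnonzero((drops < deriv_threshold)
                                    & (pos[:-1] >= residual_floor))
        if qualifying.size:
            t[j] = pos[qualifying.max()]
    return t


def locate_and_replace(
    y, y_re, e_std, t, spike_window: int = 41
) -> tuple[np.ndarray, np.ndarray]:
    """Replace spike zones of ``y`` by the fitted reference model ``y_re``.

    Channels with ``e_std >= t`` are spike centres; each centre expands to a
    ``spike_window``-channel zone (clipped at the edges, overlapping zones
    merged). Inside the mask the corrected spectrum takes ``y_re``; outside
    it is the input, bit-exact.
    """
    y = np.asarray(y, dtype=float).ravel()
    y_re = np.asarray(y_re, dtype=float).ravel()
    e_std = np.asarray(e_std, dtype=float).ravel()
    t = np.asarray(t, dtype=float).ravel()
    n = y.size
    if not (y_re.size == n and e_std.size == n and t.size == n):
        raise ValidationError("all vectors must share the same length")
    if spike_window < 1 or spike_window % 2 == 0:
        raise ValidationError("spike_window must be an odd positive integer")
    centers = np.flatnonzero(e_std >= t)
    mask = np.zeros(n, dtype=bool)
    half = spike_window // 2
    for c in centers:
        mask[max(0, c - half): min(n, c + half + 1)] = True
    corrected = y.copy()
    corrected[mask] = y_re[mask]
    return corrected, mask


def _candidate_masks(
    Xc: np.ndarray, mss_index: np.ndarray, cfg: APRIConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Detection pass for a fixed MSS assignment.

    Returns (E0, threshold, zone_masks, reg_a, reg_b); ``zone_masks`` holds
    the expanded (window-wide, merged) spike zones per spectrum.
    """
    m, n = Xc.shape
    E0 = np.empty_like(Xc)
    reg_a = np.empty(m)
    reg_b = np.empty(m)
    Yre = np.empty_like(Xc)
    for i in range(m):
        a, b, y_re, _ = linear_fit(Xc[mss_index[i]], Xc[i])
        reg_a[i] = a
        reg_b[i] = b
        Yre[i] = y_re
        E0[i] = standardize_residual(Xc[i] - y_re)
    t = threshold_vector(E0, cfg.deriv_threshold, cfg.residual_floor)
    masks = np.zeros((m, n), dtype=bool)
    for i in range(m):
        _, masks[i] = locate_and_replace(
            Xc[i], Yre[i], E0[i], t, cfg.spike_window
        )
    return E0, t, masks, reg_a, reg_b


def despike_dataset(Xc, cfg: APRIConfig | None = None) -> DespikeResult:
    """Detect and repair cosmic spikes across a baseline-corrected matrix.

    A provisional detection with nearest-neighbour references flags candidate
    spike zones; references whose own candidates collide with a spectrum's
    zones are then demoted to the next-nearest neighbour before the final
    detection and replacement. Refuses data sets with fewer than 3 spectra
    (single-spectrum filtering is the appropriate tool there) and warns below
    10, where a spike-free close reference may not exist.
    """
    if cfg is None:
        cfg = APRIConfig()
    X = _check_matrix(Xc, min_rows=1)
    m, n = X.shape
    if m < 3:
        raise ValidationError(
            "despiking needs at least 3 spectra; for fewer, use a "
            "single-spectrum filtering method instead"
        )
    if m < 10:
        logger.warning(
            "despike_dataset: only %d spectra; reference-based repair is "
            "unreliable for very small data sets", m,
        )
    pca = pca_features(X, cfg.variance_threshold)
    D = pairwise_sq_distances(pca.scores)
    neighbor_order = np.argsort(D, axis=1, kind="stable")

    def _nearest(i: int, skip: set[int]) -> int:
        for j in neighbor_order[i]:
            if j != i and j not in skip:
                return int(j)
        raise ValidationError("no reference spectrum available")

    # provisional pass: nearest neighbour for everyone
    mss0 = np.array([_nearest(i, set()) for i in range(m)])
    _, _, candidate_masks, _, _ = _candidate_masks(X, mss0, cfg)

    # demote references whose own candidate zones overlap this spectrum's
    mss = mss0.copy()
    for i in range(m):
        if not candidate_masks[i].any():
            continue
        skip: set[int] = set()
        choice: int | None = None
        for _ in range(min(m - 1, _MAX_MSS_FALLBACKS)):
            j = _nearest(i, skip)
            if not (candidate_masks[j] & candidate_masks[i]).any():
                choice = j
                break
            skip.add(j)
        if choice is None:
            choice = int(mss0[i])  # every fallback collided: accept the nearest
        mss[i] = choice

    E0, t, _, reg_a, reg_b = _candidate_masks(X, mss, cfg)
    corrected = np.empty_like(X)
    spike_mask = np.zeros((m, n), dtype=bool)
    Yre = reg_a[:, None] * X[mss] + reg_b[:, None]
    for i in range(m):
        corrected[i], spike_mask[i] = locate_and_replace(
            X[i], Yre[i], E0[i], t, cfg.spike_window
        )
    return DespikeResult(
        corrected=corrected,
        spike_mask=spike_mask,
        mss_index=mss,
        reg_a=reg_a,
        reg_b=reg_b,
        residual_matrix=E0,
        threshold=t,
        pca=pca,
        distances=D if m <= _DISTANCE_KEEP_LIMIT else None,
    )


def _check_matrix(X, min_rows: int = 1) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError(f"expected a 2-D matrix, got ndim={X.ndim}")
    if X.shape[0] < min_rows:
        raise ValidationError(f"need at least {min_rows} rows, got {X.shape[0]}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("matrix contains non-finite values")
    return X
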