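"""Baseline estimation by adaptive iteratively reweighted penalized least squares.

Fluorescence and detector drift put a smooth additive background under every
Raman spectrum. The estimator used here fits, per spectrum, a baseline ``z``
that balances weighted fidelity to the data against roughness:

    Q(z) = Σᵢ wᵢ (xᵢ − zᵢ)² + λ ‖D z‖²

where ``D`` is a finite-difference matrix (order 1 by default) and λ controls
stiffness. Minimising Q is a sparse banded linear solve,
``(W + λ DᵀD) z = W x`` — Whittaker smoothing. The weights are then adapted
iteratively: channels sitting above the current baseline candidate are treated
as peak territory and their weight is set to zero; channels below keep a
weight ``exp(t·(xᵢ − zᵢ)/|d|₁) ∈ (0, 1]`` where ``d`` collects the negative
residuals of iteration ``t``. Iteration stops when the mass of negative
residuals drops below ``term_ratio · ‖x‖₁`` or after ``max_iter`` rounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from .config import APRIConfig
from .dataset import SpectralImageDataset
from .exceptions import NumericalError, ValidationError

__all__ = [
    "BaselineFitResult",
    "whittaker_smooth",
    "airpls_baseline",
    "correct_baseline_dataset",
]


@dataclass
class BaselineFitResult:
    """Per-spectrum outcome of the baseline fit.

    ``corrected + baseline`` reconstructs the input exactly; ``weights`` is
    the final fidelity weight vector (0 on peak channels), ``converged``
    records whether the termination criterion fired before ``max_iter``.
    """

    baseline: np.ndarray
    corrected: np.ndarray
    weights: np.ndarray
    iterations_used: int
    converged: bool
    lambda_used: float


@lru_cache(maxsize=32)
def _penalty_bands(n: int, order: int) -> np.ndarray:
    """Upper banded form (rows = superdiagonals order..0) of DᵀD."""
    D = scipy.sparse.identity(n, format="csc")
    for _ in range(order):
        D = D[1:] - D[:-1]
    DtD = (D.T @ D).tocsc()
    bands = np.zeros((order + 1, n))
    for k in range(order + 1):
        bands[order - k, k:] = DtD.diagonal(k)
    return bands


def whittaker_smooth(
    x, w, lambda_smooth: float, diff_order: int = 1
) -> np.ndarray:
    """Solve ``(W + λ DᵀD) z = W x`` for the smooth vector ``z``.

    With unit weights and λ = 0 this is the identity; growing λ trades
    fidelity for smoothness. The banded symmetric system is solved with a
    banded Cholesky factorization (LAPACK ``pbsv``), falling back to a
    sparse LU solve if the matrix is not numerically positive definite.
    """
    x = np.asarray(x, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    n = x.size
    if diff_order not in (1, 2):
        raise ValidationError("diff_order must be 1 or 2")
    if n < diff_order + 1:
        raise ValidationError(f"need n >= {diff_order + 1} points, got {n}")
    if w.size != n:
        raise ValidationError("weight vector length must match x")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(w)):
        raise ValidationError("non-finite values in x or w")
    if np.any(w < 0):
        raise ValidationError("weights must be non-negative")
    if lambda_smooth < 0:
        raise ValidationError("lambda_smooth must be non-negative")
    if not np.any(w > 0):
        raise NumericalError(
            "all-zero weight vector leaves the system singular "
            "(constants lie in the null space of D)"
        )
    ab = lambda_smooth * _penalty_bands(n, diff_order)
    ab = np.array(ab, dtype=float)  # copy: cached template must stay pristine
    ab[diff_order] = ab[diff_order] + w
    rhs = w * x
    try:
        return scipy.linalg.solveh_banded(ab, rhs, lower=False)
    except np.linalg.LinAlgError:
        A = scipy.sparse.diags(w) + lambda_smooth * _penalty_csc(n, diff_order)
        return scipy.sparse.linalg.spsolve(A.tocsc(), rhs)


@lru_cache(maxsize=32)
def _penalty_csc(n: int, order: int):
    D = scipy.sparse.identity(n, format="csc")
    for _ in range(order):
        D = D[1:] - D[:-1]
    return (D.T @ D).tocsc()


def airpls_baseline(x, cfg: APRIConfig | None = None) -> BaselineFitResult:
    """Estimate and subtract the baseline of a single spectrum.

    Returns a :class:`BaselineFitResult` whose ``baseline`` is the final
    smooth fit and ``corrected = x − baseline``. Non-convergence within
    ``cfg.max_iter`` is reported, not raised.
    """
    if cfg is None:
        cfg = APRIConfig()
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValidationError("spectrum needs at least 2 channels")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite values in spectrum")
    n = x.size
    abs_x_l1 = np.abs(x).sum()
    n_anchor = int(np.ceil(cfg.edge_anchor * n)) if cfg.edge_anchor > 0 else 0
    w = np.ones(n)
    z = np.zeros(n)
    converged = False
    iterations = 0
    for t in range(1, cfg.max_iter + 1):
        z = whittaker_smooth(x, w, cfg.lambda_smooth, cfg.diff_order)
        iterations = t
        d = x - z
        neg = d < 0
        dssn = float(-d[neg].sum())
        if dssn < cfg.term_ratio * abs_x_l1 or dssn == 0.0:
            converged = True
            break
        if t == cfg.max_iter:
            break
        w.fill(0.0)
        # points above the candidate baseline are peak territory -> weight 0;
        # points below keep exp(t*(x-z)/|d|_1), which lies in (0, 1]
        w[neg] = np.exp(t * d[neg] / dssn)
        if n_anchor:
            # spectrum ends keep full fidelity weight so the (order-2) fit
            # cannot tilt away at the boundaries, where the roughness
            # penalty exerts no curvature cost
            w[:n_anchor] = 1.0
            w[-n_anchor:] = 1.0
    # report the weight assignment implied by the final baseline, so that
    # weight 0 <=> x_i >= z_i holds for the returned fit
    d = x - z
    neg = d < 0
    dssn = float(-d[neg].sum())
    w_final = np.zeros(n)
    if dssn > 0:
        w_final[neg] = np.exp(iterations * d[neg] / dssn)
    return BaselineFitResult(
        baseline=z,
        corrected=x - z,
        weights=w_final,
        iterations_used=iterations,
        converged=converged,
        lambda_used=cfg.lambda_smooth,
    )


def correct_baseline_dataset(
    ds: SpectralImageDataset, cfg: APRIConfig | None = None
) -> tuple[SpectralImageDataset, list[BaselineFitResult]]:
    """Baseline-correct every spectrum of a data set independently.

    Row ``i`` of the output is ``airpls_baseline(row i).corrected``; order and
    shape are preserved and per-row validation errors carry the row index.
    """
    if cfg is None:
        cfg = APRIConfig()
    X = ds.intensities
    corrected = np.empty_like(X)
    fits: list[BaselineFitResult] = []
    for i in range(X.shape[0]):
        try:
            fit = airpls_baseline(X[i], cfg)
        except ValidationError as exc:
            raise ValidationError(f"spectrum {i}: {exc}") from exc
        corrected[i] = fit.corrected
        fits.append(fit)
    return ds.with_intensities(corrected), fits
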