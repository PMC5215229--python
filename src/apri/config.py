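"""Pipeline configuration.

One flat configuration object carries every tunable of the two-stage
pre-processing pipeline (baseline correction followed by despiking), so that
the whole run is reproducible from a single record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Any, Mapping

from .exceptions import ValidationError

__all__ = ["APRIConfig"]


@dataclass
class APRIConfig:
    """Tunable parameters of the pre-processing pipeline.

    Parameters
    ----------
    lambda_smooth
        Roughness-penalty weight λ of the Whittaker smoother used inside the
        baseline fit. Larger values give smoother (stiffer) baselines.
    max_iter
        Maximum number of reweighting iterations of the baseline fit.
    term_ratio
        Termination ratio: iteration stops when the L1 norm of the negative
        residuals falls below ``term_ratio`` times the L1 norm of the spectrum.
    diff_order
        Order of the finite-difference roughness penalty (1 or 2). The
        default 2 matches the reference airPLS implementation: its null
        space contains affine trends, so at large λ the fit still tracks
        smoothly drifting baselines. Order 1 at λ ~ 1e7 forces a nearly
        constant baseline over ~1000 channels.
    edge_anchor
        Fraction of channels at each spectrum end whose fidelity weight is
        pinned to 1 during reweighting (the reference implementation's
        "weight exception"), preventing the fit from tilting away at the
        boundaries. 0 disables anchoring.
    variance_threshold
        Cumulative proportion of variance retained when choosing the number
        of principal components used as spectral features.
    spike_window
        Odd width, in channels, of the replacement zone centred on each
        detected spike channel.
    deriv_threshold
        Negative cut on the discrete derivative of the rank-sorted
        standardized-residual columns; a drop steeper than this marks the
        threshold point of a channel.
    residual_floor
        Minimum standardized-residual value an entry must reach before it
        can anchor a channel threshold. Spikes are, by premise, far outside
        the normal residual range: a genuine spike of ≥10 noise σ
        standardizes to ≳8, while the expected maximum of pure Gaussian
        residuals over an entire desk-scale matrix is ≈ 4. The default 5
        therefore rejects sorted-gap events produced by noise order
        statistics in small data sets (where consecutive-gap > 1 events
        are common) without touching real spikes; it is inactive at
        imaging scale (m ≳ 10⁴), where noise gaps are tiny anyway.
        Set 0 to disable.
    passes
        Number of full pipeline passes. Two passes resolve spikes that
        coincide in a spectrum and its most similar reference.
    seed
        Optional seed forwarded to stochastic helpers (synthetic data).
    """

    lambda_smooth: float = 1e7
    max_iter: int = 20
    term_ratio: float = 0.001
    diff_order: int = 2
    edge_anchor: float = 0.02
    variance_threshold: float = 0.85
    spike_window: int = 41
    deriv_threshold: float = -1.0
    residual_floor: float = 5.0
    passes: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.lambda_smooth > 0:
            raise ValidationError("lambda_smooth must be positive")
        if not (isinstance(self.max_iter, int) and self.max_iter >= 1):
            raise ValidationError("max_iter must be a positive integer")
        if not self.term_ratio > 0:
            raise ValidationError("term_ratio must be positive")
        if self.diff_order not in (1, 2):
            raise ValidationError("diff_order must be 1 or 2")
        if not (0 <= self.edge_anchor < 0.5):
            raise ValidationError("edge_anchor must lie in [0, 0.5)")
        if not (0 < self.variance_threshold <= 1):
            raise ValidationError("variance_threshold must lie in (0, 1]")
        if not (isinstance(self.spike_window, int) and self.spike_window >= 1
                and self.spike_window % 2 == 1):
            raise ValidationError("spike_window must be an odd positive integer")
        if not self.deriv_threshold < 0:
            raise ValidationError("deriv_threshold must be negative")
        if self.residual_floor < 0:
            raise ValidationError("residual_floor must be non-negative")
        if not (isinstance(self.passes, int) and self.passes >= 1):
            raise ValidationError("passes must be a positive integer")

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if getattr(self, f.name) is not None}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "APRIConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**dict(mapping))
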