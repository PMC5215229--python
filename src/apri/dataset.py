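"""Core domain types: wavenumber axis, imaging grid, spectral data set.

A Raman imaging measurement is stored as an ``m × n`` matrix: one row per
recorded position (spectrum) and one column per wavenumber channel. All
algorithms in this package operate on the channel index; the wavenumber axis
is carried along only for labelling and plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "WavenumberAxis",
    "GridGeometry",
    "SpectralImageDataset",
    "grid_dimensions",
]


class WavenumberAxis:
    """Strictly monotonic spectral axis in cm⁻¹, stored increasing.

    A decreasing axis (some spectrometers emit high-to-low) is normalized to
    increasing order; :attr:`reversed_on_input` records whether that happened
    so callers can flip the matching intensity columns.
    """

    __slots__ = ("values", "reversed_on_input")

    def __init__(self, values) -> None:
        arr = np.asarray(values, dtype=float).ravel()
        if arr.size < 2:
            raise ValidationError("wavenumber axis needs at least 2 points")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("wavenumber axis contains non-finite values")
        diffs = np.diff(arr)
        if np.all(diffs > 0):
            self.reversed_on_input = False
        elif np.all(diffs < 0):
            arr = arr[::-1].copy()
            self.reversed_on_input = True
        else:
            raise ValidationError("wavenumber axis must be strictly monotonic")
        self.values = arr

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return isinstance(other, WavenumberAxis) and np.array_equal(
            self.values, other.values
        )

    def __repr__(self) -> str:
        v = self.values
        return f"WavenumberAxis({v[0]:g}..{v[-1]:g} cm-1, n={v.size})"


@dataclass(frozen=True)
class GridGeometry:
    """Spatial raster of a mapping measurement: rows × cols pixels, step in μm."""

    rows: int
    cols: int
    step_um: float

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValidationError("grid rows and cols must be positive integers")
        if not self.step_um > 0:
            raise ValidationError("grid step_um must be positive")

    @property
    def n_pixels(self) -> int:
        return self.rows * self.cols


class SpectralImageDataset:
    """An ``m × n`` matrix of spectra with optional axis and grid metadata.

    Rows are spectra (one per mapped position), columns are wavenumber
    channels. Non-finite entries are rejected on construction: the linear
    algebra downstream assumes complete spectra.
    """

    __slots__ = ("intensities", "axis", "grid")

    def __init__(
        self,
        intensities,
        axis: Optional[WavenumberAxis] = None,
        grid: Optional[GridGeometry] = None,
    ) -> None:
        arr = np.asarray(intensities, dtype=float)
        if arr.ndim == 1:
            arr = arr[np.newaxis, :]
        if arr.ndim != 2:
            raise ValidationError(f"intensities must be 2-D, got ndim={arr.ndim}")
        m, n = arr.shape
        if m < 1 or n < 2:
            raise ValidationError(f"need m >= 1 spectra and n >= 2 channels, got {m} x {n}")
        bad = ~np.isfinite(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite intensity at row {i}, column {j}"
            )
        if axis is not None:
            if len(axis) != n:
                raise ValidationError(
                    f"axis length {len(axis)} does not match n={n} channels"
                )
            if axis.reversed_on_input:
                # keep column order consistent with the (now increasing) axis
                arr = arr[:, ::-1]
                axis = WavenumberAxis(axis.values)  # already increasing
        if grid is not None and grid.n_pixels != m:
            raise ValidationError(
                f"grid {grid.rows} x {grid.cols} = {grid.n_pixels} pixels "
                f"does not match m={m} spectra"
            )
        self.intensities = np.ascontiguousarray(arr)
        self.axis = axis
        self.grid = grid

    @property
    def m(self) -> int:
        """Number of spectra."""
        return self.intensities.shape[0]

    @property
    def n(self) -> int:
        """Number of wavenumber channels."""
        return self.intensities.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def with_intensities(self, intensities) -> "SpectralImageDataset":
        """New data set sharing this one's axis/grid metadata."""
        return SpectralImageDataset(intensities, axis=self.axis, grid=self.grid)

    def __repr__(self) -> str:
        bits = [f"SpectralImageDataset(m={self.m}, n={self.n}"]
        if self.grid is not None:
            bits.append(f", grid={self.grid.rows}x{self.grid.cols}")
        return "".join(bits) + ")"


def grid_dimensions(
    width_um: float, height_um: float, step_um: float
) -> tuple[int, int, int]:
    """Pixel counts of a mapping raster covering ``width_um × height_um``.

    The convention is steps-per-axis = floor(extent / step): a 65 × 49.5 μm
    region at 0.5 μm/pixel yields 130 × 99 = 12,870 spectra. Returns
    ``(cols, rows, m)`` with ``cols`` along the width.
    """
    if not (width_um > 0 and height_um > 0 and step_um > 0):
        raise ValidationError("width, height and step must all be positive")
    if step_um > width_um or step_um > height_um:
        raise ValidationError("step exceeds an extent; at least one pixel must fit per axis")
    # round to 9 decimals first so 49.5/0.5 -> 99.0 survives binary rounding
    cols = int(math.floor(round(width_um / step_um, 9)))
    rows = int(math.floor(round(height_um / step_um, 9)))
    return cols, rows, cols * rows
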