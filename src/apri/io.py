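"""Readers and writers for spectral matrices and sidecar configuration.

Two on-disk formats are supported for the ``m × n`` intensity matrix:

* delimited text (CSV/TSV; delimiter auto-detected, decimal point only,
  no header row unless requested), which stores the matrix alone;
* MATLAB MAT-file v5, which can additionally carry the wavenumber axis and
  the imaging-grid metadata in named variables.

Grid metadata and pipeline configuration for delimited files travel in a
TOML sidecar file (see :func:`write_sidecar` / :func:`read_sidecar`).
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.io

from .config import APRIConfig
from .dataset import GridGeometry, SpectralImageDataset, WavenumberAxis
from .exceptions import FormatError, ValidationError

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_sidecar",
    "write_sidecar",
]

_MAT_MATRIX_KEY = "intensities"
_MAT_AXIS_KEY = "wavenumbers"


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        if format not in ("delimited", "mat"):
            raise ValidationError(f"unknown format {format!r}; use 'delimited' or 'mat'")
        return format
    return "mat" if path.suffix.lower() == ".mat" else "delimited"


def _sniff_delimiter(line: str) -> Optional[str]:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # whitespace split


def _parse_delimited(path: Path, header: bool) -> np.ndarray:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    rows: list[tuple[int, list[str]]] = []  # (1-based line number, cells)
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        delim = _sniff_delimiter(line) if not rows else rows_delim
        if not rows:
            rows_delim = delim
        cells = line.split(delim) if delim else line.split()
        rows.append((lineno, [c.strip() for c in cells]))
    if header and rows:
        rows = rows[1:]
    if not rows:
        raise FormatError(f"{path}: file contains no data rows")
    ncols = len(rows[0][1])
    data = np.empty((len(rows), ncols), dtype=float)
    for i, (lineno, cells) in enumerate(rows):
        if len(cells) != ncols:
            raise FormatError(
                f"{path}: ragged row at line {lineno} "
                f"({len(cells)} fields, expected {ncols})"
            )
        try:
            data[i] = np.asarray(cells, dtype=float)
        except ValueError:
            for j, cell in enumerate(cells):
                try:
                    float(cell)
                except ValueError:
                    raise ValidationError(
                        f"{path}: non-numeric value {cell!r} at line {lineno}, "
                        f"column {j + 1}"
                    ) from None
            raise
    bad = ~np.isfinite(data)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: non-finite value at data row {i + 1}, column {j + 1}"
        )
    return data


def _load_mat(path: Path) -> SpectralImageDataset:
    try:
        contents = scipy.io.loadmat(path)
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"{path}: not a readable MAT v5 file ({exc})") from exc
    matrix = None
    if _MAT_MATRIX_KEY in contents:
        matrix = np.asarray(contents[_MAT_MATRIX_KEY])
    else:
        for key, value in contents.items():
            if key.startswith("__"):
                continue
            arr = np.asarray(value)
            if arr.ndim == 2 and arr.size > 1 and np.issubdtype(arr.dtype, np.number):
                matrix = arr
                break
    if matrix is None:
        raise FormatError(f"{path}: no 2-D numeric array found in MAT container")
    axis = None
    if _MAT_AXIS_KEY in contents:
        axis = WavenumberAxis(np.asarray(contents[_MAT_AXIS_KEY], dtype=float).ravel())
    grid = None
    if all(k in contents for k in ("grid_rows", "grid_cols", "grid_step_um")):
        grid = GridGeometry(
            rows=int(np.asarray(contents["grid_rows"]).ravel()[0]),
            cols=int(np.asarray(contents["grid_cols"]).ravel()[0]),
            step_um=float(np.asarray(contents["grid_step_um"]).ravel()[0]),
        )
    return SpectralImageDataset(matrix.astype(float), axis=axis, grid=grid)


def read_dataset(
    path,
    format: Optional[str] = None,
    header: bool = False,
) -> SpectralImageDataset:
    """Load a spectral matrix from a delimited text file or MAT v5 container.

    Rows are spectra, columns are channels. ``format`` defaults to ``"mat"``
    for ``*.mat`` paths and ``"delimited"`` otherwise. ``header=True`` skips
    one leading header line of a delimited file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "mat":
        return _load_mat(path)
    return SpectralImageDataset(_parse_delimited(path, header=header))


def write_dataset(
    ds: SpectralImageDataset,
    path,
    format: Optional[str] = None,
) -> None:
    """Write a data set so that :func:`read_dataset` reproduces the matrix.

    Delimited output stores the matrix only (full ``%.17g`` precision, so
    float64 values round-trip bit-exactly); axis and grid metadata belong in
    a sidecar file. MAT output stores matrix, axis and grid together.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "mat":
        payload: dict = {_MAT_MATRIX_KEY: ds.intensities}
        if ds.axis is not None:
            payload[_MAT_AXIS_KEY] = ds.axis.values
        if ds.grid is not None:
            payload["grid_rows"] = ds.grid.rows
            payload["grid_cols"] = ds.grid.cols
            payload["grid_step_um"] = ds.grid.step_um
        scipy.io.savemat(path, payload, format="5", oned_as="row")
    else:
        delim = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
        np.savetxt(path, ds.intensities, fmt="%.17g", delimiter=delim)


def write_sidecar(
    path,
    config: Optional[APRIConfig] = None,
    grid: Optional[GridGeometry] = None,
) -> None:
    """Write pipeline configuration and grid metadata as a small TOML file."""
    lines: list[str] = []
    if config is not None:
        lines.append("[apri]")
        for key, value in config.to_dict().items():
            lines.append(f"{key} = {_toml_scalar(value)}")
        lines.append("")
    if grid is not None:
        lines.append("[grid]")
        lines.append(f"rows = {grid.rows}")
        lines.append(f"cols = {grid.cols}")
        lines.append(f"step_um = {_toml_scalar(grid.step_um)}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def read_sidecar(path) -> tuple[Optional[APRIConfig], Optional[GridGeometry]]:
    """Read a sidecar file written by :func:`write_sidecar`."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    config = APRIConfig.from_mapping(doc["apri"]) if "apri" in doc else None
    grid = None
    if "grid" in doc:
        g = doc["grid"]
        grid = GridGeometry(rows=int(g["rows"]), cols=int(g["cols"]),
                            step_um=float(g["step_um"]))
    return config, grid


def _toml_scalar(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        return repr(float(value))
    return f'"{value}"'
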