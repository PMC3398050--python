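"""Raster containers shared by all model components.

All grids in this package live on a torus: opposite edges are adjacent,
so home ranges and neighbourhood means never see a boundary.  Cells are
addressed ``(row, col)``, 0-based, row-major, origin at the top-left.
The analysis resolution is 15 m (one trap-grid interval).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

#: side length of one analysis cell, metres
DEFAULT_RESOLUTION = 15.0

#: area of one cell in hectares (15 m x 15 m = 225 m^2)
CELL_AREA_HA = DEFAULT_RESOLUTION * DEFAULT_RESOLUTION / 10_000.0


def _as_grid(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("grid values must be a non-empty 2-D array")
    if not np.all(np.isfinite(arr)):
        raise ValueError("grid values must be finite")
    return arr


@dataclass(frozen=True)
class ResourceGrid:
    """Per-cell amount of one habitat resource (shrub, DWD, shade, substrate).

    Values are in the units the resource was sampled in; they must be
    finite and non-negative.
    """

    name: str
    values: np.ndarray
    resolution: float = DEFAULT_RESOLUTION

    def __post_init__(self):
        arr = _as_grid(self.values)
        if np.any(arr < 0):
            raise ValueError(f"resource {self.name!r} has negative cell values")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ValueGrid:
    """Per-cell habitat value V, the substrate all home-range computation uses.

    ``baseline`` records the constant subtracted when the grid was derived
    from resource layers (the lowest-value local habitat in the calibration
    data); it is 0.0 for grids loaded directly from file.
    """

    values: np.ndarray
    resolution: float = DEFAULT_RESOLUTION
    baseline: float = 0.0

    def __post_init__(self):
        arr = _as_grid(self.values)
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return self.values.size

    @property
    def mean_value(self) -> float:
        return float(self.values.mean())


def toroidal_neighbours(shape: tuple[int, int]) -> np.ndarray:
    """Rook (4-neighbour) adjacency table under toroidal wrap.

    Returns an ``(n, 4)`` int array of flat indices: up, down, left, right
    of every cell in row-major order.
    """
    nrow, ncol = shape
    idx = np.arange(nrow * ncol).reshape(nrow, ncol)
    up = np.roll(idx, 1, axis=0)
    down = np.roll(idx, -1, axis=0)
    left = np.roll(idx, 1, axis=1)
    right = np.roll(idx, -1, axis=1)
    return np.stack([up, down, left, right], axis=-1).reshape(-1, 4).astype(np.int64)


def toroidal_distance_offsets(shape: tuple[int, int], resolution: float) -> np.ndarray:
    """Matrix of centre-to-centre toroidal distances for all (drow, dcol) offsets."""
    nrow, ncol = shape
    dr = np.arange(nrow)
    dc = np.arange(ncol)
    dr = np.minimum(dr, nrow - dr) * resolution
    dc = np.minimum(dc, ncol - dc) * resolution
    return np.hypot(dr[:, None], dc[None, :])


# ---------------------------------------------------------------------------
# File formats: headerless matrix CSV and ESRI ASCII grid
# ---------------------------------------------------------------------------

_ESRI_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_grid(path: Union[str, Path], resolution: float | None = None) -> np.ndarray:
    """Read a matrix CSV or ESRI ASCII grid; dialect sniffed from the header.

    Returns the raw 2-D array; wrap it in :class:`ResourceGrid` or
    :class:`ValueGrid` as appropriate.  For ESRI grids the header cellsize
    must equal 15 unless ``resolution`` overrides it.
    """
    path = Path(path)
    text = path.read_text()
    first = text.lstrip().split(None, 1)[0].lower()
    if first == "ncols":
        return _read_esri(text, resolution)
    return np.atleast_2d(np.loadtxt(io.StringIO(text), delimiter=","))


def _read_esri(text: str, resolution: float | None) -> np.ndarray:
    lines = text.splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ESRI_KEYS + ("nodata_value",):
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"ESRI ASCII grid missing header key {key!r}")
    expect = resolution if resolution is not None else DEFAULT_RESOLUTION
    if abs(header["cellsize"] - expect) > 1e-9:
        raise ValueError(
            f"cellsize {header['cellsize']} does not match expected {expect}"
        )
    arr = np.loadtxt(io.StringIO("\n".join(lines[body_start:])))
    arr = np.atleast_2d(arr)
    if arr.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ESRI ASCII grid body does not match declared shape")
    return arr


def write_grid_csv(path: Union[str, Path], values: np.ndarray) -> None:
    np.savetxt(path, np.asarray(values, dtype=float), delimiter=",", fmt="%.10g")


def write_grid_esri(
    path: Union[str, Path], values: np.ndarray, resolution: float = DEFAULT_RESOLUTION
) -> None:
    values = np.asarray(values, dtype=float)
    nrow, ncol = values.shape
    header = (
        f"ncols {ncol}\nnrows {nrow}\nxllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize {resolution:g}\nNODATA_value -9999\n"
    )
    body = "\n".join(" ".join(f"{v:.10g}" for v in row) for row in values)
    Path(path).write_text(header + body + "\n")
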