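"""Raster grid containers and TIFF/JSON round-trip I/O.

Grids are planar and equal-area: every cell covers the same ``cell_area``
(km²), matching the uniform 1-km² framing of gridded bioclimatic analyses.
Rasters are stored as float arrays with NaN at nodata cells plus an explicit
boolean validity mask shared by all layers of a stack.

On disk a stack is a directory of single-band float32 TIFF files (one per
variable, NaN nodata) and a ``grid.json`` sidecar with the grid geometry and
layer order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "BIOCLIM_VARS",
    "PRECIP_VARS",
    "TEMPERATURE_LEVEL_VARS",
    "SEASONALITY_VARS",
    "GridSpec",
    "RasterStack",
    "BioclimStack",
    "PCStack",
    "read_stack",
    "write_stack",
]

#: The 19 standard bioclimatic variables, in canonical order.
BIOCLIM_VARS: tuple[str, ...] = tuple(f"BIO{i}" for i in range(1, 20))

#: Precipitation-based bioclims (mm or CV): the default log-transform set.
PRECIP_VARS: tuple[str, ...] = tuple(f"BIO{i}" for i in range(12, 20))

#: Temperature-level layers (°C) that shift additively under mean warming.
#: Range-type layers (BIO2, BIO3, BIO7) are invariant to a uniform shift.
TEMPERATURE_LEVEL_VARS: tuple[str, ...] = (
    "BIO1", "BIO5", "BIO6", "BIO8", "BIO9", "BIO10", "BIO11",
)

#: Seasonality layers that scale multiplicatively under seasonality inflation.
SEASONALITY_VARS: tuple[str, ...] = ("BIO4", "BIO15")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a planar equal-area raster grid.

    ``(x_origin, y_origin)`` is the top-left corner of the top-left cell;
    x increases with column index, y decreases with row index. ``resolution``
    is the cell side length in the planar coordinate units; ``cell_area`` is
    the area represented by one cell, in km². ``nodata_fraction`` is the
    fraction of cells a synthetic generator should void (always < 1).
    """

    n_rows: int
    n_cols: int
    cell_area: float = 1.0
    x_origin: float = 0.0
    y_origin: float = 0.0
    resolution: float = 1.0
    nodata_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not 0.0 <= self.nodata_fraction < 1.0:
            raise ValueError("nodata_fraction must lie in [0, 1)")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def bounds(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the grid extent."""
        return (
            self.x_origin,
            self.y_origin - self.n_rows * self.resolution,
            self.x_origin + self.n_cols * self.resolution,
            self.y_origin,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates as 2-D arrays ``(x, y)`` of grid shape."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.x_origin + (cols + 0.5) * self.resolution
        y = self.y_origin - (rows + 0.5) * self.resolution
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(
            y[:, None], self.shape
        ).copy()

    def locate(self, x, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map planar coordinates to (row, col) cell indices.

        Cells are half-open ``[x0, x0+res) × (y0-res, y0]``; points exactly
        on the grid's outer right or bottom edge are assigned to the adjacent
        interior cell. Returns ``(row, col, inside)`` where ``inside`` flags
        points within the grid extent.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x_min, y_min, x_max, y_max = self.bounds()
        inside = (x >= x_min) & (x <= x_max) & (y >= y_min) & (y <= y_max)
        col = np.floor((x - x_min) / self.resolution).astype(int)
        row = np.floor((y_max - y) / self.resolution).astype(int)
        # outer-edge snap: x == x_max or y == y_min land one index out
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.clip(row, 0, self.n_rows - 1)
        return row, col, inside


@dataclass
class RasterStack:
    """A set of congruent raster layers with one shared validity mask.

    ``data`` has shape ``(n_layers, n_rows, n_cols)`` and holds NaN at every
    nodata cell; ``mask`` is True at valid cells.
    """

    names: tuple[str, ...]
    data: np.ndarray
    mask: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.names):
            raise ValueError("data must be (n_layers, n_rows, n_cols)")
        if self.data.shape[1:] != self.grid.shape:
            raise ValueError("data shape does not match grid")
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        self.data[:, ~self.mask] = np.nan

    @property
    def n_layers(self) -> int:
        return len(self.names)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def layer(self, name: str) -> np.ndarray:
        try:
            return self.data[self.names.index(name)]
        except ValueError:
            raise KeyError(f"layer {name!r} not in stack") from None

    def valid_table(self) -> np.ndarray:
        """Values at valid cells as an ``(n_valid, n_layers)`` array.

        Cells are ordered row-major, matching ``valid_indices``.
        """
        return self.data[:, self.mask].T

    def valid_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of valid cells in row-major order."""
        return np.nonzero(self.mask)

    def with_data(self, data: np.ndarray, names: tuple[str, ...] | None = None):
        return replace(self, data=data, names=self.names if names is None else names)


@dataclass
class BioclimStack(RasterStack):
    """A RasterStack holding exactly the 19 bioclimatic variables."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if tuple(self.names) != BIOCLIM_VARS:
            missing = set(BIOCLIM_VARS) - set(self.names)
            extra = set(self.names) - set(BIOCLIM_VARS)
            raise ValueError(
                "bioclim stack must carry BIO1..BIO19 in order "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )


@dataclass
class PCStack(RasterStack):
    """Principal-component score layers produced by a ClimateTransform.

    ``transform`` is a back-reference to the fitted transform; the mask is
    inherited unchanged from the source stack.
    """

    transform: "object" = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return self.n_layers

    def scores(self) -> np.ndarray:
        """PC scores at valid cells, shape ``(n_valid, k)``."""
        return self.valid_table()


def write_stack(stack: RasterStack, path: str | Path) -> Path:
    """Write a stack as one float32 TIFF per layer plus a grid.json sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, name in enumerate(stack.names):
        tifffile.imwrite(path / f"{name}.tif", stack.data[i].astype(np.float32))
    g = stack.grid
    meta = {
        "layers": list(stack.names),
        "n_rows": g.n_rows,
        "n_cols": g.n_cols,
        "cell_area": g.cell_area,
        "x_origin": g.x_origin,
        "y_origin": g.y_origin,
        "resolution": g.resolution,
        "nodata_fraction": g.nodata_fraction,
        "nodata": "nan",
    }
    (path / "grid.json").write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path: str | Path, kind: type = RasterStack) -> RasterStack:
    """Read a stack written by :func:`write_stack`.

    ``kind`` selects the container class (e.g. :class:`BioclimStack`).
    """
    path = Path(path)
    meta = json.loads((path / "grid.json").read_text())
    grid = GridSpec(
        n_rows=meta["n_rows"],
        n_cols=meta["n_cols"],
        cell_area=meta["cell_area"],
        x_origin=meta["x_origin"],
        y_origin=meta["y_origin"],
        resolution=meta["resolution"],
        nodata_fraction=meta.get("nodata_fraction", 0.0),
    )
    names = tuple(meta["layers"])
    data = np.stack(
        [tifffile.imread(path / f"{n}.tif").astype(float) for n in names]
    )
    mask = np.all(np.isfinite(data), axis=0)
    return kind(names=names, data=data, mask=mask, grid=grid)
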