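"""Lightweight single-band raster containers and ESRI ASCII grid I/O.

A :class:`RasterLayer` is a named 2-D grid of floats with an affine-like
transform and a nodata mask.  The row convention is *south-up*: row 0 is the
southernmost row, so ``values[i, j]`` covers the half-open cell

    x in [x0 + j*dx, x0 + (j+1)*dx),  y in [y0 + i*dy, y0 + (i+1)*dy).

ESRI ASCII grids store rows north-down; the I/O functions flip accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = ["RasterLayer", "RasterStack", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class RasterLayer:
    """One named environmental layer on a regular grid.

    Parameters
    ----------
    name : str
        Layer name (e.g. ``"bio4"`` or ``"env1"``).
    values : ndarray, shape (n_rows, n_cols)
        Cell values; entries under the nodata mask are ignored.
    transform : tuple (x0, y0, dx, dy)
        Lower-left corner of the grid and positive cell sizes.
    nodata_mask : ndarray of bool, same shape
        True where the cell holds no data.
    crs_tag : str
        Free-form tag; ``"planar-km"`` for synthetic grids, ``"EPSG:4326"``
        for geographic ones.
    """

    name: str
    values: np.ndarray
    transform: tuple[float, float, float, float]
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    crs_tag: str = "planar-km"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("values and nodata_mask must share shape")
        x0, y0, dx, dy = self.transform
        if dx <= 0 or dy <= 0:
            raise ValueError("cell sizes must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int((~self.nodata_mask).sum())

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Return (row, col) of the half-open cell containing (x, y)."""
        x0, y0, dx, dy = self.transform
        col = int(np.floor((x - x0) / dx))
        row = int(np.floor((y - y0) / dy))
        nr, nc = self.shape
        if not (0 <= row < nr and 0 <= col < nc):
            raise IndexError(f"point ({x}, {y}) falls outside the grid "
                             f"(row={row}, col={col}, shape={self.shape})")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0, dx, dy = self.transform
        return x0 + (col + 0.5) * dx, y0 + (row + 0.5) * dy

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of x and y cell-center coordinates (broadcastable grids)."""
        x0, y0, dx, dy = self.transform
        nr, nc = self.shape
        xs = x0 + (np.arange(nc) + 0.5) * dx
        ys = y0 + (np.arange(nr) + 0.5) * dy
        return np.meshgrid(xs, ys)

    def values_at(self, points: np.ndarray) -> np.ndarray:
        """Sample layer values at an (n, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty(len(pts))
        for i, (x, y) in enumerate(pts):
            r, c = self.cell_of(x, y)
            out[i] = self.values[r, c]
        return out

    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]

    def copy_with(self, name: str, values: np.ndarray) -> "RasterLayer":
        return RasterLayer(name, values, self.transform,
                           self.nodata_mask.copy(), self.crs_tag)


class RasterStack:
    """An ordered collection of aligned :class:`RasterLayer` objects."""

    def __init__(self, layers: list[RasterLayer]):
        if not layers:
            raise ValueError("empty raster stack")
        names = [l.name for l in layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names: {names}")
        ref = layers[0]
        for l in layers[1:]:
            if l.shape != ref.shape or l.transform != ref.transform \
                    or l.crs_tag != ref.crs_tag:
                raise ValueError(f"layer {l.name!r} is not aligned with "
                                 f"{ref.name!r}")
        self._layers: dict[str, RasterLayer] = {l.name: l for l in layers}

    # -- mapping protocol ---------------------------------------------------
    def __getitem__(self, name: str) -> RasterLayer:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __iter__(self) -> Iterator[RasterLayer]:
        return iter(self._layers.values())

    def __len__(self) -> int:
        return len(self._layers)

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    @property
    def template(self) -> RasterLayer:
        return next(iter(self._layers.values()))

    @property
    def joint_valid_mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        mask = ~self.template.nodata_mask
        for l in self:
            mask &= ~l.nodata_mask
        return mask

    def subset(self, names: list[str]) -> "RasterStack":
        return RasterStack([self._layers[n] for n in names])

    def feature_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, valid_index): X is (n_valid, n_layers) of cell values,
        valid_index the flat indices of jointly valid cells."""
        mask = self.joint_valid_mask
        idx = np.flatnonzero(mask.ravel())
        X = np.column_stack([l.values.ravel()[idx] for l in self])
        return X, idx

    def features_at(self, points: np.ndarray) -> np.ndarray:
        """(n, n_layers) matrix of layer values at (x, y) points."""
        return np.column_stack([l.values_at(points) for l in self])


# -- ESRI ASCII grid I/O ----------------------------------------------------

_NODATA = -9999.0


def write_ascii_grid(layer: RasterLayer, path) -> None:
    """Write a layer as an ESRI ASCII grid (square cells required)."""
    x0, y0, dx, dy = layer.transform
    if not np.isclose(dx, dy):
        raise ValueError("ESRI ASCII grids require square cells")
    nr, nc = layer.shape
    vals = np.where(layer.nodata_mask, _NODATA, layer.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {nc}\nnrows {nr}\n")
        fh.write(f"xllcorner {x0!r}\nyllcorner {y0!r}\n")
        fh.write(f"cellsize {dx!r}\nNODATA_value {_NODATA!r}\n")
        # file rows run north -> south
        np.savetxt(fh, vals[::-1], fmt="%.10g")


def read_ascii_grid(path, name: str | None = None,
                    crs_tag: str = "planar-km") -> RasterLayer:
    """Read an ESRI ASCII grid into a :class:`RasterLayer`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)[::-1]  # back to south-up
    nodata = header.get("nodata_value", _NODATA)
    mask = np.isclose(vals, nodata)
    cs = header["cellsize"]
    transform = (header["xllcorner"], header["yllcorner"], cs, cs)
    import os
    lname = name or os.path.splitext(os.path.basename(str(path)))[0]
    return RasterLayer(lname, np.where(mask, np.nan, vals), transform,
                       mask, crs_tag)
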