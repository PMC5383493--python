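"""Raster grid containers and single-band GeoTIFF round-trip I/O.

All rasters in this package are small north-up grids in a projected
equal-area coordinate system (meters).  ``origin`` is the outer corner of
the top-left cell, so the center of cell ``(row, col)`` sits at::

    x = origin_x + (col + 0.5) * cell_size
    y = origin_y - (row + 0.5) * cell_size

GeoTIFF georeferencing is written as the standard ModelPixelScale /
ModelTiepoint / GDAL_NODATA tags so files interoperate with ordinary GIS
software; reading only supports what writing produces (single band,
square pixels, north-up).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "RasterGrid",
    "CategoricalRaster",
    "LandscapeStack",
    "read_raster",
    "write_raster",
]

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class RasterGrid:
    """A rectangular single-band raster.

    Parameters
    ----------
    values : ndarray, shape (rows, cols)
        Cell values, row 0 northernmost.
    cell_size : float
        Cell edge length in projected meters (30 m in the study design).
    origin : (float, float)
        Projected (x, y) of the outer corner of the top-left cell.
    nodata : float or int, optional
        Sentinel marking missing cells.
    crs_label : str
        Free-text tag for the projection (informational only).
    """

    values: np.ndarray
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float | int | None = None
    crs_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a non-empty 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        finite = np.isfinite(self.values.astype(float))
        if self.nodata is not None:
            finite |= self.values == self.nodata
        if not finite.all():
            raise ValueError("raster contains non-finite values that are not nodata")

    # -- geometry -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells carrying data."""
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        return self.values != self.nodata

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate arrays, each of shape (rows, cols)."""
        rows, cols = self.shape
        x = self.origin[0] + (np.arange(cols) + 0.5) * self.cell_size
        y = self.origin[1] - (np.arange(rows) + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def cell_containing(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing projected points."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((self.origin[1] - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.cell_containing(x, y)
        r, c = self.shape
        return (row >= 0) & (row < r) & (col >= 0) & (col < c)

    def value_at(self, x, y):
        """Cell value at projected point(s); points must be on the map."""
        row, col = self.cell_containing(x, y)
        return self.values[row, col]

    def like(self, values: np.ndarray, nodata=None) -> "RasterGrid":
        """New grid with the same geometry and different values."""
        return RasterGrid(
            values,
            cell_size=self.cell_size,
            origin=self.origin,
            nodata=self.nodata if nodata is None else nodata,
            crs_label=self.crs_label,
        )

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin == other.origin
        )


@dataclass
class CategoricalRaster(RasterGrid):
    """Integer-coded raster with a legend mapping code -> class name."""

    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("categorical raster values must be integers")
        codes = np.unique(self.values[self.valid_mask])
        missing = [int(c) for c in codes if int(c) not in self.legend]
        if missing:
            raise ValueError(f"codes absent from legend: {missing}")

    def like_categorical(self, values, legend=None) -> "CategoricalRaster":
        return CategoricalRaster(
            values,
            cell_size=self.cell_size,
            origin=self.origin,
            nodata=self.nodata,
            crs_label=self.crs_label,
            legend=dict(self.legend if legend is None else legend),
        )


class LandscapeStack:
    """Named set of co-registered rasters over one study area.

    Focal-scale variants of a layer use the suffixes ``_s`` (3x3 window)
    and ``_l`` (27x27 window).
    """

    SCALE_SUFFIXES = ("", "_s", "_l")

    def __init__(self, layers: dict[str, RasterGrid] | None = None):
        self.layers: dict[str, RasterGrid] = {}
        for name, grid in (layers or {}).items():
            self.add(name, grid)

    def add(self, name: str, grid: RasterGrid) -> None:
        if self.layers:
            ref = next(iter(self.layers.values()))
            if not ref.same_geometry(grid):
                raise ValueError(
                    f"layer {name!r} is not co-registered with the stack "
                    f"(shape/origin/cell_size mismatch)"
                )
        self.layers[name] = grid

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def cell_size(self) -> float:
        return next(iter(self.layers.values())).cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    def continuous_names(self) -> list[str]:
        """Layers without a legend (i.e. usable directly as covariates)."""
        return [n for n, g in self.layers.items() if not isinstance(g, CategoricalRaster)]

    def write_dir(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, grid in self.layers.items():
            write_raster(grid, directory / f"{name}.tif")

    @classmethod
    def read_dir(cls, directory) -> "LandscapeStack":
        directory = Path(directory)
        paths = sorted(directory.glob("*.tif"))
        if not paths:
            raise FileNotFoundError(f"no .tif layers under {directory}")
        return cls({p.stem: read_raster(p) for p in paths})


def _legend_path(path) -> Path:
    return Path(str(path) + ".legend.json")


def write_raster(grid: RasterGrid, path) -> None:
    """Write a single-band GeoTIFF (plus a legend sidecar if categorical)."""
    path = Path(path)
    values = grid.values
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (float(grid.cell_size), float(grid.cell_size), 0.0)),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, float(grid.origin[0]), float(grid.origin[1]), 0.0),
        ),
    ]
    if grid.nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, repr(grid.nodata)))
    tifffile.imwrite(
        path,
        values,
        photometric="minisblack",
        description=grid.crs_label,
        extratags=extratags,
    )
    if isinstance(grid, CategoricalRaster):
        _legend_path(path).write_text(
            json.dumps({str(k): v for k, v in grid.legend.items()}, indent=1)
        )


def read_raster(path) -> RasterGrid:
    """Read a GeoTIFF written by :func:`write_raster`.

    Returns a :class:`CategoricalRaster` when a legend sidecar is present.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(f"{path} is multi-band; only single-band rasters are supported")
        values = page.asarray()
        tags = page.tags
        cell_size = 1.0
        origin = (0.0, 0.0)
        nodata = None
        if _TAG_MODEL_PIXEL_SCALE in tags:
            sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
            if abs(sx - sy) > 1e-9:
                raise ValueError(f"{path} has non-square pixels")
            cell_size = float(sx)
        if _TAG_MODEL_TIEPOINT in tags:
            tp = tags[_TAG_MODEL_TIEPOINT].value
            origin = (float(tp[3]), float(tp[4]))
        if _TAG_GDAL_NODATA in tags:
            raw = tags[_TAG_GDAL_NODATA].value.rstrip("\x00")
            nodata = values.dtype.type(float(raw))
            if np.issubdtype(values.dtype, np.integer):
                nodata = int(nodata)
        crs_label = page.description or ""
    legend_file = _legend_path(path)
    if legend_file.exists():
        legend = {int(k): v for k, v in json.loads(legend_file.read_text()).items()}
        return CategoricalRaster(
            values, cell_size=cell_size, origin=origin, nodata=nodata,
            crs_label=crs_label, legend=legend,
        )
    return RasterGrid(values, cell_size=cell_size, origin=origin, nodata=nodata,
                      crs_label=crs_label)
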