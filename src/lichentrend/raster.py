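"""Gridded data types and GeoTIFF input/output.

All rasters are row-major with a top-left origin: row 0 is the northernmost
row and row indices increase southward, matching the usual GeoTIFF layout.
Every analysis raster must live in a projected coordinate system with metre
units; geographic (longitude/latitude) grids are rejected because kernel and
zonal arithmetic assume uniform cell area.

GeoTIFFs are written through :mod:`tifffile` with the standard georeferencing
tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA) plus a JSON payload in the
ImageDescription tag carrying the CRS identifier, band labels and year.
"""

from __future__ import annotations

import json

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .errors import AlignmentError, ConfigurationError

NODATA_DEFAULT = -9999.0

#: semantic band labels a reflectance stack must provide
REQUIRED_BANDS = ("green", "nir", "swir1")

_GEOGRAPHIC_CRS_IDS = {"EPSG:4326", "WGS84", "CRS84", "EPSG:4269"}

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113


def _check_projected(crs_id: str) -> None:
    cid = crs_id.strip().upper()
    if cid in _GEOGRAPHIC_CRS_IDS or cid.startswith("GEOG"):
        raise ConfigurationError(
            f"geographic CRS {crs_id!r} rejected: rasters must use a projected, "
            "metre-unit coordinate system"
        )


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up raster grid in a projected CRS.

    ``origin_x``/``origin_y`` are the projected coordinates of the *outer*
    top-left corner of cell (0, 0); cells are square with side ``cell_size``
    metres.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float
    origin_y: float
    crs_id: str

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        _check_projected(self.crs_id)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def aligned(self, other: "GridSpec") -> bool:
        return self == other

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Projected (x, y) coordinates of every cell center, each (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(y[:, None], self.shape).copy()

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each projected point (may be out of bounds)."""
        col = np.floor((np.asarray(x, dtype=float) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y, dtype=float)) / self.cell_size).astype(int)
        return row, col

    def contains_index(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


def require_aligned(a: GridSpec, b: GridSpec, what: str = "rasters") -> None:
    if not a.aligned(b):
        raise AlignmentError(f"{what} are not on the same grid: {a} vs {b}")


@dataclass
class ScalarRaster:
    """A single-band real-valued raster with a validity mask."""

    grid: GridSpec
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.grid.shape or self.valid.shape != self.grid.shape:
            raise ValueError("values/valid shape must match grid")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("values must be finite wherever valid")


@dataclass
class LichenMask:
    """Boolean lichen-tundra mask co-registered with the reflectance stack."""

    grid: GridSpec
    is_lichen: np.ndarray

    def __post_init__(self) -> None:
        self.is_lichen = np.asarray(self.is_lichen, dtype=bool)
        if self.is_lichen.shape != self.grid.shape:
            raise ValueError("mask shape must match grid")


@dataclass
class ReflectanceStack:
    """Annual multiband surface reflectance: values[(year, band, row, col)].

    ``valid`` is per (year, row, col): a nodata observation in any band marks
    the cell invalid for that whole year.
    """

    grid: GridSpec
    years: np.ndarray
    bands: tuple[str, ...]
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not np.all(np.diff(self.years) > 0):
            raise ValueError("years must be strictly increasing")
        for b in REQUIRED_BANDS:
            if b not in self.bands:
                raise ConfigurationError(f"stack is missing required band label {b!r}")
        ny, nb = len(self.years), len(self.bands)
        if self.values.shape != (ny, nb, *self.grid.shape):
            raise ValueError("values shape must be (years, bands, rows, cols)")
        if self.valid.shape != (ny, *self.grid.shape):
            raise ValueError("valid shape must be (years, rows, cols)")
        v = self.values[:, :, :, :][np.broadcast_to(self.valid[:, None], self.values.shape)]
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite wherever valid")

    def band(self, label: str, year_index: int) -> np.ndarray:
        return self.values[year_index, self.bands.index(label)]

    def year_index(self, year: int) -> int:
        idx = np.nonzero(self.years == year)[0]
        if idx.size == 0:
            raise KeyError(f"year {year} not in stack")
        return int(idx[0])


# ---------------------------------------------------------------------------
# GeoTIFF read/write
# ---------------------------------------------------------------------------

def _geo_extratags(grid: GridSpec, nodata: float, meta: dict) -> list:
    # GTModelTypeGeoKey = 1 (projected CRS)
    geokeys = (1, 1, 0, 1, 1024, 0, 1, 1)
    return [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", 8, geokeys),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(nodata))),
    ]


def _write_geotiff(path, data: np.ndarray, grid: GridSpec, nodata: float, meta: dict) -> None:
    desc = dict(meta)
    desc["crs_id"] = grid.crs_id
    try:
        tifffile.imwrite(
            str(path),
            np.ascontiguousarray(data),
            photometric="minisblack",
            description=json.dumps(desc, sort_keys=True),
            extratags=_geo_extratags(grid, nodata, meta),
        )
    except OSError as exc:  # unwritable path
        raise OSError(f"cannot write raster to {path}: {exc}") from exc


def _read_geotiff(path) -> tuple[np.ndarray, GridSpec, float, dict]:
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        data = tf.asarray()
        tags = page.tags
        try:
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value
            tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        except KeyError as exc:
            raise ConfigurationError(f"{path}: missing georeferencing tags") from exc
        nodata = NODATA_DEFAULT
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        meta: dict = {}
        if 270 in tags:
            try:
                meta = json.loads(tags[270].value)
            except (TypeError, ValueError):
                meta = {}
    if data.ndim == 2:
        n_rows, n_cols = data.shape
    else:
        n_rows, n_cols = data.shape[-2:]
    if abs(scale[0] - scale[1]) > 1e-9:
        raise ConfigurationError(f"{path}: non-square cells unsupported")
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=float(scale[0]),
        origin_x=float(tiepoint[3]),
        origin_y=float(tiepoint[4]),
        crs_id=str(meta.get("crs_id", "UNKNOWN-PROJECTED")),
    )
    return np.asarray(data), grid, nodata, meta


def write_raster(r: ScalarRaster, path, nodata: float = NODATA_DEFAULT, meta: dict | None = None) -> None:
    """Write a ScalarRaster as a single-band float64 GeoTIFF.

    Invalid cells are written as ``nodata``; finite values round-trip
    bit-exactly through :func:`read_raster`.
    """
    data = np.where(r.valid, r.values, nodata).astype(np.float64)
    m = {"kind": "scalar"}
    if meta:
        m.update(meta)
    _write_geotiff(path, data, r.grid, nodata, m)


def read_raster(path) -> ScalarRaster:
    data, grid, nodata, _ = _read_geotiff(path)
    if data.ndim != 2:
        raise ConfigurationError(f"{path}: expected single-band raster")
    data = data.astype(np.float64)
    valid = np.isfinite(data) & (data != nodata)
    values = np.where(valid, data, 0.0)
    return ScalarRaster(grid=grid, values=values, valid=valid)


def write_mask(mask: LichenMask, path) -> None:
    _write_geotiff(path, mask.is_lichen.astype(np.uint8), mask.grid, 255, {"kind": "mask"})


def read_mask(path) -> LichenMask:
    data, grid, _, _ = _read_geotiff(path)
    return LichenMask(grid=grid, is_lichen=data.astype(bool))


def write_reflectance_year(
    stack: ReflectanceStack, year: int, path, nodata: float = NODATA_DEFAULT
) -> None:
    """Write one year of a stack as a multi-band GeoTIFF with labelled bands."""
    yi = stack.year_index(year)
    data = stack.values[yi].astype(np.float64).copy()
    data[:, ~stack.valid[yi]] = nodata
    meta = {"kind": "reflectance", "year": int(year), "band_labels": list(stack.bands)}
    _write_geotiff(path, data, stack.grid, nodata, meta)


_YEAR_RE = re.compile(r"(19|20)\d{2}")


def _year_from(path, meta: dict) -> int:
    if "year" in meta:
        return int(meta["year"])
    m = _YEAR_RE.search(Path(path).stem)
    if m is None:
        raise ConfigurationError(
            f"{path}: year not present in metadata and not parseable from file name"
        )
    return int(m.group(0))


def read_stack(paths: Sequence, band_map: Mapping[str, int]) -> ReflectanceStack:
    """Read yearly multiband GeoTIFFs into a ReflectanceStack.

    ``band_map`` maps the semantic labels green/nir/swir1 to 0-based band
    indices within each file. Years come from file metadata or, failing that,
    a 4-digit year in the file name. All files must share one grid; a nodata
    value in any mapped band marks the cell invalid for that year.
    """
    for b in REQUIRED_BANDS:
        if b not in band_map:
            raise ConfigurationError(f"band_map is missing required label {b!r}")
    if not paths:
        raise ConfigurationError("read_stack needs at least one file")

    entries = []
    ref_grid: GridSpec | None = None
    for p in paths:
        data, grid, nodata, meta = _read_geotiff(p)
        if data.ndim == 2:
            data = data[None]
        if ref_grid is None:
            ref_grid = grid
        elif not grid.aligned(ref_grid):
            raise AlignmentError(f"{p}: grid does not match first file's grid")
        year = _year_from(p, meta)
        entries.append((year, data.astype(np.float64), nodata))
    entries.sort(key=lambda e: e[0])
    years = [e[0] for e in entries]
    if len(set(years)) != len(years):
        raise ConfigurationError(f"duplicate years in input files: {years}")

    bands = tuple(REQUIRED_BANDS)
    n_rows, n_cols = ref_grid.shape
    values = np.zeros((len(years), len(bands), n_rows, n_cols))
    valid = np.ones((len(years), n_rows, n_cols), dtype=bool)
    for yi, (_, data, nodata) in enumerate(entries):
        for bi, label in enumerate(bands):
            src = band_map[label]
            if src >= data.shape[0]:
                raise ConfigurationError(
                    f"band_map index {src} for {label!r} out of range ({data.shape[0]} bands)"
                )
            layer = data[src]
            bad = ~np.isfinite(layer) | (layer == nodata)
            valid[yi] &= ~bad
            values[yi, bi] = np.where(bad, 0.0, layer)
    return ReflectanceStack(
        grid=ref_grid, years=np.array(years), bands=bands, values=values, valid=valid
    )


def resample_mask_nearest(coarse: LichenMask, target: GridSpec) -> LichenMask:
    """Nearest-neighbour mask resampling by fine-cell-center lookup.

    Each target cell takes the value of the coarse cell containing its
    center, which is well defined for non-integer nesting factors (e.g. a
    250 m product onto a 30 m grid). Raises AlignmentError if any target
    center falls outside the coarse extent or the CRSs differ.
    """
    if coarse.grid.crs_id != target.crs_id:
        raise AlignmentError("mask and target grids are in different CRSs")
    x, y = target.cell_centers()
    row, col = coarse.grid.index_of(x, y)
    inside = coarse.grid.contains_index(row, col)
    if not inside.all():
        raise AlignmentError("target grid does not nest inside the coarse mask extent")
    return LichenMask(grid=target, is_lichen=coarse.is_lichen[row, col])
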