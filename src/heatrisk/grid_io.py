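"""Raster containers and I/O for the heat-health-risk pipeline.

Every layer in the pipeline is a single-band, north-up raster held in a
:class:`Grid`: a value matrix, a nodata mask, a cell size in metres and the
projected coordinate of the upper-left corner.  Cell (0, 0) is the NW corner
and the centre of cell (i, j) sits at ``origin + ((j + 0.5), -(i + 0.5)) *
cell_size``.

Two on-disk formats are supported: single-band float32 GeoTIFF (georeference
carried in the ModelPixelScale / ModelTiepoint tags, nodata in the GDAL_NODATA
tag) and the ESRI ASCII grid text format.  No reprojection is performed: all
inputs to one analysis must declare the same ``crs_tag`` and the pipeline
fails otherwise.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile

__all__ = [
    "Grid",
    "IndicatorSpec",
    "IndicatorStack",
    "CANONICAL_INDICATORS",
    "RasterIOError",
    "AlignmentError",
    "read_raster",
    "write_raster",
    "align_stack",
    "clip_to_boundary",
    "rasterize_admin_table",
    "read_admin_table",
]

#: Sentinel written to nodata cells on disk.  Pipeline values live in
#: [0.01, 1.01] (normalised) or modest physical ranges, far from this value.
NODATA = -9999.0

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113
_TAG_GEO_ASCII = 34737


class RasterIOError(RuntimeError):
    """Raised when a raster file cannot be read or written."""


class AlignmentError(ValueError):
    """Raised when two rasters do not share grid geometry or CRS."""


@dataclass
class Grid:
    """A single-band, north-up raster.

    Parameters
    ----------
    values
        2-D float array, row-major, row 0 is the northernmost row.
    nodata_mask
        Boolean array of the same shape; ``True`` marks missing cells.
        Masked cells are excluded from every statistic.
    cell_size
        Cell edge length in projection units (metres), default 1000 (1 km).
    origin
        ``(x, y)`` of the upper-left *corner* in projection units.
    crs_tag
        Opaque coordinate-system identifier; layers entering one analysis
        must agree on it.
    """

    values: np.ndarray
    nodata_mask: np.ndarray | None = None
    cell_size: float = 1000.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError(
                f"mask shape {self.nodata_mask.shape} != values shape {self.values.shape}"
            )
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(left, bottom, right, top) in projection units."""
        nrows, ncols = self.shape
        left, top = self.origin
        return (left, top - nrows * self.cell_size, left + ncols * self.cell_size, top)

    def aligned_with(self, other: "Grid", *, check_crs: bool = True) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) < 1e-6
            and abs(self.origin[0] - other.origin[0]) < 1e-6 * self.cell_size
            and abs(self.origin[1] - other.origin[1]) < 1e-6 * self.cell_size
            and (not check_crs or self.crs_tag == other.crs_tag)
        )

    def require_aligned(self, other: "Grid", what: str = "grid") -> None:
        if not self.aligned_with(other):
            raise AlignmentError(
                f"{what} is not aligned: shape/cell_size/origin/crs differ "
                f"({self.shape}@{self.origin} vs {other.shape}@{other.origin})"
            )

    # -- data access ------------------------------------------------------
    def unmasked_values(self) -> np.ndarray:
        """Valid cell values as a flat array."""
        return self.values[~self.nodata_mask]

    def copy(self) -> "Grid":
        return replace(self, values=self.values.copy(), nodata_mask=self.nodata_mask.copy())

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Grid":
        """New grid sharing this geometry with different values/mask."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            nodata_mask=self.nodata_mask.copy() if mask is None else np.asarray(mask, bool),
        )


@dataclass(frozen=True)
class IndicatorSpec:
    """Metadata for one assessment indicator.

    ``direction`` encodes whether larger raw values raise risk (``positive``)
    or protect against it (``negative``); it selects the normalisation
    formula, so weights can stay non-negative.
    """

    name: str
    category: str  # hazard | social_vulnerability | exposure
    direction: str  # positive | negative
    units: str = ""

    def __post_init__(self) -> None:
        if self.category not in ("hazard", "social_vulnerability", "exposure"):
            raise ValueError(f"unknown category {self.category!r}")
        if self.direction not in ("positive", "negative"):
            raise ValueError(f"unknown direction {self.direction!r}")


#: The 13-indicator heat-health-risk system: nighttime land-surface
#: temperature as the hazard, seven social-vulnerability indicators and five
#: exposure indicators, each with its risk direction.
CANONICAL_INDICATORS: tuple[IndicatorSpec, ...] = (
    IndicatorSpec("lst", "hazard", "positive", "degC"),
    IndicatorSpec("gdp", "social_vulnerability", "negative", "yuan"),
    IndicatorSpec("disposable_income", "social_vulnerability", "negative", "yuan"),
    IndicatorSpec("physicians", "social_vulnerability", "negative", "persons"),
    IndicatorSpec("hospital_beds", "social_vulnerability", "negative", "beds"),
    IndicatorSpec("older_adults", "social_vulnerability", "positive", "%"),
    IndicatorSpec("female", "social_vulnerability", "positive", "%"),
    IndicatorSpec("unemployment", "social_vulnerability", "positive", "%"),
    IndicatorSpec("ndvi", "exposure", "negative", ""),
    IndicatorSpec("population_density", "exposure", "positive", "persons/km2"),
    IndicatorSpec("water_resources", "exposure", "negative", "m3"),
    IndicatorSpec("agricultural_practitioners", "exposure", "positive", "%"),
    IndicatorSpec("construction_practitioners", "exposure", "positive", "%"),
)


@dataclass
class IndicatorStack:
    """Named, aligned indicator grids for one year."""

    specs: list[IndicatorSpec]
    grids: list[Grid]
    year: int = 0

    def __post_init__(self) -> None:
        if len(self.specs) != len(self.grids):
            raise ValueError("one grid per spec required")
        if self.grids:
            ref = self.grids[0]
            for spec, g in zip(self.specs, self.grids):
                if not g.aligned_with(ref):
                    raise AlignmentError(f"indicator {spec.name!r} is not aligned with the stack")

    def __len__(self) -> int:
        return len(self.specs)

    def __getitem__(self, name: str) -> Grid:
        for spec, g in zip(self.specs, self.grids):
            if spec.name == name:
                return g
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def union_mask(self) -> np.ndarray:
        """Cells missing in *any* layer; the index is undefined there."""
        mask = np.zeros(self.grids[0].shape, dtype=bool)
        for g in self.grids:
            mask |= g.nodata_mask
        return mask

    def select(self, category: str) -> "IndicatorStack":
        pairs = [(s, g) for s, g in zip(self.specs, self.grids) if s.category == category]
        if not pairs:
            raise KeyError(f"no indicators in category {category!r}")
        return IndicatorStack([p[0] for p in pairs], [p[1] for p in pairs], self.year)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _detect_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        return "geotiff"
    if ext in (".asc", ".txt", ".grd"):
        return "ascii_grid"
    # fall back to magic bytes
    try:
        with open(path, "rb") as fh:
            head = fh.read(4)
    except OSError as exc:
        raise RasterIOError(f"cannot open raster {path!r}: {exc}") from exc
    if head[:2] in (b"II", b"MM"):
        return "geotiff"
    return "ascii_grid"


def read_raster(path: str, format: str = "auto") -> Grid:
    """Read a single-band raster into a :class:`Grid`.

    Cells equal to the file's declared nodata value are masked.  Raises
    :class:`RasterIOError` naming the file if it cannot be parsed or lacks
    georeference information.
    """
    if not os.path.exists(path):
        raise RasterIOError(f"raster file does not exist: {path!r}")
    fmt = _detect_format(path) if format == "auto" else format
    if fmt == "geotiff":
        return _read_geotiff(path)
    if fmt == "ascii_grid":
        return _read_ascii_grid(path)
    raise RasterIOError(f"unknown raster format {format!r} for {path!r}")


def write_raster(grid: Grid, path: str, format: str = "auto") -> None:
    """Write a :class:`Grid` to disk (float32 GeoTIFF or ESRI ASCII grid)."""
    fmt = _detect_format_for_write(path) if format == "auto" else format
    try:
        if fmt == "geotiff":
            _write_geotiff(grid, path)
        elif fmt == "ascii_grid":
            _write_ascii_grid(grid, path)
        else:
            raise RasterIOError(f"unknown raster format {format!r} for {path!r}")
    except OSError as exc:
        raise RasterIOError(f"cannot write raster {path!r}: {exc}") from exc


def _detect_format_for_write(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    return "ascii_grid" if ext in (".asc", ".txt", ".grd") else "geotiff"


def _write_geotiff(grid: Grid, path: str) -> None:
    data = np.where(grid.nodata_mask, NODATA, grid.values).astype(np.float32)
    cs = float(grid.cell_size)
    ox, oy = grid.origin
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ox, oy, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(NODATA)),
        (_TAG_GEO_ASCII, "s", 0, grid.crs_tag or "unspecified"),
    ]
    tifffile.imwrite(path, data, photometric="minisblack", extratags=extratags)


def _read_geotiff(path: str) -> Grid:
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = page.asarray()
            tags = page.tags
            scale = tags.valueof(_TAG_PIXEL_SCALE)
            tiepoint = tags.valueof(_TAG_TIEPOINT)
            nod = tags.valueof(_TAG_GDAL_NODATA)
            crs = tags.valueof(_TAG_GEO_ASCII)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise RasterIOError(f"cannot parse GeoTIFF {path!r}: {exc}") from exc
    if data.ndim == 3:
        if data.shape[2] != 1 and data.shape[0] != 1:
            raise RasterIOError(f"{path!r} is not single-band")
        data = np.squeeze(data)
    if scale is None or tiepoint is None:
        raise RasterIOError(f"GeoTIFF {path!r} has no georeference (pixel scale / tiepoint)")
    cs = float(scale[0])
    origin = (float(tiepoint[3]), float(tiepoint[4]))
    nodata = float(nod) if nod is not None else NODATA
    values = np.asarray(data, dtype=float)
    mask = np.isclose(values, nodata) | ~np.isfinite(values)
    crs_tag = str(crs).rstrip("\x00|") if crs is not None else ""
    if crs_tag == "unspecified":
        crs_tag = ""
    return Grid(values, mask, cell_size=cs, origin=origin, crs_tag=crs_tag)


def _write_ascii_grid(grid: Grid, path: str) -> None:
    nrows, ncols = grid.shape
    left, bottom, _, _ = grid.bounds
    data = np.where(grid.nodata_mask, NODATA, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {left!r}\n")
        fh.write(f"yllcorner {bottom!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {NODATA!r}\n")
        for row in data:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_ascii_grid(path: str) -> Grid:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    header_keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    try:
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0].lower() in header_keys and len(parts) == 2:
                    header[parts[0].lower()] = float(parts[1])
                else:
                    rows.append([float(v) for v in parts])
    except (OSError, ValueError) as exc:
        raise RasterIOError(f"cannot parse ASCII grid {path!r}: {exc}") from exc
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise RasterIOError(f"ASCII grid {path!r} is missing header field {key!r}")
    values = np.array(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise RasterIOError(
            f"ASCII grid {path!r}: data shape {values.shape} does not match header"
        )
    nodata = header.get("nodata_value", NODATA)
    cs = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + values.shape[0] * cs)
    mask = np.isclose(values, nodata)
    return Grid(values, mask, cell_size=cs, origin=origin, crs_tag="")


# ---------------------------------------------------------------------------
# alignment / clipping / rasterisation
# ---------------------------------------------------------------------------

def _resample_nearest(grid: Grid, origin: tuple[float, float], shape: tuple[int, int],
                      cell_size: float) -> Grid:
    """Nearest-neighbour resample onto the given target geometry."""
    nrows, ncols = shape
    left, top = origin
    # centres of the output cells
    cx = left + (np.arange(ncols) + 0.5) * cell_size
    cy = top - (np.arange(nrows) + 0.5) * cell_size
    gx, gy = grid.origin
    col = np.floor((cx - gx) / grid.cell_size).astype(int)
    row = np.floor((gy - cy) / grid.cell_size).astype(int)
    col = np.clip(col, 0, grid.shape[1] - 1)
    row = np.clip(row, 0, grid.shape[0] - 1)
    values = grid.values[np.ix_(row, col)]
    mask = grid.nodata_mask[np.ix_(row, col)]
    return Grid(values, mask, cell_size=cell_size, origin=origin, crs_tag=grid.crs_tag)


def align_stack(grids: Sequence[Grid], specs: Sequence[IndicatorSpec],
                target_cell_size: float = 1000.0, year: int = 0) -> IndicatorStack:
    """Co-register layers onto the intersection extent at ``target_cell_size``.

    Resampling is nearest-neighbour (no new values are invented) and every
    layer keeps its own nodata mask; the undefined region of the composite
    index is the union of the masks.  Fails if the layers do not spatially
    overlap or disagree on ``crs_tag``.
    """
    if len(grids) != len(specs):
        raise ValueError("one spec per grid required")
    if not grids:
        raise ValueError("empty grid list")
    if target_cell_size <= 0:
        raise ValueError("target_cell_size must be positive")
    crs_tags = {g.crs_tag for g in grids}
    if len(crs_tags) > 1:
        raise AlignmentError(f"layers declare different CRS tags: {sorted(crs_tags)}")

    lefts, bottoms, rights, tops = zip(*(g.bounds for g in grids))
    left, bottom = max(lefts), max(bottoms)
    right, top = min(rights), min(tops)
    if right - left < target_cell_size or top - bottom < target_cell_size:
        raise AlignmentError("input rasters have empty (or sub-cell) spatial intersection")
    ncols = int(np.floor((right - left) / target_cell_size + 1e-9))
    nrows = int(np.floor((top - bottom) / target_cell_size + 1e-9))
    origin = (left, top)
    out = [_resample_nearest(g, origin, (nrows, ncols), target_cell_size) for g in grids]
    return IndicatorStack(list(specs), out, year)


def clip_to_boundary(grid: Grid, boundary: Grid) -> Grid:
    """Mask cells outside the study boundary (boundary cells != 0 are inside)."""
    grid.require_aligned(boundary, "boundary")
    inside = (boundary.values != 0) & ~boundary.nodata_mask
    return grid.with_values(grid.values, grid.nodata_mask | ~inside)


def read_admin_table(path: str) -> dict[int, float]:
    """Read a ``unit_id,value`` CSV into a mapping."""
    table: dict[int, float] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "unit_id" not in reader.fieldnames:
            raise RasterIOError(f"admin table {path!r} must have header 'unit_id,value'")
        for rec in reader:
            table[int(rec["unit_id"])] = float(rec["value"])
    return table


def rasterize_admin_table(table: Mapping[int, float] | Iterable[tuple[int, float]],
                          zones: Grid, template: Grid | None = None) -> Grid:
    """Spread admin-unit statistics uniformly over their zone rasters.

    Each cell takes the tabular value of its zone id; id 0 means "outside any
    unit" and is masked.  A zone id present in the raster but absent from the
    table is an error (silently zero-filling a yearbook variable would bias
    the index).
    """
    if not isinstance(table, Mapping):
        table = dict(table)
    if template is not None:
        zones.require_aligned(template, "zones/template")
    ids = zones.values.astype(int)
    present = np.unique(ids[~zones.nodata_mask])
    missing = [int(z) for z in present if z != 0 and int(z) not in table]
    if missing:
        raise ValueError(f"zone ids missing from admin table: {missing}")
    values = np.zeros(zones.shape, dtype=float)
    for zid in present:
        if zid == 0:
            continue
        values[ids == zid] = table[int(zid)]
    mask = zones.nodata_mask | (ids == 0)
    return Grid(values, mask, cell_size=zones.cell_size, origin=zones.origin,
                crs_tag=zones.crs_tag)
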