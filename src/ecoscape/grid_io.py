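"""Raster and lookup-table data model.

Every analysis module consumes only the types defined here: a :class:`Grid`
(continuous raster), a :class:`LandUseGrid` (categorical raster with a
legend), and a :class:`LookupTable` (per-class parameter table).

Conventions
-----------
* Row 0 is the top (north) row of ``values``; the stored ``origin`` is the
  lower-left corner, matching the ESRI ASCII header. Conversion between the
  two happens only at the I/O boundary.
* All analysis runs at one fixed resolution (default 500 m). Misaligned
  inputs raise :class:`AlignmentError`; there is no implicit resampling.
* nodata defaults to -9999.0 for continuous grids and 0 for categorical
  grids (0 is reserved and never a class code).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LAND_USE_CLASSES",
    "CLASS_ORDER",
    "CLASS_LETTERS",
    "Grid",
    "LandUseGrid",
    "LookupTable",
    "GridParseError",
    "AlignmentError",
    "read_raster",
    "write_raster",
    "assert_aligned",
]

#: Default six-class legend: code -> name.
LAND_USE_CLASSES: dict[int, str] = {
    1: "cropland",
    2: "forest",
    3: "grassland",
    4: "water",
    5: "construction",
    6: "unutilized",
}

#: Class codes in canonical (reporting) order.
CLASS_ORDER: tuple[int, ...] = (1, 2, 3, 4, 5, 6)

#: One-letter aliases used in the conversion-cost tables.
CLASS_LETTERS: dict[str, int] = {"A": 1, "F": 2, "G": 3, "W": 4, "C": 5, "U": 6}

DEFAULT_NODATA = -9999.0


class GridParseError(ValueError):
    """Malformed raster file (bad header, wrong value count, unknown tag)."""


class AlignmentError(ValueError):
    """Two grids disagree on shape, cell size or origin."""


@dataclasses.dataclass
class Grid:
    """A single-band georeferenced raster.

    Parameters
    ----------
    values
        2-D array; row 0 is the northernmost row.
    cell_size
        Cell edge length in metres (> 0).
    origin
        (x, y) of the lower-left corner in projected metres.
    nodata
        Sentinel marking invalid cells.
    """

    values: np.ndarray
    cell_size: float = 500.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("grid values must be a non-empty 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True on valid (non-nodata) cells."""
        return self.values != self.nodata

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "Grid":
        """A new grid sharing this grid's geometry."""
        return Grid(
            np.asarray(values),
            cell_size=self.cell_size,
            origin=self.origin,
            nodata=self.nodata if nodata is None else nodata,
        )


@dataclasses.dataclass
class LandUseGrid(Grid):
    """Categorical raster whose integer codes are described by ``legend``."""

    nodata: float = 0
    legend: Mapping[int, str] = dataclasses.field(
        default_factory=lambda: dict(LAND_USE_CLASSES)
    )

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(np.int32, copy=False)
        self.nodata = int(self.nodata)
        codes = np.unique(self.values[self.mask])
        unknown = [int(c) for c in codes if int(c) not in self.legend]
        if unknown:
            raise ValueError(f"codes {unknown} not in legend {sorted(self.legend)}")

    def class_counts(self) -> dict[int, int]:
        """Cell count per legend code (zero for absent classes)."""
        vals = self.values[self.mask]
        return {c: int(np.count_nonzero(vals == c)) for c in sorted(self.legend)}

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "LandUseGrid":
        return LandUseGrid(
            np.asarray(values),
            cell_size=self.cell_size,
            origin=self.origin,
            nodata=self.nodata if nodata is None else nodata,
            legend=dict(self.legend),
        )


class LookupTable:
    """Per-class numeric parameters, one row per land-use code.

    Thin wrapper over a :class:`pandas.DataFrame` indexed by ``code``,
    validated against a legend so missing classes fail early.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.name != "code":
            if "code" in frame.columns:
                frame = frame.set_index("code")
            else:
                raise ValueError("lookup table needs a 'code' column or index")
        if frame.index.duplicated().any():
            raise ValueError("duplicate codes in lookup table")
        if frame.isna().any().any():
            raise ValueError("lookup table has missing cells")
        self.frame = frame.sort_index()

    @property
    def codes(self) -> list[int]:
        return [int(c) for c in self.frame.index]

    def column(self, name: str) -> dict[int, float]:
        return {int(c): float(v) for c, v in self.frame[name].items()}

    def require(self, codes: Iterable[int], columns: Sequence[str]) -> None:
        missing_codes = sorted(set(int(c) for c in codes) - set(self.codes))
        if missing_codes:
            raise KeyError(f"lookup table missing rows for codes {missing_codes}")
        missing_cols = [c for c in columns if c not in self.frame.columns]
        if missing_cols:
            raise KeyError(f"lookup table missing columns {missing_cols}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LookupTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path)

    def __repr__(self) -> str:  # pragma: no cover
        return f"LookupTable({list(self.frame.columns)}, codes={self.codes})"


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _read_ascii(path: Path) -> tuple[np.ndarray, float, tuple[float, float], float]:
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ASCII_HEADER_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise GridParseError(f"{path}: bad header line {i + 1}: {line!r}") from exc
            body_start = i + 1
        else:
            break
    for key in _ASCII_HEADER_KEYS:
        if key not in header:
            raise GridParseError(f"{path}: missing header field '{key}'")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    flat: list[float] = []
    for i, line in enumerate(lines[body_start:], start=body_start + 1):
        for tok in line.split():
            try:
                flat.append(float(tok))
            except ValueError as exc:
                raise GridParseError(f"{path}: non-numeric value {tok!r} on line {i}") from exc
    if len(flat) != nrows * ncols:
        raise GridParseError(
            f"{path}: body has {len(flat)} values, expected {nrows}x{ncols}={nrows * ncols}"
        )
    values = np.array(flat).reshape(nrows, ncols)
    if np.all(values == np.floor(values)):
        as_int = values.astype(np.int64)
        if np.array_equal(as_int, values):
            values = as_int
    return values, header["cellsize"], (header["xllcorner"], header["yllcorner"]), nodata


def _write_ascii(grid: Grid, path: Path) -> None:
    is_int = np.issubdtype(grid.values.dtype, np.integer)
    nodata = int(grid.nodata) if is_int else grid.nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.6f}\n")
        fh.write(f"yllcorner {grid.origin[1]:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        fmt = "%d" if is_int else "%.17g"
        np.savetxt(fh, grid.values, fmt=fmt)


# ---------------------------------------------------------------------------
# GeoTIFF (single band, via tifffile + standard GeoTIFF tags)
# ---------------------------------------------------------------------------

_TAG_PIXEL_SCALE = 33550  # ModelPixelScaleTag
_TAG_TIEPOINT = 33922  # ModelTiepointTag
_TAG_GDAL_NODATA = 42113


def _read_geotiff(path: Path) -> tuple[np.ndarray, float, tuple[float, float], float]:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        if values.ndim != 2:
            raise GridParseError(f"{path}: expected a single-band raster, got shape {values.shape}")
        tags = page.tags
        scale = tags[_TAG_PIXEL_SCALE].value if _TAG_PIXEL_SCALE in tags else (1.0, 1.0, 0.0)
        tie = tags[_TAG_TIEPOINT].value if _TAG_TIEPOINT in tags else (0, 0, 0, 0, 0, 0)
        cell_size = float(scale[0])
        # tiepoint maps raster (0,0) [upper-left corner] to model (x, y)
        x_ul, y_ul = float(tie[3]), float(tie[4])
        origin = (x_ul, y_ul - values.shape[0] * cell_size)
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            try:
                nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
            except ValueError as exc:
                raise GridParseError(f"{path}: unparseable GDAL nodata tag") from exc
    return values, cell_size, origin, nodata


def _write_geotiff(grid: Grid, path: Path) -> None:
    import tifffile

    values = grid.values
    if np.issubdtype(values.dtype, np.integer):
        values = values.astype(np.int32)
        nodata_str = str(int(grid.nodata))
    else:
        values = values.astype(np.float64)
        nodata_str = repr(float(grid.nodata))
    x_ul = grid.origin[0]
    y_ul = grid.origin[1] + grid.nrows * grid.cell_size
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x_ul, y_ul, 0.0)),
        (_TAG_GDAL_NODATA, "s", None, nodata_str),
    ]
    tifffile.imwrite(path, values, extratags=extratags)


# ---------------------------------------------------------------------------
# Public I/O
# ---------------------------------------------------------------------------

_FORMATS = {"ascii", "geotiff"}
_EXT_FORMAT = {".asc": "ascii", ".txt": "ascii", ".tif": "geotiff", ".tiff": "geotiff"}


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
        if fmt not in _FORMATS:
            raise ValueError(f"unknown raster format {format!r}; use 'ascii' or 'geotiff'")
        return fmt
    fmt = _EXT_FORMAT.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(f"cannot infer format from extension of {path}; pass format=")
    return fmt


def read_raster(
    path: str | Path,
    format: str | None = None,
    legend: Mapping[int, str] | None = None,
) -> Grid:
    """Read a single-band raster.

    When ``legend`` is given and the band is integer-typed, a
    :class:`LandUseGrid` is returned; otherwise a plain :class:`Grid`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    reader = _read_ascii if fmt == "ascii" else _read_geotiff
    values, cell_size, origin, nodata = reader(path)
    if legend is not None and np.issubdtype(values.dtype, np.integer):
        return LandUseGrid(values, cell_size=cell_size, origin=origin,
                           nodata=int(nodata), legend=dict(legend))
    return Grid(values, cell_size=cell_size, origin=origin, nodata=nodata)


def write_raster(grid: Grid, path: str | Path, format: str | None = None) -> None:
    """Write ``grid`` so that :func:`read_raster` recovers it exactly."""
    path = Path(path)
    fmt = _infer_format(path, format)
    try:
        if fmt == "ascii":
            _write_ascii(grid, path)
        else:
            _write_geotiff(grid, path)
    except OSError as exc:
        raise OSError(f"failed writing raster to {path}: {exc}") from exc


def assert_aligned(*grids: Grid, tol: float = 1e-6) -> None:
    """Verify that all grids share shape, cell size and origin.

    Raises :class:`AlignmentError` naming the first differing field.
    """
    flat: list[Grid] = []
    for g in grids:
        flat.extend(g) if isinstance(g, (list, tuple)) else flat.append(g)
    if len(flat) < 2:
        raise ValueError("assert_aligned needs at least two grids")
    ref = flat[0]
    for i, g in enumerate(flat[1:], start=1):
        if g.shape != ref.shape:
            raise AlignmentError(f"grid {i}: shape {g.shape} != {ref.shape}")
        if abs(g.cell_size - ref.cell_size) > tol:
            raise AlignmentError(f"grid {i}: cell_size {g.cell_size} != {ref.cell_size}")
        if abs(g.origin[0] - ref.origin[0]) > tol or abs(g.origin[1] - ref.origin[1]) > tol:
            raise AlignmentError(f"grid {i}: origin {g.origin} != {ref.origin}")
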