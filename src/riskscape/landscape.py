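"""Categorical land-use rasters and circular-buffer habitat composition.

The study landscape is a planar-metric categorical raster (meters on both
axes).  Raw land-use codes are merged into the analysis classes (young /
mature forest types by dominant species, built areas, bogs, clear cuts and
agricultural fields), and habitat availability around a nest box is
summarised as the area of each merged class whose cell centers fall within
a circular buffer.  Two buffer radii per species approximate the home-range
and dispersal scales.

Zonal rule: a cell contributes its full area iff its *center* lies within
the buffer radius (Euclidean distance).  Areas are reported in hectares.
Buffers are truncated at the grid edge; an entirely-outside buffer yields an
empty composition and a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LandUseGrid",
    "ClassTable",
    "HabitatComposition",
    "GridFormatError",
    "MERGED_CLASSES",
    "default_class_table",
    "read_grid",
    "write_grid",
    "merge_classes",
    "buffer_composition",
    "compositions_for_boxes",
]

#: Canonical merged analysis classes, in reporting order.  "Field"
#: (agriculture) comes from a separate land-use source in the original maps
#: and is carried as raw code 25 in synthetic grids.
MERGED_CLASSES = [
    "Clear cut",
    "Y birch",
    "Y pine",
    "Y mix",
    "Mo birch",
    "Mo pine",
    "Mo spruce",
    "Mo birch pine",
    "Mo pine spruce",
    "Mo birch spruce",
    "Built",
    "Bog",
    "Field",
]

_DEFAULT_MERGE = {
    1: "Clear cut",
    3: "Y birch",
    6: "Y birch",
    4: "Y pine",
    5: "Y mix",
    7: "Y mix",
    8: "Y mix",
    9: "Mo birch",
    15: "Mo birch",
    10: "Mo pine",
    16: "Mo pine",
    11: "Mo spruce",
    17: "Mo spruce",
    12: "Mo birch pine",
    18: "Mo birch pine",
    13: "Mo pine spruce",
    19: "Mo pine spruce",
    14: "Mo birch spruce",
    20: "Mo birch spruce",
    21: "Built",
    22: "Built",
    23: "Built",
    24: "Bog",
    25: "Field",
}


class GridFormatError(ValueError):
    """Raster file violates the expected format."""


@dataclass
class ClassTable:
    """Mapping raw land-use codes to merged analysis class labels."""

    mapping: dict[int, str] = field(default_factory=lambda: dict(_DEFAULT_MERGE))

    def __post_init__(self) -> None:
        for code, label in self.mapping.items():
            if not label:
                raise ValueError(f"empty merged label for raw code {code}")

    @property
    def labels(self) -> list[str]:
        """Merged labels in order of first appearance."""
        seen: list[str] = []
        for label in self.mapping.values():
            if label not in seen:
                seen.append(label)
        return seen

    @classmethod
    def from_csv(cls, path: str | Path) -> "ClassTable":
        df = pd.read_csv(path)
        if not {"raw_code", "merged_label"} <= set(df.columns):
            raise GridFormatError(
                f"{path}: class table needs columns raw_code,merged_label"
            )
        return cls(dict(zip(df["raw_code"].astype(int), df["merged_label"].astype(str))))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"raw_code": list(self.mapping), "merged_label": list(self.mapping.values())}
        ).to_csv(path, index=False)


def default_class_table() -> ClassTable:
    return ClassTable()


@dataclass
class LandUseGrid:
    """Categorical raster on a planar metric grid.

    ``cells`` is row-major with row 0 the *northernmost* row (the ESRI ASCII
    convention); ``origin_x, origin_y`` is the lower-left corner in meters.
    ``labels`` maps cell codes to merged class labels once ``merge_classes``
    has been applied.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    cells: np.ndarray
    nodata_code: int = -9999
    labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        if self.cells.ndim != 2:
            raise ValueError("cells must be a 2-D array")
        if not np.issubdtype(self.cells.dtype, np.integer):
            raise GridFormatError("cell values must be integers")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.cells.shape[0]

    @property
    def n_cols(self) -> int:
        return self.cells.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the covered rectangle."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def value_at(self, x: float, y: float) -> int:
        """Cell code containing point (x, y); nodata_code if outside."""
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row = self.n_rows - 1 - int(np.floor((y - self.origin_y) / self.cell_size))
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return int(self.cells[row, col])
        return self.nodata_code


@dataclass
class HabitatComposition:
    """Per-class area (ha) within one circular buffer around one point."""

    box_id: str
    radius_m: float
    areas_ha: dict[str, float]
    total_covered_ha: float

    def as_rows(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "box_id": self.box_id,
                "radius_m": self.radius_m,
                "class": list(self.areas_ha),
                "area_ha": list(self.areas_ha.values()),
            }
        )


# ---------------------------------------------------------------------------
# Raster I/O


def read_grid(path: str | Path, format: str | None = None) -> LandUseGrid:
    """Read a categorical raster from ESRI ASCII or single-band GeoTIFF.

    ``format`` is inferred from the file suffix when omitted.
    """
    path = Path(path)
    if format is None:
        format = "geotiff" if path.suffix.lower() in {".tif", ".tiff"} else "esri_ascii"
    if format == "esri_ascii":
        return _read_ascii(path)
    if format == "geotiff":
        return _read_geotiff(path)
    raise ValueError(f"unknown raster format {format!r}")


def _read_ascii(path: Path) -> LandUseGrid:
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(f"{path}: bad header line {i + 1}: {line!r}") from exc
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
        if key not in header:
            raise GridFormatError(f"{path}: header missing {key!r}")
    for j, line in enumerate(lines[i:], start=i):
        if not line.strip():
            continue
        vals = np.array(line.split())
        try:
            fvals = vals.astype(float)
        except ValueError as exc:
            raise GridFormatError(f"{path}: non-numeric cell value on line {j + 1}") from exc
        if not np.all(fvals == np.round(fvals)):
            raise GridFormatError(f"{path}: non-integer cell value on line {j + 1}")
        rows.append(fvals.astype(np.int64))
    cells = np.vstack(rows)
    if cells.shape != (int(header["nrows"]), int(header["ncols"])):
        raise GridFormatError(
            f"{path}: data shape {cells.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return LandUseGrid(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        cells=cells,
        nodata_code=int(header["nodata_value"]),
    )


# GeoTIFF tag ids used for minimal georeferencing.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _read_geotiff(path: Path) -> LandUseGrid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = {tag.code: tag.value for tag in page.tags.values()}
    if data.ndim != 2:
        raise GridFormatError(f"{path}: expected a single-band raster, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        if np.all(data == np.round(data)):
            data = data.astype(np.int64)
        else:
            raise GridFormatError(f"{path}: non-integer cell values in band 1")
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise GridFormatError(f"{path}: missing GeoTIFF pixel-scale/tiepoint tags in band 1")
    if _TAG_GDAL_NODATA not in tags:
        raise GridFormatError(f"{path}: missing nodata declaration (GDAL_NODATA tag) in band 1")
    sx, sy = float(tags[_TAG_PIXEL_SCALE][0]), float(tags[_TAG_PIXEL_SCALE][1])
    if not np.isclose(sx, sy):
        raise GridFormatError(f"{path}: anisotropic pixels ({sx} x {sy}) unsupported")
    tp = tags[_TAG_TIEPOINT]
    x_tl, y_tl = float(tp[3]), float(tp[4])
    nodata = int(float(str(tags[_TAG_GDAL_NODATA]).strip("\x00 ")))
    n_rows = data.shape[0]
    return LandUseGrid(
        origin_x=x_tl,
        origin_y=y_tl - n_rows * sx,
        cell_size=sx,
        cells=data.astype(np.int64),
        nodata_code=nodata,
    )


def write_grid(grid: LandUseGrid, path: str | Path, format: str | None = None) -> None:
    """Write a grid as ESRI ASCII or GeoTIFF (suffix-inferred)."""
    path = Path(path)
    if format is None:
        format = "geotiff" if path.suffix.lower() in {".tif", ".tiff"} else "esri_ascii"
    if format == "esri_ascii":
        with open(path, "w") as fh:
            fh.write(f"ncols {grid.n_cols}\n")
            fh.write(f"nrows {grid.n_rows}\n")
            fh.write(f"xllcorner {grid.origin_x:.6f}\n")
            fh.write(f"yllcorner {grid.origin_y:.6f}\n")
            fh.write(f"cellsize {grid.cell_size:.6f}\n")
            fh.write(f"NODATA_value {grid.nodata_code}\n")
            np.savetxt(fh, grid.cells, fmt="%d")
    elif format == "geotiff":
        import tifffile

        y_tl = grid.origin_y + grid.n_rows * grid.cell_size
        extratags = [
            (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
            (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, y_tl, 0.0)),
            (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata_code)),
        ]
        tifffile.imwrite(path, grid.cells.astype(np.int32), extratags=extratags)
    else:
        raise ValueError(f"unknown raster format {format!r}")


# ---------------------------------------------------------------------------
# Class merging


def merge_classes(grid: LandUseGrid, table: ClassTable | None = None) -> LandUseGrid:
    """Replace raw cell codes by merged analysis-class codes.

    Merged codes are the position of the label in ``table.labels``; the
    result carries a ``labels`` dict.  Applying the operation to an
    already-merged grid returns it unchanged (idempotent).
    """
    table = table or default_class_table()
    if grid.labels is not None and set(grid.labels.values()) <= set(table.mapping.values()):
        return grid
    labels = table.labels
    label_code = {lab: i for i, lab in enumerate(labels)}
    lut_size = max(max(table.mapping), grid.nodata_code if grid.nodata_code >= 0 else 0) + 1
    mask = grid.cells != grid.nodata_code
    raw = grid.cells[mask]
    unknown = np.setdiff1d(np.unique(raw), np.fromiter(table.mapping, dtype=np.int64))
    if unknown.size:
        idx = int(np.flatnonzero((grid.cells == unknown[0]).ravel())[0])
        raise ValueError(
            f"unknown raw land-use code(s) {unknown.tolist()} "
            f"(first at flat cell index {idx})"
        )
    if raw.size and raw.min() < 0:
        raise ValueError("negative non-nodata cell codes are not supported")
    lut = np.full(lut_size, -1, dtype=np.int64)
    for code, lab in table.mapping.items():
        lut[code] = label_code[lab]
    merged = np.full_like(grid.cells, grid.nodata_code)
    merged[mask] = lut[raw]
    return replace(grid, cells=merged, labels={i: lab for lab, i in label_code.items()})


# ---------------------------------------------------------------------------
# Buffer composition


def buffer_composition(
    grid: LandUseGrid,
    x: float,
    y: float,
    radius_m: float,
    box_id: str = "",
) -> HabitatComposition:
    """Area (ha) of each class whose cell center lies within ``radius_m`` of (x, y).

    Classes absent inside the buffer are reported with area 0.  The class set
    is ``grid.labels`` for merged grids, otherwise the distinct codes present
    in the grid (as strings).
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("point coordinates must be finite")
    if grid.labels is not None:
        class_names = [grid.labels[c] for c in sorted(grid.labels)]
        code_of = {c: i for i, c in enumerate(sorted(grid.labels))}
    else:
        codes = sorted(int(c) for c in np.unique(grid.cells) if c != grid.nodata_code)
        class_names = [str(c) for c in codes]
        code_of = {c: i for i, c in enumerate(codes)}

    cs = grid.cell_size
    col_lo = int(np.floor((x - radius_m - grid.origin_x) / cs))
    col_hi = int(np.ceil((x + radius_m - grid.origin_x) / cs))
    y_top = grid.origin_y + grid.n_rows * cs
    row_lo = int(np.floor((y_top - (y + radius_m)) / cs))
    row_hi = int(np.ceil((y_top - (y - radius_m)) / cs))
    col_lo, col_hi = max(col_lo, 0), min(col_hi, grid.n_cols)
    row_lo, row_hi = max(row_lo, 0), min(row_hi, grid.n_rows)

    counts = np.zeros(len(class_names), dtype=np.int64)
    if col_lo < col_hi and row_lo < row_hi:
        sub = grid.cells[row_lo:row_hi, col_lo:col_hi]
        cols = np.arange(col_lo, col_hi)
        rows = np.arange(row_lo, row_hi)
        cx = grid.origin_x + (cols + 0.5) * cs
        cy = grid.origin_y + (grid.n_rows - rows - 0.5) * cs
        d2 = (cx[None, :] - x) ** 2 + (cy[:, None] - y) ** 2
        inside = (d2 <= radius_m**2) & (sub != grid.nodata_code)
        if inside.any():
            vals = sub[inside]
            for code, count in zip(*np.unique(vals, return_counts=True)):
                counts[code_of[int(code)]] += count
    if counts.sum() == 0:
        logger.warning(
            "buffer (%.1f, %.1f, r=%.0f m) covers no grid cells; empty composition",
            x, y, radius_m,
        )
    cell_ha = cs * cs / 1e4
    areas = {name: float(c) * cell_ha for name, c in zip(class_names, counts)}
    return HabitatComposition(
        box_id=box_id,
        radius_m=float(radius_m),
        areas_ha=areas,
        total_covered_ha=float(counts.sum()) * cell_ha,
    )


def compositions_for_boxes(
    grid: LandUseGrid,
    boxes: pd.DataFrame,
    radius_m: float,
) -> pd.DataFrame:
    """Wide per-box composition table: one row per box, one column per class.

    ``boxes`` needs columns box_id, x, y.
    """
    records = []
    for row in boxes.itertuples(index=False):
        comp = buffer_composition(grid, row.x, row.y, radius_m, box_id=str(row.box_id))
        rec = {"box_id": row.box_id, "radius_m": radius_m, **comp.areas_ha}
        records.append(rec)
    return pd.DataFrame(records)
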