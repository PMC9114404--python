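"""Raster data model and I/O shared by every stage of the pipeline.

A :class:`Grid` is a regular, north-up, square-celled raster of one
variable in a planar metric coordinate system.  Internally nodata cells
are stored as NaN; the ``nodata`` sentinel is only used when reading and
writing files.  Cell centres sit at ``origin_x + (col + 0.5) * cell`` and
``origin_y - (row + 0.5) * cell`` (the origin is the outer north-west
corner of cell (0, 0)), and point-in-cell tests use half-open intervals
so every point belongs to exactly one cell.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class GridFormatError(ValueError):
    """Raised when a raster file lacks required geometry metadata."""


class GeometryMismatchError(ValueError):
    """Raised when grids that must share one geometry do not."""


@dataclass
class Grid:
    """Single-variable raster with square cells and NaN-coded nodata."""

    values: np.ndarray
    cell_size_m: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float = -9999.0
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be a 2-D array")
        if not self.cell_size_m > 0:
            raise ValueError("cell_size_m must be positive")

    # -- geometry ----------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.cell_size_m, other.cell_size_m)
            and np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
        )

    def cell_of(self, x, y):
        """Map point coordinates to (row, col); half-open cell intervals."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size_m).astype(int)
        row = np.floor((self.origin_y - y) / self.cell_size_m).astype(int)
        return row, col

    def contains(self, x, y):
        row, col = self.cell_of(x, y)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    def sample(self, x, y):
        """Cell value at point locations; NaN outside the grid."""
        row, col = self.cell_of(x, y)
        inside = (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)
        out = np.full(np.shape(row), np.nan, dtype=float)
        out[inside] = self.values[row[inside], col[inside]]
        return out

    def cell_centres(self):
        """(x, y) coordinate arrays of all cell centres, shape (nrows, ncols)."""
        xs = self.origin_x + (np.arange(self.ncols) + 0.5) * self.cell_size_m
        ys = self.origin_y - (np.arange(self.nrows) + 0.5) * self.cell_size_m
        return np.meshgrid(xs, ys)

    def copy(self, **changes) -> "Grid":
        g = replace(self, **changes)
        if "values" not in changes:
            g.values = self.values.copy()
        return g


@dataclass
class GridStack:
    """Ordered collection of named grids sharing one geometry.

    A cell is valid in the stack iff it is valid in every layer
    (nodata propagates conjunctively).
    """

    layers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = list(self.layers.values())
        for g in grids[1:]:
            if not grids[0].same_geometry(g):
                raise GeometryMismatchError("stack layers must share one geometry")

    def add(self, name: str, grid: Grid) -> None:
        if name in self.layers:
            raise ValueError(f"duplicate layer name {name!r}")
        if self.layers and not self.reference.same_geometry(grid):
            raise GeometryMismatchError(f"layer {name!r} geometry mismatch")
        grid.name = name
        self.layers[name] = grid

    def __getitem__(self, name: str) -> Grid:
        if name not in self.layers:
            raise KeyError(f"no layer named {name!r}; have {list(self.layers)}")
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def names(self) -> list:
        return list(self.layers)

    @property
    def reference(self) -> Grid:
        return next(iter(self.layers.values()))

    @property
    def joint_valid_mask(self) -> np.ndarray:
        mask = np.ones(self.reference.values.shape, dtype=bool)
        for g in self.layers.values():
            mask &= g.valid_mask
        return mask

    def as_table(self, names=None) -> pd.DataFrame:
        """Jointly valid cells as a DataFrame, one column per layer plus row/col."""
        names = list(names) if names is not None else self.names
        mask = self.joint_valid_mask
        rows, cols = np.nonzero(mask)
        data = {"row": rows, "col": cols}
        for n in names:
            data[n] = self[n].values[rows, cols]
        return pd.DataFrame(data)

    def subset(self, names) -> "GridStack":
        return GridStack({n: self[n] for n in names})

    def copy(self) -> "GridStack":
        return GridStack({n: g.copy() for n, g in self.layers.items()})


# ---------------------------------------------------------------------------
# I/O


def write_grid(grid: Grid, path: str, format: str | None = None) -> None:
    """Write a grid as ESRI ASCII (.asc) or single-band float32 GeoTIFF."""
    fmt = format or _infer_format(path)
    if fmt == "ascii_grid":
        _write_ascii(grid, path)
    elif fmt == "geotiff":
        _write_geotiff(grid, path)
    else:
        raise ValueError(f"unknown raster format {fmt!r}")


def read_grid(path: str, format: str | None = None) -> Grid:
    """Read a grid, honouring the file's nodata sentinel."""
    if not os.path.exists(path):
        raise IOError(f"raster file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt == "ascii_grid":
        return _read_ascii(path)
    if fmt == "geotiff":
        return _read_geotiff(path)
    raise ValueError(f"unknown raster format {fmt!r}")


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".asc", ".agr"):
        return "ascii_grid"
    if ext in (".tif", ".tiff"):
        return "geotiff"
    raise ValueError(f"cannot infer raster format from {path!r}")


def _write_ascii(grid: Grid, path: str) -> None:
    vals = grid.values.copy()
    vals[~np.isfinite(vals)] = grid.nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.origin_x!r}\n")
        fh.write(f"yllcorner {grid.origin_y - grid.nrows * grid.cell_size_m!r}\n")
        fh.write(f"cellsize {grid.cell_size_m!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in vals:  # ESRI rows run north to south, matching our layout
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_ascii(path: str) -> Grid:
    header: dict = {}
    data_lines: list = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in (
                "ncols", "nrows", "xllcorner", "yllcorner",
                "xllcenter", "yllcenter", "cellsize", "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                data_lines.append(parts)
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise GridFormatError(f"{path}: missing header field {req!r}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    vals = np.array([[float(v) for v in row] for row in data_lines], dtype=float)
    if vals.shape != (nrows, ncols):
        raise GridFormatError(
            f"{path}: data shape {vals.shape} does not match header ({nrows},{ncols})"
        )
    nodata = header.get("nodata_value", -9999.0)
    vals[vals == nodata] = np.nan
    if "xllcorner" in header:
        x0 = header["xllcorner"]
        y0 = header["yllcorner"] + nrows * cell
    else:  # llcenter variant
        x0 = header["xllcenter"] - cell / 2
        y0 = header["yllcenter"] - cell / 2 + nrows * cell
    return Grid(vals, cell, x0, y0, nodata=nodata)


_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _write_geotiff(grid: Grid, path: str) -> None:
    import tifffile

    vals = grid.values.astype(np.float32)
    vals[~np.isfinite(vals)] = np.float32(grid.nodata)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size_m, grid.cell_size_m, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(grid.nodata)),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def _read_geotiff(path: str) -> Grid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        vals = page.asarray().astype(float)
        tags = {t.code: t.value for t in page.tags.values()}
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise GridFormatError(f"{path}: missing GeoTIFF geometry tags")
    scale = tags[_TAG_PIXEL_SCALE]
    tie = tags[_TAG_TIEPOINT]
    nodata = float(tags.get(_TAG_GDAL_NODATA, "-9999"))
    vals[vals == np.float32(nodata)] = np.nan
    return Grid(vals, float(scale[0]), float(tie[3]), float(tie[4]), nodata=nodata)


# ---------------------------------------------------------------------------
# Resampling and masking


def resample(grid: Grid, target_cell_size_m: float, method: str = "block_mean") -> Grid:
    """Aggregate to a coarser grid defined on the same origin.

    Each target cell aggregates the source cells whose centres fall inside
    it, so source and target cell sizes need not nest as integer multiples.
    Methods: ``block_mean`` (continuous), ``mode`` (labels; smallest label
    wins ties), ``nearest`` (source cell containing the target centre).
    """
    if target_cell_size_m < grid.cell_size_m:
        raise ValueError(
            "unsupported upsampling: target cell "
            f"{target_cell_size_m} < source cell {grid.cell_size_m}"
        )
    factor = target_cell_size_m / grid.cell_size_m
    t_nrows = max(1, int(np.ceil(grid.nrows / factor)))
    t_ncols = max(1, int(np.ceil(grid.ncols / factor)))

    if method == "nearest":
        out = np.full((t_nrows, t_ncols), np.nan)
        tx = grid.origin_x + (np.arange(t_ncols) + 0.5) * target_cell_size_m
        ty = grid.origin_y - (np.arange(t_nrows) + 0.5) * target_cell_size_m
        xx, yy = np.meshgrid(tx, ty)
        out = grid.sample(xx, yy)
        return Grid(out, target_cell_size_m, grid.origin_x, grid.origin_y,
                    nodata=grid.nodata, name=grid.name, units=grid.units)

    # target index of every source cell centre
    src_rows = np.arange(grid.nrows)
    src_cols = np.arange(grid.ncols)
    t_row = np.floor((src_rows + 0.5) / factor).astype(int)
    t_col = np.floor((src_cols + 0.5) / factor).astype(int)
    t_row = np.clip(t_row, 0, t_nrows - 1)
    t_col = np.clip(t_col, 0, t_ncols - 1)
    ridx, cidx = np.meshgrid(t_row, t_col, indexing="ij")
    flat_idx = (ridx * t_ncols + cidx).ravel()
    vals = grid.values.ravel()
    valid = np.isfinite(vals)

    if method == "block_mean":
        sums = np.bincount(flat_idx[valid], weights=vals[valid],
                           minlength=t_nrows * t_ncols)
        counts = np.bincount(flat_idx[valid], minlength=t_nrows * t_ncols)
        out = np.full(t_nrows * t_ncols, np.nan)
        nz = counts > 0
        out[nz] = sums[nz] / counts[nz]
    elif method == "mode":
        out = np.full(t_nrows * t_ncols, np.nan)
        df = pd.DataFrame({"cell": flat_idx[valid], "label": vals[valid]})
        if len(df):
            counts = df.groupby(["cell", "label"]).size().reset_index(name="n")
            counts = counts.sort_values(["cell", "n", "label"],
                                        ascending=[True, False, True])
            best = counts.drop_duplicates("cell")
            out[best["cell"].to_numpy(dtype=int)] = best["label"].to_numpy()
    else:
        raise ValueError(f"unknown resample method {method!r}")

    return Grid(out.reshape(t_nrows, t_ncols), target_cell_size_m,
                grid.origin_x, grid.origin_y, nodata=grid.nodata,
                name=grid.name, units=grid.units)


def mask_by_depth(stack: GridStack, depth_layer: str, min_depth_m: float):
    """Set cells shallower than ``min_depth_m`` to nodata in every layer.

    Depth is stored positive-down (metres below the sea surface).  Returns
    the masked stack and the number of cells newly masked, mirroring the
    exclusion of shallow seamount sites from habitat mapping.
    """
    depth = stack[depth_layer]
    shallow = depth.valid_mask & (depth.values < min_depth_m)
    out = stack.copy()
    for g in out.layers.values():
        g.values[shallow] = np.nan
    return out, int(shallow.sum())
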