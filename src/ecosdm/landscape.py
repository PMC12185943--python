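"""Gridded landscapes: the raster container shared by every pipeline stage.

A :class:`Landscape` is a stack of named environmental layers on a common
grid with a shared nodata mask; an :class:`EcoregionMap` is a categorical
raster of region codes on the same geometry.  Coordinates live in an
abstract projected frame: cell centers, 0-based row/col, x increasing east
(with column), y increasing north (so row 0 is the northern edge).

Rasters are serialized as ESRI ASCII grids (plain-text ``.asc``), one file
per layer, with a JSON sidecar holding the variable catalog and provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

CLIMATE = "climate"
SOIL = "soil"

#: Canonical variable names mirrored from continental climate/soil products:
#: nine bioclimatic summaries and eight soil attributes.
CLIMATE_NAMES = ("bio1", "bio2", "bio4", "bio5", "bio6", "bio12", "bio13", "bio14", "bio15")
SOIL_NAMES = ("BDW", "CEC", "CLY", "DES", "NTO", "PTO", "TWI", "SOC")

NODATA = -9999.0


@dataclass(frozen=True)
class VariableInfo:
    name: str
    category: str  # "climate" | "soil"
    units: str = "z-score"


@dataclass
class Landscape:
    """Multi-layer environmental raster with shared geometry and mask."""

    layers: dict[str, np.ndarray]
    nodata_mask: np.ndarray  # True where a cell carries no data
    catalog: list[VariableInfo]
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)  # (x0, y0) = lower-left corner

    def __post_init__(self) -> None:
        names = [v.name for v in self.catalog]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in catalog")
        if set(names) != set(self.layers):
            raise ValueError("catalog and layers disagree on variable names")
        shape = self.nodata_mask.shape
        for name, grid in self.layers.items():
            if grid.shape != shape:
                raise ValueError(f"layer {name!r} shape {grid.shape} != mask shape {shape}")

    # -- geometry ---------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.nodata_mask.shape[0]

    @property
    def n_cols(self) -> int:
        return self.nodata_mask.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.nodata_mask.shape

    def variable_names(self, category: str | None = None) -> list[str]:
        return [v.name for v in self.catalog if category is None or v.category == category]

    def category_of(self, name: str) -> str:
        for v in self.catalog:
            if v.name == name:
                return v.category
        raise KeyError(name)

    def rowcol_to_xy(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates; row 0 is the northernmost row."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = y0 + (self.n_rows - np.asarray(row) - 0.5) * self.cell_size
        return x, y

    def xy_to_rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Containing cell of each point (no interpolation). May fall off-grid."""
        x0, y0 = self.origin
        fc = np.floor((np.asarray(x, dtype=float) - x0) / self.cell_size)
        fr = self.n_rows - 1 - np.floor((np.asarray(y, dtype=float) - y0) / self.cell_size)
        # non-finite coordinates map to a far off-grid cell instead of erroring
        col = np.where(np.isfinite(fc), fc, -(2**30)).astype(int)
        row = np.where(np.isfinite(fr), fr, -(2**30)).astype(int)
        return row, col

    def in_extent(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.xy_to_rowcol(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = np.indices(self.shape)
        return self.rowcol_to_xy(rows.ravel(), cols.ravel())

    def values_at(self, x: np.ndarray, y: np.ndarray, variables: Sequence[str]) -> np.ndarray:
        """Matrix of layer values at the containing cell of each point.

        Off-grid or masked points yield NaN rows.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        out = np.full((x.size, len(variables)), np.nan)
        ok = np.isfinite(x) & np.isfinite(y) & self.in_extent(np.where(np.isfinite(x), x, 0), np.where(np.isfinite(y), y, 0))
        row, col = self.xy_to_rowcol(x[ok], y[ok])
        unmasked = ~self.nodata_mask[row, col]
        idx = np.flatnonzero(ok)[unmasked]
        for j, name in enumerate(variables):
            out[idx, j] = self.layers[name][row[unmasked], col[unmasked]]
        return out


@dataclass
class EcoregionMap:
    """Categorical raster of integer region codes with human-readable labels."""

    codes: np.ndarray  # int grid; -1 on masked cells
    labels: dict[int, str]
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.codes.shape, dtype=bool)
        present = set(np.unique(self.codes[~self.nodata_mask]).tolist())
        if not present <= set(self.labels):
            raise ValueError(f"codes {present - set(self.labels)} missing from labels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def region_at(self, landscape: Landscape, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Region code at each point; -1 when off-grid or masked."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        out = np.full(x.size, -1, dtype=int)
        ok = np.isfinite(x) & np.isfinite(y)
        ok[ok] = landscape.in_extent(x[ok], y[ok])
        row, col = landscape.xy_to_rowcol(x[ok], y[ok])
        vals = np.where(self.nodata_mask[row, col], -1, self.codes[row, col])
        out[np.flatnonzero(ok)] = vals
        return out


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def write_ascii_grid(path: str | Path, grid: np.ndarray, mask: np.ndarray,
                     cell_size: float = 1.0, origin: tuple[float, float] = (0.0, 0.0)) -> None:
    arr = np.where(mask, NODATA, grid)
    n_rows, n_cols = arr.shape
    header = (
        f"ncols {n_cols}\nnrows {n_rows}\n"
        f"xllcorner {origin[0]}\nyllcorner {origin[1]}\n"
        f"cellsize {cell_size}\nNODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, np.ndarray, float, tuple[float, float]]:
    """Return (grid, mask, cell_size, origin) from an ESRI ASCII file."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    grid = grid.reshape(int(meta["nrows"]), int(meta["ncols"]))
    mask = grid == meta["nodata_value"]
    return grid, mask, meta["cellsize"], (meta["xllcorner"], meta["yllcorner"])


def save_landscape(landscape: Landscape, outdir: str | Path, params: Mapping | None = None) -> None:
    """One .asc per layer plus a JSON sidecar with the catalog and provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, grid in landscape.layers.items():
        write_ascii_grid(outdir / f"{name}.asc", grid, landscape.nodata_mask,
                         landscape.cell_size, landscape.origin)
    sidecar = {
        "catalog": [{"name": v.name, "category": v.category, "units": v.units}
                    for v in landscape.catalog],
        "cell_size": landscape.cell_size,
        "origin": list(landscape.origin),
        "params": dict(params or {}),
    }
    (outdir / "landscape.json").write_text(json.dumps(sidecar, indent=2))


def load_landscape(outdir: str | Path) -> Landscape:
    outdir = Path(outdir)
    sidecar = json.loads((outdir / "landscape.json").read_text())
    layers: dict[str, np.ndarray] = {}
    mask = None
    for entry in sidecar["catalog"]:
        grid, m, _, _ = read_ascii_grid(outdir / f"{entry['name']}.asc")
        layers[entry["name"]] = grid
        mask = m if mask is None else mask
    catalog = [VariableInfo(e["name"], e["category"], e.get("units", "z-score"))
               for e in sidecar["catalog"]]
    return Landscape(layers=layers, nodata_mask=mask, catalog=catalog,
                     cell_size=sidecar["cell_size"], origin=tuple(sidecar["origin"]))


def save_ecoregions(eco: EcoregionMap, path: str | Path,
                    cell_size: float = 1.0, origin: tuple[float, float] = (0.0, 0.0)) -> None:
    path = Path(path)
    write_ascii_grid(path, eco.codes.astype(float), eco.nodata_mask, cell_size, origin)
    path.with_suffix(".labels.json").write_text(
        json.dumps({str(k): v for k, v in eco.labels.items()}, indent=2))


def load_ecoregions(path: str | Path) -> EcoregionMap:
    path = Path(path)
    grid, mask, _, _ = read_ascii_grid(path)
    labels = {int(k): v for k, v in
              json.loads(path.with_suffix(".labels.json").read_text()).items()}
    codes = np.where(mask, -1, grid).astype(int)
    return EcoregionMap(codes=codes, labels=labels, nodata_mask=mask)
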