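"""Environmental raster stacks, site extraction, and spatial predictors.

Rasters are modelled as co-registered 2-D float grids on a regular planar
grid (cell centres at ``x = xll + (col + 0.5) * cell``, rows counted from the
top as in the ESRI ASCII grid convention).  The module covers the predictor
preparation steps of the analysis: resampling layers onto a common grid,
extracting per-site values, greedy pruning of inter-correlated variables, and
PCNM (principal coordinates of neighbour matrices) spatial eigenvectors used
to absorb spatial genetic structure in the gradient-forest stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "GridSpec", "EnvStack", "SpatialVectors",
    "read_ascii_grid", "write_ascii_grid",
    "resample_to_grid", "extract_at_points", "prune_correlated", "pcnm",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid (planar coordinates)."""

    nrows: int
    ncols: int
    xll: float = 0.0
    yll: float = 0.0
    cell: float = 1.0

    def __post_init__(self):
        if self.nrows < 1 or self.ncols < 1 or self.cell <= 0:
            raise ValueError("grid must have positive dimensions and cell size")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax)."""
        return (self.xll, self.xll + self.ncols * self.cell,
                self.yll, self.yll + self.nrows * self.cell)

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cells containing planar points; raises if outside."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        xmin, xmax, ymin, ymax = self.extent
        bad = (x < xmin) | (x > xmax) | (y < ymin) | (y > ymax)
        if np.any(bad):
            sites = np.flatnonzero(bad).tolist()
            raise ValueError(f"coordinates outside raster extent for sites {sites}")
        col = np.clip(np.floor((x - self.xll) / self.cell).astype(int), 0, self.ncols - 1)
        # rows are counted from the top edge
        row = np.clip(np.floor(self.nrows - (y - self.yll) / self.cell).astype(int),
                      0, self.nrows - 1)
        return row, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell centre, shape (nrows, ncols)."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.xll + (cols + 0.5) * self.cell
        y = self.yll + (self.nrows - rows - 0.5) * self.cell
        return np.meshgrid(x, y)


@dataclass
class EnvStack:
    """Named, co-registered environmental layers plus an in-range mask."""

    layers: dict[str, np.ndarray]
    grid: GridSpec
    kinds: dict[str, str] = field(default_factory=dict)
    mask: np.ndarray | None = None

    def __post_init__(self):
        if not self.layers:
            raise ValueError("EnvStack requires at least one layer")
        shape = (self.grid.nrows, self.grid.ncols)
        for name, arr in self.layers.items():
            arr = np.asarray(arr, float)
            if arr.shape != shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} != grid {shape}")
            self.layers[name] = arr
            self.kinds.setdefault(name, "continuous")
        if self.mask is None:
            self.mask = np.ones(shape, bool)
        else:
            self.mask = np.asarray(self.mask, bool)
            if self.mask.shape != shape:
                raise ValueError("mask shape does not match grid")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.grid.nrows, self.grid.ncols)

    def copy(self) -> "EnvStack":
        return EnvStack({k: v.copy() for k, v in self.layers.items()}, self.grid,
                        dict(self.kinds), self.mask.copy())

    def to_dir(self, path: str | Path) -> None:
        """Write every layer (and mask) as headered ASCII grids."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, arr in self.layers.items():
            write_ascii_grid(path / f"{name}.asc", arr, self.grid)
        write_ascii_grid(path / "mask.asc", self.mask.astype(float), self.grid)

    @classmethod
    def from_dir(cls, path: str | Path) -> "EnvStack":
        path = Path(path)
        layers: dict[str, np.ndarray] = {}
        grid = None
        mask = None
        for f in sorted(path.glob("*.asc")):
            arr, g = read_ascii_grid(f)
            if grid is None:
                grid = g
            elif g != grid:
                raise ValueError(f"layer {f.name} not co-registered with the stack")
            if f.stem == "mask":
                mask = arr > 0.5
            else:
                layers[f.stem] = arr
        if not layers:
            raise ValueError(f"no .asc layers found in {path}")
        return cls(layers, grid, mask=mask)


def write_ascii_grid(path: str | Path, arr: np.ndarray, grid: GridSpec,
                     nodata: float = -9999.0) -> None:
    """Write a 2-D array as an ESRI ASCII grid (plain text)."""
    arr = np.asarray(arr, float)
    out = np.where(np.isnan(arr), nodata, arr)
    header = (f"ncols {grid.ncols}\nnrows {grid.nrows}\n"
              f"xllcorner {grid.xll!r}\nyllcorner {grid.yll!r}\n"
              f"cellsize {grid.cell!r}\nNODATA_value {nodata!r}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; NODATA cells become NaN."""
    head: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    grid = GridSpec(int(head["nrows"]), int(head["ncols"]),
                    head.get("xllcorner", 0.0), head.get("yllcorner", 0.0),
                    head.get("cellsize", 1.0))
    arr = arr.reshape(grid.nrows, grid.ncols)
    nodata = head.get("nodata_value")
    if nodata is not None:
        arr = np.where(arr == nodata, np.nan, arr)
    return arr, grid


def resample_to_grid(layer: np.ndarray, source: GridSpec, target: GridSpec,
                     kind: str = "continuous") -> np.ndarray:
    """Resample a layer onto a target grid.

    Continuous layers use bilinear interpolation between source cell centres;
    categorical layers use nearest neighbour, so output values are a subset of
    the input values.
    """
    if kind not in ("continuous", "categorical"):
        raise ValueError(f"unknown layer kind {kind!r}")
    sx0, sx1, sy0, sy1 = source.extent
    tx0, tx1, ty0, ty1 = target.extent
    if tx1 <= sx0 or tx0 >= sx1 or ty1 <= sy0 or ty0 >= sy1:
        raise ValueError("target extent is disjoint from the source extent")
    layer = np.asarray(layer, float)
    tx, ty = target.cell_centers()
    # fractional source array indices of target cell centres
    col = (tx - source.xll) / source.cell - 0.5
    row = (source.nrows - (ty - source.yll) / source.cell) - 0.5
    order = 1 if kind == "continuous" else 0
    return ndimage.map_coordinates(layer, [row, col], order=order, mode="nearest")


def extract_at_points(stack: EnvStack, coords: np.ndarray) -> pd.DataFrame:
    """Per-site values of every layer (value of the containing cell).

    ``coords`` is an (n, 2) array of (x, y).  Sites falling outside the mask
    are flagged in the ``in_mask`` column; sites outside the raster extent
    raise, naming the offending rows.
    """
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array of x, y")
    row, col = stack.grid.cell_index(coords[:, 0], coords[:, 1])
    data = {name: arr[row, col] for name, arr in stack.layers.items()}
    df = pd.DataFrame(data)
    df["in_mask"] = stack.mask[row, col]
    return df


def prune_correlated(table: pd.DataFrame, threshold: float = 0.7
                     ) -> tuple[pd.DataFrame, list[str]]:
    """Iteratively drop one member of every over-correlated variable pair.

    While any pair of variables has |Pearson r| > ``threshold``, the pair
    with the largest |r| is located and the member with the larger mean
    absolute correlation against all remaining variables is removed (ties
    broken by dropping the later-named variable); correlations are then
    recomputed.  Mirrors the greedy ``findCorrelation``-style rule.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    removed: list[str] = []
    cols = [c for c in table.columns if np.issubdtype(table[c].dtype, np.number)]
    work = table[cols].copy()
    if len(cols) < 2:
        return table.copy(), removed
    while work.shape[1] >= 2:
        corr = work.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        corr = np.nan_to_num(corr)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= threshold:
            break
        mean_abs = corr.sum(axis=0) / (corr.shape[0] - 1)
        if mean_abs[i] > mean_abs[j]:
            drop = i
        elif mean_abs[j] > mean_abs[i]:
            drop = j
        else:
            drop = max(i, j)  # tie: later-named variable
        removed.append(work.columns[drop])
        work = work.drop(columns=work.columns[drop])
    keep = [c for c in table.columns if c not in removed]
    return table[keep].copy(), removed


@dataclass
class SpatialVectors:
    """PCNM spatial eigenvectors for a set of sites."""

    vectors: np.ndarray        # n_sites x n_kept, orthonormal columns
    eigenvalues: np.ndarray    # descending, all positive
    truncation_distance: float

    @property
    def names(self) -> list[str]:
        return [f"pcnm{i + 1}" for i in range(self.vectors.shape[1])]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.vectors, columns=self.names)


def pcnm(coords: np.ndarray, truncation: float | None = None) -> SpatialVectors:
    """Principal coordinates of neighbour matrices from site coordinates.

    Pairwise Euclidean distances beyond the truncation distance are replaced
    by 4x the truncation (the method's original convention); the resulting
    matrix is double-centred and eigen-decomposed.  Of the eigenvectors with
    positive eigenvalue, the top half by eigenvalue — the broadest spatial
    scales — is returned.  ``truncation=None`` uses the longest edge of the
    minimum spanning tree of the sites.
    """
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise ValueError("pcnm requires at least 3 sites of planar coordinates")
    d = squareform(pdist(coords))
    if np.all(d[np.triu_indices_from(d, 1)] == 0):
        raise ValueError("all sites are identical; distances are degenerate")
    if truncation is None:
        mst = minimum_spanning_tree(d).toarray()
        truncation = float(mst.max())
    if truncation <= 0:
        raise ValueError("truncation distance must be positive")
    dt = np.where(d > truncation, 4.0 * truncation, d)
    np.fill_diagonal(dt, 0.0)
    n = dt.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dt ** 2) @ j
    b = (b + b.T) / 2
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-8 * max(evals.max(), 1.0)
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError("no positive PCNM eigenvalues")
    n_keep = math.ceil(n_pos / 2)
    return SpatialVectors(evecs[:, :n_keep].copy(), evals[:n_keep].copy(),
                          float(truncation))
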