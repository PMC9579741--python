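"""Tile-based probability map over the 2-D reference embedding.

The map's bounding box (padded by 2% per side) is split into a
rectangular grid of tiles.  For each tile the per-library-type
percentage is computed with the type totals divided out first:

    percent[tile, t] = 100 * (count[tile, t] / N_t) / sum_u (count[tile, u] / N_u)

where ``N_t`` is the number of samples of type ``t`` in the whole
database.  Dividing by ``N_t`` makes the percentages invariant to how
many samples of each type the database happens to hold (and hence to the
500-sample cap): duplicating every sample of one type leaves every tile
percentage unchanged.

A type-level self-consistency summary ("confusion matrix" in the loose
sense used for these maps) averages, over all samples of a type, the
tile-percentage vector of the tile each sample falls in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_TILES = 24
DEFAULT_PADDING = 0.02

#: Sentinel returned by :func:`tile_of` for coordinates outside the grid.
OUT_OF_BOUNDS = None


@dataclass
class TileGrid:
    """Rectangular partition of the map with per-tile type percentages."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    nx: int
    ny: int
    types: list[str]
    tile_counts: np.ndarray  # nx x ny x T ints
    tile_percent: np.ndarray  # nx x ny x T, rows of occupied tiles sum to 100
    type_totals: np.ndarray  # length T

    @property
    def occupied(self) -> np.ndarray:
        """Boolean nx x ny mask of tiles holding at least one sample."""
        return self.tile_counts.sum(axis=2) > 0

    def tile_centers(self) -> tuple[np.ndarray, np.ndarray]:
        dx = (self.x_max - self.x_min) / self.nx
        dy = (self.y_max - self.y_min) / self.ny
        cx = self.x_min + dx * (np.arange(self.nx) + 0.5)
        cy = self.y_min + dy * (np.arange(self.ny) + 0.5)
        return cx, cy


def _bin_index(v: np.ndarray, lo: float, hi: float, n: int) -> np.ndarray:
    """Half-open binning [edge_i, edge_{i+1}) with the top edge closed.

    Returns -1 for out-of-box values.
    """
    edges = np.linspace(lo, hi, n + 1)
    idx = np.searchsorted(edges, v, side="right") - 1
    idx = np.where(v == hi, n - 1, idx)  # closed top edge
    idx = np.where((v < lo) | (v > hi), -1, idx)
    return idx.astype(int)


def build_grid(
    coords: np.ndarray,
    labels: np.ndarray,
    nx: int = DEFAULT_TILES,
    ny: int = DEFAULT_TILES,
    padding: float = DEFAULT_PADDING,
) -> TileGrid:
    """Bin the reference coordinates and compute normalized percentages."""
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be S x 2")
    if len(coords) < 1 or nx < 1 or ny < 1:
        raise ValueError("need at least one sample and one tile per axis")
    span_x = coords[:, 0].max() - coords[:, 0].min()
    span_y = coords[:, 1].max() - coords[:, 1].min()
    if span_x == 0 and span_y == 0:
        raise ValueError("degenerate bounding box: all coordinates identical")
    # a zero span on one axis still yields a usable (thin) box
    pad_x = padding * span_x or 0.5
    pad_y = padding * span_y or 0.5
    x_min, x_max = coords[:, 0].min() - pad_x, coords[:, 0].max() + pad_x
    y_min, y_max = coords[:, 1].min() - pad_y, coords[:, 1].max() + pad_y

    types = sorted(pd.unique(labels).tolist())
    t_index = {t: k for k, t in enumerate(types)}
    T = len(types)
    ix = _bin_index(coords[:, 0], x_min, x_max, nx)
    iy = _bin_index(coords[:, 1], y_min, y_max, ny)
    counts = np.zeros((nx, ny, T), dtype=np.int64)
    for i, j, lab in zip(ix, iy, labels):
        counts[i, j, t_index[lab]] += 1
    type_totals = counts.sum(axis=(0, 1))

    weighted = counts / type_totals[None, None, :]
    denom = weighted.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = 100.0 * weighted / denom
    percent[denom[..., 0] == 0] = 0.0
    return TileGrid(
        x_min=x_min, x_max=x_max, y_min=y_min, y_max=y_max,
        nx=nx, ny=ny, types=types,
        tile_counts=counts, tile_percent=percent,
        type_totals=type_totals,
    )


def tile_of(grid: TileGrid, coord: np.ndarray):
    """Tile index ``(i, j)`` of a coordinate, or ``OUT_OF_BOUNDS``."""
    x, y = float(coord[0]), float(coord[1])
    i = _bin_index(np.array([x]), grid.x_min, grid.x_max, grid.nx)[0]
    j = _bin_index(np.array([y]), grid.y_min, grid.y_max, grid.ny)[0]
    if i < 0 or j < 0:
        return OUT_OF_BOUNDS
    return (int(i), int(j))


def nearest_occupied_tile(grid: TileGrid, where) -> tuple[int, int]:
    """Occupied tile with the closest center (ties: lowest row-major index).

    ``where`` is either a tile index ``(i, j)`` or a raw coordinate pair
    outside the grid.
    """
    occupied = grid.occupied
    if not occupied.any():
        raise ValueError("grid has no occupied tiles")
    cx, cy = grid.tile_centers()
    if isinstance(where, tuple) and len(where) == 2 and all(
        isinstance(v, (int, np.integer)) for v in where
    ):
        px, py = cx[where[0]], cy[where[1]]
        if occupied[where]:
            return (int(where[0]), int(where[1]))
    else:
        px, py = float(where[0]), float(where[1])
    d2 = (cx[:, None] - px) ** 2 + (cy[None, :] - py) ** 2
    d2 = np.where(occupied, d2, np.inf)
    flat = int(np.argmin(d2))  # first minimum in row-major order
    return (flat // grid.ny, flat % grid.ny)


def confusion_matrix(
    grid: TileGrid, coords: np.ndarray, labels: np.ndarray
) -> pd.DataFrame:
    """Average own-tile percentage vector per library type (T x T, rows sum to 100).

    Row t answers: for samples of type t, what mix of types do their map
    tiles report?  High diagonal values mean the type occupies tiles
    specific to it.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    T = len(grid.types)
    sums = np.zeros((T, T))
    counts = np.zeros(T, dtype=int)
    t_index = {t: k for k, t in enumerate(grid.types)}
    for coord, lab in zip(coords, labels):
        tile = tile_of(grid, coord)
        if tile is OUT_OF_BOUNDS:
            tile = nearest_occupied_tile(grid, coord)
        k = t_index[lab]
        sums[k] += grid.tile_percent[tile[0], tile[1], :]
        counts[k] += 1
    empty = counts == 0
    if empty.any():
        missing = [grid.types[k] for k in np.flatnonzero(empty)]
        warnings.warn(
            f"type(s) with no samples excluded from confusion matrix: {missing}",
            stacklevel=2,
        )
    keep = ~empty
    matrix = sums[keep] / counts[keep, None]
    kept_types = [t for t, k in zip(grid.types, keep) if k]
    return pd.DataFrame(matrix, index=kept_types, columns=grid.types)


def grid_to_table(grid: TileGrid) -> pd.DataFrame:
    """Long-format export: tile_x, tile_y, type, count, percent."""
    rows = []
    for i in range(grid.nx):
        for j in range(grid.ny):
            for k, t in enumerate(grid.types):
                rows.append(
                    (i, j, t, int(grid.tile_counts[i, j, k]),
                     float(grid.tile_percent[i, j, k]))
                )
    return pd.DataFrame(rows, columns=["tile_x", "tile_y", "type", "count", "percent"])


def save_grid(grid: TileGrid, path: str | Path) -> None:
    """JSON serialization (exact integer counts; percentages recomputable)."""
    import json

    payload = {
        "format_version": 1,
        "bbox": [grid.x_min, grid.x_max, grid.y_min, grid.y_max],
        "nx": grid.nx,
        "ny": grid.ny,
        "types": grid.types,
        "tile_counts": grid.tile_counts.tolist(),
        "type_totals": grid.type_totals.tolist(),
    }
    with open(path, "wt") as fh:
        json.dump(payload, fh)


def load_grid(path: str | Path) -> TileGrid:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != 1:
        raise ValueError(f"{path}: unsupported grid file version")
    counts = np.asarray(payload["tile_counts"], dtype=np.int64)
    type_totals = np.asarray(payload["type_totals"], dtype=np.int64)
    weighted = counts / type_totals[None, None, :]
    denom = weighted.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = 100.0 * weighted / denom
    percent[denom[..., 0] == 0] = 0.0
    x_min, x_max, y_min, y_max = payload["bbox"]
    return TileGrid(
        x_min=x_min, x_max=x_max, y_min=y_min, y_max=y_max,
        nx=payload["nx"], ny=payload["ny"], types=list(payload["types"]),
        tile_counts=counts, tile_percent=percent, type_totals=type_totals,
    )
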