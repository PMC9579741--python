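"""Query path: composition profile -> map position -> tile -> type report.

A test library is summarised by the percentage of each library type
found in its reference-map tile.  This is deliberately reported as a
tile occupancy mix, not a calibrated posterior probability: it lets the
user gauge how similar the test library's composition is to published
libraries of each type, leaving any red-flag judgement to them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import CompositionProfile
from .database import profile_features
from .embedding import EmbeddingModel, project
from .tiling import OUT_OF_BOUNDS, TileGrid, nearest_occupied_tile, tile_of

logger = logging.getLogger(__name__)


@dataclass
class PredictionReport:
    """Per-query result: map position, tile, and the tile's type mix."""

    sample_id: str
    coordinates: np.ndarray  # (x, y)
    tile: tuple[int, int]
    fallback_used: bool
    type_percent: pd.Series  # indexed by library type, sums to 100
    parameters: dict = field(default_factory=dict)

    @property
    def top_type(self) -> str:
        return str(self.type_percent.idxmax())


def predict(
    profiles: list[CompositionProfile],
    model: EmbeddingModel,
    grid: TileGrid,
) -> list[PredictionReport]:
    """One report per profile, in input order; deterministic for a fixed model.

    A query landing in an empty tile (or off the padded map) is assigned
    the nearest occupied tile and flagged ``fallback_used`` so the report
    carries its lower confidence.  A profile whose length does not match
    the model is reported as an error and skipped; the batch continues.
    """
    usable: list[CompositionProfile] = []
    for p in profiles:
        if 4 * p.positions != model.n_features:
            logger.error(
                "%s: profile has %d positions but the model expects %d; skipped",
                p.sample_id, p.positions, model.n_features // 4,
            )
            continue
        usable.append(p)
    if not usable:
        return []
    fill = None
    if model.feature_means is not None:
        fill = model.feature_means.reshape(-1, 4)
    # one transform call per query: UMAP optimizes a batch of new points
    # jointly, so batching would let queries influence each other's
    # coordinates and break predict(A ++ B) == predict(A) ++ predict(B)
    coords = [project(model, profile_features(p, fill=fill))[0] for p in usable]
    reports = []
    for p, coord in zip(usable, coords):
        tile = tile_of(grid, coord)
        fallback = tile is OUT_OF_BOUNDS or not grid.occupied[tile]
        if fallback:
            tile = nearest_occupied_tile(grid, tuple(coord) if tile is OUT_OF_BOUNDS else tile)
        percent = pd.Series(grid.tile_percent[tile[0], tile[1], :], index=grid.types)
        reports.append(
            PredictionReport(
                sample_id=p.sample_id,
                coordinates=np.asarray(coord, dtype=float),
                tile=tile,
                fallback_used=bool(fallback),
                type_percent=percent,
                parameters={
                    "seed": p.seed,
                    "reads_sampled": p.reads_sampled,
                    "model_seed": model.params.seed,
                },
            )
        )
    return reports


def reports_to_table(reports: list[PredictionReport], grid: TileGrid) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {
            "sample_id": r.sample_id,
            "x": r.coordinates[0],
            "y": r.coordinates[1],
            "tile_x": r.tile[0],
            "tile_y": r.tile[1],
            "fallback_used": r.fallback_used,
        }
        row.update({t: r.type_percent[t] for t in grid.types})
        rows.append(row)
    return pd.DataFrame(rows)


def render_report(
    reports: list[PredictionReport],
    model: EmbeddingModel,
    grid: TileGrid,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("svg", "png"),
) -> list[Path]:
    """Write the graphical and tabular outputs for a batch of queries.

    Produces (1) the reference-map scatter with query positions,
    (2) per-type tile probability maps with query positions, (3) the
    query x type percentage heatmap, in SVG and PNG, plus the TSV report.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not reports:
        raise ValueError("nothing to render: empty report list")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    qx = np.array([r.coordinates[0] for r in reports])
    qy = np.array([r.coordinates[1] for r in reports])

    def _save(fig, stem: str) -> None:
        for fmt in formats:
            p = out_dir / f"{stem}.{fmt}"
            fig.savefig(p, bbox_inches="tight")
            written.append(p)
        plt.close(fig)

    # 1. reference map scatter
    fig, ax = plt.subplots(figsize=(7, 6))
    coords = model.reference_coords
    if model.reference_labels is not None:
        for t in grid.types:
            mask = model.reference_labels == t
            ax.scatter(coords[mask, 0], coords[mask, 1], s=8, alpha=0.6, label=t)
        ax.legend(fontsize=8, markerscale=2)
    else:
        ax.scatter(coords[:, 0], coords[:, 1], s=8, alpha=0.6, color="grey")
    ax.scatter(qx, qy, marker="x", s=90, color="black", label="query")
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.set_title("Reference map with query positions")
    _save(fig, "reference_map")

    # 2. per-type tile probability maps
    T = len(grid.types)
    ncols = min(3, T)
    nrows = -(-T // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3.5 * nrows), squeeze=False)
    extent = (grid.x_min, grid.x_max, grid.y_min, grid.y_max)
    for k, t in enumerate(grid.types):
        ax = axes[k // ncols][k % ncols]
        im = ax.imshow(
            grid.tile_percent[:, :, k].T, origin="lower", extent=extent,
            aspect="auto", cmap="viridis", vmin=0, vmax=100,
        )
        ax.scatter(qx, qy, marker="x", s=60, color="red")
        ax.set_title(t, fontsize=9)
        fig.colorbar(im, ax=ax, label="% of tile")
    for k in range(T, nrows * ncols):
        axes[k // ncols][k % ncols].axis("off")
    fig.suptitle("Per-type tile probability maps")
    _save(fig, "tile_maps")

    # 3. query x type percentage heatmap
    table = reports_to_table(reports, grid)
    mat = table[grid.types].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(1.2 * T + 3, 0.5 * len(reports) + 2))
    im = ax.imshow(mat, cmap="viridis", vmin=0, vmax=100, aspect="auto")
    ax.set_xticks(range(T), grid.types, rotation=45, ha="right", fontsize=8)
    ax.set_yticks(range(len(reports)), [r.sample_id for r in reports], fontsize=8)
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            ax.text(j, i, f"{mat[i, j]:.0f}", ha="center", va="center",
                    color="white" if mat[i, j] < 60 else "black", fontsize=7)
    fig.colorbar(im, ax=ax, label="% of library type in tile")
    ax.set_title("Library-type percentages in each query's tile")
    _save(fig, "type_percent_heatmap")

    tsv = out_dir / "predictions.tsv"
    table.to_csv(tsv, sep="\t", index=False)
    written.append(tsv)
    return written
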