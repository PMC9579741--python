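"""Labelled reference database of composition profiles.

The reference map is trained on a table of labelled libraries, one row
per sample: metadata (sample id, library type, species) plus the 200
composition features (A/C/G/T percentage at each of the first 50 read
positions, N excluded).  Before training, repository-style inclusion
rules are applied: samples tagged 'OTHER' are excluded, library types
with fewer than 25 samples are dropped, and over-represented types are
capped at 500 samples by seeded uniform subsampling so that no single
protocol dominates the map.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import DEFAULT_MAX_POSITIONS, CompositionProfile, to_percentages

logger = logging.getLogger(__name__)

DEFAULT_MIN_PER_TYPE = 25
DEFAULT_CAP_PER_TYPE = 500
EXCLUDED_LABEL = "other"  # compared case-insensitively

_META_COLUMNS = ["sample_id", "library_type", "species"]
FEATURE_BASES = "ACGT"


def feature_names(positions: int = DEFAULT_MAX_POSITIONS) -> list[str]:
    """pos1_A, pos1_C, pos1_G, pos1_T, pos2_A, ... column names."""
    return [f"pos{p + 1}_{b}" for p in range(positions) for b in FEATURE_BASES]


@dataclass
class SampleRecord:
    """One labelled library: metadata plus its composition profile."""

    sample_id: str
    library_type: str
    profile: CompositionProfile
    species: str = ""

    def __post_init__(self) -> None:
        if not self.library_type:
            raise ValueError(f"{self.sample_id}: empty library_type label")


@dataclass
class ReferenceDatabase:
    """Feature table of labelled samples plus the filtering provenance.

    ``table`` has the metadata columns followed by the 200 feature
    columns and ``reads_sampled``.  ``filter_log`` records per-type
    counts before/after filtering and the parameters used.
    """

    table: pd.DataFrame
    filter_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _META_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"database table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def positions(self) -> int:
        return sum(c.endswith("_A") for c in self.table.columns if c.startswith("pos"))

    @property
    def labels(self) -> pd.Series:
        return self.table["library_type"]

    @property
    def library_types(self) -> list[str]:
        return sorted(self.table["library_type"].unique())

    def type_counts(self) -> pd.Series:
        return self.table["library_type"].value_counts()


def database_from_profiles(records: list[SampleRecord]) -> ReferenceDatabase:
    """Build the feature table from labelled composition profiles.

    Zero-coverage positions in individual profiles (all sampled reads
    shorter than the position) are imputed with the database-wide mean
    composition at that position, with a warning; profiles must share L.
    """
    if not records:
        raise ValueError("no records supplied")
    lengths = {r.profile.positions for r in records}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent profile lengths across records: {sorted(lengths)}")
    L = lengths.pop()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pct = np.stack([to_percentages(r.profile, include_n=False) for r in records])
    nan_rows = np.isnan(pct).any(axis=2)
    if nan_rows.any():
        col_mean = np.nanmean(pct, axis=0)  # L x 4 database-wide mean
        if np.isnan(col_mean).any():
            raise ValueError("a position has zero coverage in every profile")
        idx = np.nonzero(nan_rows)
        pct[idx[0], idx[1], :] = col_mean[idx[1], :]
        warnings.warn(
            f"{int(nan_rows.any(axis=1).sum())} profile(s) had zero-coverage "
            "positions imputed with the database-wide mean composition",
            stacklevel=2,
        )
    features = pct.reshape(len(records), 4 * L)
    table = pd.DataFrame(features, columns=feature_names(L))
    table.insert(0, "sample_id", [r.sample_id for r in records])
    table.insert(1, "library_type", [r.library_type for r in records])
    table.insert(2, "species", [r.species for r in records])
    table["reads_sampled"] = [r.profile.reads_sampled for r in records]
    return ReferenceDatabase(table=table)


def filter_database(
    db: ReferenceDatabase | pd.DataFrame,
    min_per_type: int = DEFAULT_MIN_PER_TYPE,
    cap_per_type: int = DEFAULT_CAP_PER_TYPE,
    seed: int = 0,
) -> ReferenceDatabase:
    """Apply the inclusion rules that define the training set.

    Drops 'OTHER'-labelled samples (case-insensitive), drops every
    library type with fewer than ``min_per_type`` samples, and caps
    types above ``cap_per_type`` by a seeded uniform random subset of
    exactly ``cap_per_type``.  Idempotent: re-filtering a filtered
    database changes nothing (a type already at the cap is left as is).
    """
    table = db.table if isinstance(db, ReferenceDatabase) else db
    if len(table) == 0:
        raise ValueError("empty database")
    rng = np.random.default_rng(seed)
    before = table["library_type"].value_counts().to_dict()
    keep = table[table["library_type"].str.casefold() != EXCLUDED_LABEL]
    log: dict = {
        "params": {"min_per_type": min_per_type, "cap_per_type": cap_per_type, "seed": seed},
        "before": {str(k): int(v) for k, v in before.items()},
        "removed_other": int(len(table) - len(keep)),
        "removed_types": [],
        "capped_types": [],
    }
    parts = []
    for lt, group in keep.groupby("library_type", sort=True):
        if len(group) < min_per_type:
            log["removed_types"].append({"library_type": lt, "count": int(len(group))})
            continue
        if len(group) > cap_per_type:
            sel = np.sort(rng.choice(len(group), size=cap_per_type, replace=False))
            group = group.iloc[sel]
            log["capped_types"].append({"library_type": lt, "count": int(len(group))})
        parts.append(group)
    if not parts:
        raise ValueError("all records removed by filtering; database is empty")
    filtered = pd.concat(parts).sort_index().reset_index(drop=True)
    log["after"] = {str(k): int(v) for k, v in filtered["library_type"].value_counts().items()}
    for lt, n in log["before"].items():
        logger.info(
            "filter: %-20s %5d -> %5d", lt, n, log["after"].get(lt, 0)
        )
    return ReferenceDatabase(table=filtered, filter_log=log)


def feature_matrix(db: ReferenceDatabase) -> tuple[np.ndarray, np.ndarray]:
    """(S x 200 feature matrix, length-S label array).

    Row s concatenates, over positions 1..L, the A/C/G/T percentages
    (N excluded), so every 4-block sums to 100.
    """
    cols = feature_names(db.positions)
    missing = [c for c in cols if c not in db.table.columns]
    if missing:
        raise ValueError(f"database table missing feature columns (first: {missing[0]})")
    X = db.table[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN")
    return X, db.table["library_type"].to_numpy()


def profile_features(
    profile: CompositionProfile, fill: np.ndarray | None = None
) -> np.ndarray:
    """Flatten one profile to the 200-feature vector used by the map.

    ``fill`` (L x 4 or flat 4L) supplies percentages for zero-coverage
    positions, typically the reference database mean; without it such a
    profile raises.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pct = to_percentages(profile, include_n=False)
    nan_rows = np.isnan(pct).any(axis=1)
    if nan_rows.any():
        if fill is None:
            raise ValueError(
                f"{profile.sample_id}: zero-coverage positions and no fill "
                "composition available"
            )
        fill = np.asarray(fill, dtype=float).reshape(pct.shape)
        pct[nan_rows] = fill[nan_rows]
        warnings.warn(
            f"{profile.sample_id}: {int(nan_rows.sum())} zero-coverage "
            "position(s) imputed from the reference mean",
            stacklevel=2,
        )
    return pct.reshape(-1)


def save_database(db: ReferenceDatabase, path: str | Path) -> None:
    """TSV with a JSON sidecar (filter log and build parameters)."""
    path = Path(path)
    db.table.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "wt") as fh:
        json.dump({"filter_log": db.filter_log, "n_samples": len(db)}, fh, indent=1)


def load_database(path: str | Path) -> ReferenceDatabase:
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in _META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: header mismatch, missing columns {missing}")
    table["species"] = table["species"].fillna("")
    dupes = table["sample_id"][table["sample_id"].duplicated()].unique()
    if len(dupes):
        warnings.warn(
            f"{path}: duplicate sample_id(s) kept as-is: {', '.join(map(str, dupes[:5]))}",
            stacklevel=2,
        )
    filter_log: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            filter_log = json.load(fh).get("filter_log", {})
    return ReferenceDatabase(table=table, filter_log=filter_log)
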