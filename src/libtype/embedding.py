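"""2-D reference map of library compositions.

The 200-dimensional composition features of the labelled reference
database are embedded into two dimensions with UMAP (n_neighbors=15,
min_dist=8; umap-learn requires min_dist <= spread, so spread defaults
to 10).  Queries are never refit into the map: they are placed by
out-of-sample projection onto the fixed manifold built from the
reference database, so the map a test library is judged against does not
move with the test library.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
import umap

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass
class EmbeddingParams:
    """UMAP parameters of the reference map."""

    n_neighbors: int = 15
    min_dist: float = 8.0
    spread: float = 10.0
    metric: str = "euclidean"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.min_dist > self.spread:
            raise ValueError(
                f"min_dist ({self.min_dist}) must not exceed spread ({self.spread})"
            )


@dataclass
class EmbeddingModel:
    """Fitted reference map: UMAP state plus reference coordinates.

    ``reference_coords`` rows correspond 1:1 to the database rows the
    map was fitted on.  ``feature_means`` is the database-wide mean
    feature vector, used to impute zero-coverage positions in queries.
    """

    params: EmbeddingParams
    reducer: umap.UMAP
    reference_coords: np.ndarray
    reference_labels: np.ndarray | None = None
    feature_means: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return int(self.reducer._raw_data.shape[1])

    def bounding_box(self) -> tuple[float, float, float, float]:
        c = self.reference_coords
        return float(c[:, 0].min()), float(c[:, 0].max()), float(c[:, 1].min()), float(c[:, 1].max())


def fit_reference_map(
    features: np.ndarray,
    params: EmbeddingParams | None = None,
    labels: np.ndarray | None = None,
) -> EmbeddingModel:
    """Fit the 2-D map. Deterministic for a fixed ``params.seed``."""
    params = params or EmbeddingParams()
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D sample x feature matrix")
    if X.shape[0] <= params.n_neighbors:
        raise ValueError(
            f"need more than n_neighbors={params.n_neighbors} samples to fit "
            f"(got {X.shape[0]}); lower n_neighbors or enlarge the database"
        )
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=params.n_neighbors,
        min_dist=params.min_dist,
        spread=params.spread,
        metric=params.metric,
        random_state=params.seed,
    )
    coords = reducer.fit_transform(X)
    if not np.isfinite(coords).all():
        raise RuntimeError("embedding produced non-finite coordinates")
    logger.info(
        "fitted reference map: %d samples, n_neighbors=%d, min_dist=%g, spread=%g, seed=%d",
        X.shape[0], params.n_neighbors, params.min_dist, params.spread, params.seed,
    )
    return EmbeddingModel(
        params=params,
        reducer=reducer,
        reference_coords=np.asarray(coords, dtype=float),
        reference_labels=None if labels is None else np.asarray(labels),
        feature_means=X.mean(axis=0),
    )


def project(model: EmbeddingModel, features: np.ndarray) -> np.ndarray:
    """Out-of-sample projection of query feature vectors onto the map."""
    Q = np.asarray(features, dtype=float)
    if Q.ndim == 1:
        Q = Q[None, :]
    if Q.shape[0] == 0:
        return np.empty((0, 2), dtype=float)
    if Q.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension mismatch: model expects {model.n_features}, got {Q.shape[1]}"
        )
    coords = model.reducer.transform(Q)
    return np.asarray(coords, dtype=float)


def save_model(model: EmbeddingModel, path: str | Path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "params": asdict(model.params),
        "reference_coords": model.reference_coords,
        "reference_labels": model.reference_labels,
        "feature_means": model.feature_means,
        "reducer": model.reducer,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> EmbeddingModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt or foreign file
        raise ValueError(f"{path}: not a readable model file ({exc})") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path}: not a reference-map model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {payload['format_version']} "
            f"not supported (expected {MODEL_FORMAT_VERSION})"
        )
    return EmbeddingModel(
        params=EmbeddingParams(**payload["params"]),
        reducer=payload["reducer"],
        reference_coords=payload["reference_coords"],
        reference_labels=payload["reference_labels"],
        feature_means=payload["feature_means"],
    )
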