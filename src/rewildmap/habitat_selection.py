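"""Habitat-selection modelling from presence / pseudo-absence points.

Each point is characterised by the mean fractional cover of the four
modelled habitats (broadleaf forest, free-standing trees, short grassland,
tall grassland) within a disc whose area equals the species' median
individual range. A seeded bagged-tree ensemble (random forest) is fitted to
presence (1) vs pseudo-absence (0) and predicted onto the 30 m aggregated
cover raster to give a probability-of-presence surface. Discrimination is
summarised by the Mann-Whitney AUC, both resubstitution and 5-fold
cross-validated (the cross-validated figure is the headline, since
resubstitution AUC of a flexible ensemble is near 1 by construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .geodata_io import NODATA_FLOAT, ProportionRaster, SelectionSurface

logger = logging.getLogger("rewildmap")

#: The four habitats entering the selection model, in fixed feature order.
MODELLED_CLASSES = (
    "broadleaf forest",
    "free-standing trees",
    "short grassland",
    "tall grassland",
)


@dataclass
class FeatureRow:
    """Label (presence 1 / pseudo-absence 0) and four cover proportions."""

    label: int
    proportions: np.ndarray  # length 4, order MODELLED_CLASSES

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, float)
        if self.proportions.shape != (len(MODELLED_CLASSES),):
            raise ValueError("proportions must have one entry per modelled class")
        if (self.proportions < -1e-9).any() or self.proportions.sum() > 1 + 1e-6:
            raise ValueError("proportions must be >= 0 with sum <= 1")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class SelectionModel:
    """Fitted forest plus its evaluation metadata."""

    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    n_trees: int
    seed: int
    training_auc: float
    cv_auc: float

    def predict_probability(self, proportions: np.ndarray) -> np.ndarray:
        proportions = np.atleast_2d(np.asarray(proportions, float))
        if proportions.shape[1] != len(self.feature_names):
            raise ValueError(f"expected {len(self.feature_names)} features")
        proba = self.forest.predict_proba(proportions)
        return proba[:, list(self.forest.classes_).index(1)]

    def metadata(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "n_trees": self.n_trees,
            "seed": self.seed,
            "training_auc": self.training_auc,
            "cv_auc": self.cv_auc,
        }


# ---------------------------------------------------------------------------
# AUC (Mann-Whitney formulation)
# ---------------------------------------------------------------------------

def auc(scores, labels) -> float:
    """P(score of a presence > score of an absence) + half the tie mass."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    pos = labels == 1
    neg = labels == 0
    n1, n0 = int(pos.sum()), int(neg.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both presence and absence labels")
    ranks = rankdata(scores)  # average ranks handle ties as half-wins
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


# ---------------------------------------------------------------------------
# Buffer feature extraction
# ---------------------------------------------------------------------------

def extract_buffer_proportions(point: Sequence[float], proportions: ProportionRaster,
                               buffer_area_km2: float) -> np.ndarray:
    """Mean modelled-class cover in a disc of the given area around a point.

    Cells count when their centre falls inside the disc (centre rule);
    NODATA cells are excluded from the mean rather than zero-filled, so
    reserve-edge buffers are not biased toward zero cover.
    """
    if buffer_area_km2 <= 0:
        raise ValueError("buffer_area_km2 must be > 0")
    x, y = float(point[0]), float(point[1])
    grid = proportions.grid
    radius = np.sqrt(buffer_area_km2 * 1e6 / np.pi)

    r0, c0 = grid.index_of(np.array([x]), np.array([y]))
    halo = int(np.ceil(radius / grid.cell_size)) + 1
    rows = np.arange(max(r0[0] - halo, 0), min(r0[0] + halo + 1, grid.n_rows))
    cols = np.arange(max(c0[0] - halo, 0), min(c0[0] + halo + 1, grid.n_cols))
    if rows.size == 0 or cols.size == 0:
        raise ValueError("point lies outside the raster extent")
    cx = grid.origin_x + (cols + 0.5) * grid.cell_size
    cy = grid.origin_y - (rows + 0.5) * grid.cell_size
    CX, CY = np.meshgrid(cx, cy)
    in_disc = (CX - x) ** 2 + (CY - y) ** 2 <= radius ** 2
    sub_nodata = proportions.nodata_mask[np.ix_(rows, cols)]
    use = in_disc & ~sub_nodata
    if not use.any():
        raise ValueError("no usable cell centre falls inside the buffer disc")
    out = np.empty(len(MODELLED_CLASSES))
    for i, name in enumerate(MODELLED_CLASSES):
        band = proportions.band(name)[np.ix_(rows, cols)]
        out[i] = band[use].mean()
    return out


def build_training_set(presences: np.ndarray, pseudo_absences: np.ndarray,
                       proportions: ProportionRaster,
                       buffer_area_km2: float) -> pd.DataFrame:
    """One labelled feature row per point; identical buffer for both classes."""
    presences = np.asarray(presences, float).reshape(-1, 2)
    pseudo_absences = np.asarray(pseudo_absences, float).reshape(-1, 2)
    if len(presences) == 0 or len(pseudo_absences) == 0:
        raise ValueError("both presence and pseudo-absence sets must be non-empty")
    rows = []
    for label, pts in ((1, presences), (0, pseudo_absences)):
        for p in pts:
            feats = extract_buffer_proportions(p, proportions, buffer_area_km2)
            rows.append([label, *feats])
    return pd.DataFrame(rows, columns=["label", *MODELLED_CLASSES])


# ---------------------------------------------------------------------------
# Model fitting and prediction
# ---------------------------------------------------------------------------

def fit_selection_model(rows: pd.DataFrame, n_trees: int = 500,
                        seed: int = 0) -> SelectionModel:
    """Fit the presence/pseudo-absence forest; deterministic given seed.

    Stores both resubstitution AUC and 5-fold cross-validated AUC.
    """
    y = rows["label"].to_numpy(int)
    X = rows[list(MODELLED_CLASSES)].to_numpy(float)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data must contain both labels")
    if counts.min() < 10:
        raise ValueError("need at least 10 rows per label")

    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(X, y)
    model = SelectionModel(forest, MODELLED_CLASSES, n_trees, seed,
                           training_auc=float("nan"), cv_auc=float("nan"))
    model.training_auc = auc(model.predict_probability(X), y)

    cv_scores = np.empty(len(y))
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        f = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
        f.fit(X[tr], y[tr])
        cv_scores[te] = f.predict_proba(X[te])[:, list(f.classes_).index(1)]
    model.cv_auc = auc(cv_scores, y)
    logger.info("selection model: training AUC=%.3f, 5-fold CV AUC=%.3f (n=%d)",
                model.training_auc, model.cv_auc, len(y))
    return model


def predict_surface(model: SelectionModel, aggregated: ProportionRaster,
                    species: str = "") -> SelectionSurface:
    """Predict per-cell probability of presence on the aggregated raster."""
    for name in MODELLED_CLASSES:
        if name not in aggregated.catalogue.names:
            raise ValueError(f"aggregated raster lacks modelled class {name!r}")
    grid = aggregated.grid
    prob = np.full(grid.shape, NODATA_FLOAT)
    valid = ~aggregated.nodata_mask
    if valid.any():
        X = np.column_stack([aggregated.band(n)[valid] for n in MODELLED_CLASSES])
        prob[valid] = model.predict_probability(X)
    return SelectionSurface(grid, prob, species=species)
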