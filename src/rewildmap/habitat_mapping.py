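"""Two-step land-cover mapping.

Step one trains a multilayer-perceptron pixel classifier on hand-labelled
training pixels of fine-resolution imagery. Step two aggregates the fine
classification onto a coarser grid as fractional cover and trains a
regressor that predicts those per-class cover fractions from the coarse
imagery's bands, so the fine-scale classification can be extended to areas
only covered by the coarse imagery. Evaluation uses overall accuracy and
Cohen's kappa for the classifier, and r² (overall and per class) for the
fractional-cover regressor, all on a held-out validation split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.preprocessing import StandardScaler

from .geodata_io import (
    NODATA_FLOAT,
    NODATA_LABEL,
    ClassCatalogue,
    GridSpec,
    HabitatMap,
    ProportionRaster,
)

logger = logging.getLogger("rewildmap")


@dataclass
class SpectralImage:
    """Multi-band reflectance raster; bands first, NODATA_FLOAT cells allowed."""

    grid: GridSpec
    bands: np.ndarray  # float (n_bands, n_rows, n_cols)

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, float)
        if self.bands.ndim != 3 or self.bands.shape[1:] != self.grid.shape:
            raise ValueError("bands must be (n_bands, n_rows, n_cols)")
        valid = ~self.nodata_mask
        if valid.any() and not np.isfinite(self.bands[:, valid]).all():
            raise ValueError("band values must be finite")

    @property
    def n_bands(self) -> int:
        return self.bands.shape[0]

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.any(self.bands == NODATA_FLOAT, axis=0)


@dataclass
class ClassifierConfig:
    """Network architecture and training schedule for both mapping steps.

    Defaults follow the fine step (two 100-neuron layers, 100 epochs, batch
    1000); :meth:`coarse` gives the fractional-cover defaults (200 neurons,
    200 epochs, batch 10000). ``dropout_rate`` is kept as the regularisation
    knob and mapped onto L2 weight decay in the MLP backend.
    """

    hidden_layers: int = 2
    neurons_per_layer: int = 100
    dropout_rate: float = 0.1
    epochs: int = 100
    batch_size: int = 1000
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")

    @classmethod
    def coarse(cls, seed: int = 0) -> "ClassifierConfig":
        return cls(neurons_per_layer=200, epochs=200, batch_size=10000, seed=seed)

    def _mlp_kwargs(self) -> dict:
        return dict(
            hidden_layer_sizes=(self.neurons_per_layer,) * self.hidden_layers,
            alpha=max(self.dropout_rate * 1e-3, 1e-6),
            max_iter=self.epochs,
            batch_size=self.batch_size,
            random_state=self.seed,
            early_stopping=False,
        )


@dataclass
class FitReport:
    overall_accuracy: float | None = None
    kappa: float | None = None
    r2_overall: float | None = None
    r2_per_class: Mapping[str, float] = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "kappa": self.kappa,
            "r2_overall": self.r2_overall,
            "r2_per_class": dict(self.r2_per_class),
        }


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------

def overall_accuracy(predicted, observed) -> float:
    """Fraction of labels that agree."""
    predicted = np.asarray(predicted)
    observed = np.asarray(observed)
    if predicted.shape != observed.shape or predicted.size == 0:
        raise ValueError("label vectors must be non-empty and equally long")
    return float(np.mean(predicted == observed))


def cohens_kappa(predicted, observed) -> float:
    """Chance-corrected agreement: (p_o - p_e) / (1 - p_e).

    ``p_e`` comes from the marginal products of the confusion matrix.
    Perfect agreement with degenerate marginals (p_e = 1) returns 1.0.
    """
    predicted = np.asarray(predicted)
    observed = np.asarray(observed)
    if predicted.shape != observed.shape or predicted.size == 0:
        raise ValueError("label vectors must be non-empty and equally long")
    cats, pred_idx = np.unique(predicted, return_inverse=True)
    cats2, obs_idx = np.unique(observed, return_inverse=True)
    all_cats = np.unique(np.concatenate([cats, cats2]))
    k = len(all_cats)
    pi = np.searchsorted(all_cats, predicted)
    oi = np.searchsorted(all_cats, observed)
    cm = np.zeros((k, k))
    np.add.at(cm, (pi, oi), 1)
    n = cm.sum()
    p_o = np.trace(cm) / n
    p_e = float(np.sum(cm.sum(axis=0) * cm.sum(axis=1)) / n**2)
    if np.isclose(p_e, 1.0):
        return 1.0 if np.isclose(p_o, 1.0) else 0.0
    return float((p_o - p_e) / (1 - p_e))


def r_squared(predicted, observed) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    Undefined (NaN, with a warning) when the observations have no variance.
    """
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if predicted.shape != observed.shape or predicted.size < 2:
        raise ValueError("need >= 2 paired values of equal length")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("r_squared undefined: observed values have zero variance")
        return float("nan")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# Training-pixel balancing
# ---------------------------------------------------------------------------

def balance_training_pixels(labels, features, seed: int = 0):
    """Resample every class to the median original class count.

    Classes above the median are downsampled without replacement; classes
    below it upsampled with replacement. Deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    features = np.asarray(features, float)
    if len(labels) != len(features):
        raise ValueError("labels and features must align")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes to balance")
    if (counts == 0).any():
        raise ValueError("a class with zero examples cannot be balanced")
    target = int(np.median(counts))
    rng = np.random.default_rng(seed)
    keep = []
    for cls, cnt in zip(classes, counts):
        idx = np.flatnonzero(labels == cls)
        if cnt == target:
            keep.append(idx)
        else:
            keep.append(rng.choice(idx, size=target, replace=cnt < target))
    keep = np.concatenate(keep)
    return labels[keep], features[keep]


# ---------------------------------------------------------------------------
# Step one: fine-resolution pixel classifier
# ---------------------------------------------------------------------------

class FineClassifier:
    """Pixel classifier over band vectors, probability (softmax) output."""

    def __init__(self, model: MLPClassifier, scaler: StandardScaler,
                 catalogue: ClassCatalogue, n_bands: int, report: FitReport):
        self._model = model
        self._scaler = scaler
        self.catalogue = catalogue
        self.n_bands = n_bands
        self.report = report

    def predict_proba(self, band_vectors: np.ndarray) -> np.ndarray:
        """Per-class probabilities, columns in catalogue order (sum to 1)."""
        band_vectors = np.atleast_2d(np.asarray(band_vectors, float))
        if band_vectors.shape[1] != self.n_bands:
            raise ValueError(
                f"expected {self.n_bands} bands, got {band_vectors.shape[1]}"
            )
        proba = self._model.predict_proba(self._scaler.transform(band_vectors))
        out = np.zeros((len(band_vectors), len(self.catalogue)))
        out[:, self._model.classes_] = proba
        return out


def fit_fine_classifier(image: SpectralImage, training_pixels, config: ClassifierConfig
                        , catalogue: ClassCatalogue | None = None) -> FineClassifier:
    """Train the fine-step pixel classifier.

    ``training_pixels`` is (labels, rows, cols) or (labels, features): class
    indices plus either pixel indices into ``image`` or band vectors directly.
    Pixels are class-balanced, centred and scaled; ``validation_fraction`` of
    the balanced pixels is held out (stratified) for the FitReport.
    """
    catalogue = catalogue or ClassCatalogue()
    if len(training_pixels) == 3:
        labels, rows, cols = (np.asarray(a) for a in training_pixels)
        features = image.bands[:, rows, cols].T
    else:
        labels, features = (np.asarray(a) for a in training_pixels)
    if features.shape[1] != image.n_bands:
        raise ValueError("training feature width does not match image bands")

    labels, features = balance_training_pixels(labels, features, seed=config.seed)
    _, per_class = np.unique(labels, return_counts=True)
    if per_class.min() < 10:
        raise ValueError("fewer than 10 pixels per class after balancing")

    Xtr, Xval, ytr, yval = train_test_split(
        features, labels, test_size=config.validation_fraction,
        stratify=labels, random_state=config.seed,
    )
    scaler = StandardScaler().fit(Xtr)
    model = MLPClassifier(**config._mlp_kwargs())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(scaler.transform(Xtr), ytr)
    yhat = model.predict(scaler.transform(Xval))
    report = FitReport(
        overall_accuracy=overall_accuracy(yhat, yval),
        kappa=cohens_kappa(yhat, yval),
    )
    logger.info("fine classifier: accuracy=%.3f kappa=%.3f on %d held-out pixels",
                report.overall_accuracy, report.kappa, len(yval))
    return FineClassifier(model, scaler, catalogue, image.n_bands, report)


def classify_fine(classifier: FineClassifier, image: SpectralImage) -> HabitatMap:
    """Argmax classification of every non-NODATA pixel.

    Probability ties resolve to the lowest catalogue index.
    """
    if image.n_bands != classifier.n_bands:
        raise ValueError("band count differs from the classifier's training data")
    labels = np.full(image.grid.shape, NODATA_LABEL, dtype=np.int64)
    valid = ~image.nodata_mask
    if valid.any():
        proba = classifier.predict_proba(image.bands[:, valid].T)
        labels[valid] = np.argmax(proba, axis=1)  # np.argmax takes first max: lowest index
    return HabitatMap(image.grid, labels, classifier.catalogue)


# ---------------------------------------------------------------------------
# Aggregation to fractional cover
# ---------------------------------------------------------------------------

def aggregate_proportions(fine: HabitatMap, factor: int) -> ProportionRaster:
    """Aggregate a fine label map into per-class cover fractions.

    Each coarse cell covers a ``factor``×``factor`` block of fine cells; its
    vector is the class frequency among the block's non-NODATA cells. A coarse
    cell is NODATA iff more than half of its fine cells are NODATA. Trailing
    partial blocks are dropped with a warning.
    """
    if factor < 1:
        raise ValueError("aggregation factor must be a positive integer")
    nr, nc = fine.grid.shape
    cr, cc = nr // factor, nc // factor
    if cr == 0 or cc == 0:
        raise ValueError("grid smaller than one aggregation block")
    if nr % factor or nc % factor:
        logger.warning("aggregate_proportions: dropping trailing partial blocks "
                       "(%d rows, %d cols)", nr % factor, nc % factor)
    labels = fine.labels[: cr * factor, : cc * factor]
    blocks = labels.reshape(cr, factor, cc, factor).swapaxes(1, 2).reshape(cr, cc, factor * factor)

    n_classes = len(fine.catalogue)
    fracs = np.full((n_classes, cr, cc), NODATA_FLOAT)
    valid_counts = np.sum(blocks != NODATA_LABEL, axis=2)
    usable = valid_counts > factor * factor / 2
    counts = np.stack([np.sum(blocks == k, axis=2) for k in range(n_classes)])
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_all = counts / valid_counts
    for k in range(n_classes):
        fracs[k][usable] = frac_all[k][usable]

    coarse_grid = GridSpec(
        origin_x=fine.grid.origin_x,
        origin_y=fine.grid.origin_y,
        cell_size=fine.grid.cell_size * factor,
        n_rows=cr,
        n_cols=cc,
        epsg=fine.grid.epsg,
    )
    return ProportionRaster(coarse_grid, fracs, fine.catalogue)


# ---------------------------------------------------------------------------
# Step two: coarse fractional-cover regressor
# ---------------------------------------------------------------------------

class ProportionRegressor:
    """Maps a coarse band vector to a per-class cover simplex."""

    def __init__(self, model: MLPRegressor, scaler: StandardScaler,
                 catalogue: ClassCatalogue, n_bands: int, report: FitReport):
        self._model = model
        self._scaler = scaler
        self.catalogue = catalogue
        self.n_bands = n_bands
        self.report = report

    def predict(self, band_vectors: np.ndarray) -> np.ndarray:
        """Predicted cover fractions (rows sum to 1, entries >= 0)."""
        band_vectors = np.atleast_2d(np.asarray(band_vectors, float))
        if band_vectors.shape[1] != self.n_bands:
            raise ValueError(f"expected {self.n_bands} bands")
        raw = self._model.predict(self._scaler.transform(band_vectors))
        raw = np.clip(np.atleast_2d(raw), 0.0, None)
        sums = raw.sum(axis=1, keepdims=True)
        flat = sums[:, 0] <= 0
        raw[flat] = 1.0 / raw.shape[1]  # uninformative prediction falls back to uniform
        sums[flat] = raw.shape[1] * (1.0 / raw.shape[1])
        return raw / raw.sum(axis=1, keepdims=True)

    def predict_raster(self, image: SpectralImage) -> ProportionRaster:
        fracs = np.full((len(self.catalogue),) + image.grid.shape, NODATA_FLOAT)
        valid = ~image.nodata_mask
        if valid.any():
            pred = self.predict(image.bands[:, valid].T)
            for k in range(len(self.catalogue)):
                fracs[k][valid] = pred[:, k]
        return ProportionRaster(image.grid, fracs, self.catalogue)


def fit_proportion_regressor(coarse_image: SpectralImage,
                             target_proportions: ProportionRaster,
                             config: ClassifierConfig | None = None) -> ProportionRegressor:
    """Train the coarse-step fractional-cover regressor.

    Targets are per-cell cover simplices (from :func:`aggregate_proportions`
    of the fine classification over the coarse grid). 20% of cells (by
    ``validation_fraction``) are held out; the FitReport carries the overall
    and per-class r² there. A class with zero target variance gets NaN r²
    with a warning.
    """
    config = config or ClassifierConfig.coarse()
    if coarse_image.grid.shape != target_proportions.grid.shape:
        raise ValueError("image and target grids do not match")
    valid = ~(coarse_image.nodata_mask | target_proportions.nodata_mask)
    X = coarse_image.bands[:, valid].T
    Y = target_proportions.fractions[:, valid].T
    idx = np.arange(len(X))
    itr, ival = train_test_split(idx, test_size=config.validation_fraction,
                                 random_state=config.seed)
    scaler = StandardScaler().fit(X[itr])
    model = MLPRegressor(**config._mlp_kwargs())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(scaler.transform(X[itr]), Y[itr])

    reg = ProportionRegressor(model, scaler, target_proportions.catalogue,
                              coarse_image.n_bands, FitReport())
    Yhat = reg.predict(X[ival])
    report = reg.report
    report.r2_overall = r_squared(Yhat.ravel(), Y[ival].ravel())
    per_class = {}
    for k, name in enumerate(target_proportions.catalogue.names):
        obs = Y[ival][:, k]
        if np.ptp(obs) == 0:
            warnings.warn(f"per-class r2 undefined for constant class {name!r}")
            per_class[name] = float("nan")
        else:
            per_class[name] = r_squared(Yhat[:, k], obs)
    report.r2_per_class = per_class
    logger.info("proportion regressor: overall r2=%.3f on %d held-out cells",
                report.r2_overall, len(ival))
    return reg
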