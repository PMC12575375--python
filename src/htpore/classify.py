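"""Random-forest pixel classification of HT slices.

A 200-tree random forest assigns each pixel of a feature stack to one of
four classes (background, circular pore-like structure, nucleus, nucleolus).
The pore class gets a dedicated probability threshold, calibrated on a
validation set by maximizing the F1 score of pore detection; nucleus and
nucleolus masks come from the per-pixel argmax. Performance is reported as
one-vs-rest ROC curves and AUROCs per class, mirroring how trainable
pixel-segmentation tools are benchmarked.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.utils.validation import check_is_fitted

from .features import FeatureConfig, FeatureStack
from .stack_io import CLASS_CODES, GroundTruthMask

PORE_CLASS = 1


@dataclasses.dataclass
class TrainingSet:
    """Feature stacks paired with ground-truth masks, with a declared role."""

    items: list[tuple[FeatureStack, GroundTruthMask]]
    role: Literal["train", "validate", "test"]

    def __post_init__(self) -> None:
        names = {tuple(fs.names) for fs, _ in self.items}
        if len(names) > 1:
            raise ValueError("all items must share one feature configuration")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten all items into (n_pixels, n_features) X and labels y."""
        xs, ys = [], []
        for fs, mask in self.items:
            if fs.values.shape[1:] != mask.labels.shape:
                raise ValueError(
                    f"feature/label shape mismatch: {fs.values.shape[1:]} "
                    f"vs {mask.labels.shape}"
                )
            xs.append(fs.as_table())
            ys.append(mask.labels.ravel())
        return np.concatenate(xs), np.concatenate(ys)

    @property
    def n_structures(self) -> int:
        """Number of annotated circular structures (connected pore regions)."""
        from scipy import ndimage as ndi

        total = 0
        for _, mask in self.items:
            _, n = ndi.label(mask.labels == PORE_CLASS, structure=np.ones((3, 3)))
            total += n
        return total


class PixelClassifier(BaseEstimator, ClassifierMixin):
    """Multiclass random-forest pixel classifier with a calibrated pore threshold.

    scikit-learn estimator over flattened pixel tables: ``X`` has shape
    (n_pixels, n_features), ``y`` holds the class codes of
    :data:`~htpore.stack_io.CLASS_CODES`. Background pixels are subsampled
    (seeded) when they outnumber the rarest annotated class by more than
    ``max_imbalance``:1, which keeps forests tractable on large fields
    without touching the annotated classes.

    Attributes set by :meth:`fit` carry the usual trailing underscore;
    :meth:`calibrate_threshold` adds ``pore_threshold_``.
    """

    def __init__(
        self,
        n_estimators: int = 200,
        random_state: int | None = 0,
        max_imbalance: float = 50.0,
    ):
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.max_imbalance = max_imbalance

    # -- core sklearn surface ------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n_pixels, n_features) aligned with y")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training set contains a single class")
        keep = np.ones(len(y), dtype=bool)
        nonbg = counts[classes != 0]
        if 0 in classes and nonbg.size:
            n_bg = int(counts[classes == 0][0])
            cap = int(self.max_imbalance * nonbg.min())
            if n_bg > cap:
                rng = np.random.default_rng(self.random_state)
                bg_idx = np.flatnonzero(y == 0)
                drop = rng.choice(bg_idx, size=n_bg - cap, replace=False)
                keep[drop] = False
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            random_state=self.random_state,
            n_jobs=1,
        )
        self.forest_.fit(X[keep], y[keep])
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(np.asarray(X))

    def predict(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict(np.asarray(X))

    def pore_proba(self, X) -> np.ndarray:
        """Probability of the circular-structure class per pixel."""
        proba = self.predict_proba(X)
        if PORE_CLASS not in self.classes_:
            raise ValueError("model was trained without the pore class")
        return proba[:, list(self.classes_).index(PORE_CLASS)]

    def calibrate_threshold(self, X_val, y_val, grid_step: float = 0.01) -> float:
        """Pick the pore probability threshold maximizing pixelwise F1.

        The grid runs over {grid_step, 2*grid_step, ..., < 1}; among
        F1-maximizing grid points the lowest is returned and stored as
        ``pore_threshold_``. Positive prediction is ``proba >= t``.
        """
        y_val = np.asarray(y_val)
        truth = y_val == PORE_CLASS
        if not truth.any():
            raise ValueError("no positive pixels: validation set has no pore pixels")
        proba = self.pore_proba(X_val)
        self.pore_threshold_ = _best_f1_threshold(proba, truth, grid_step)
        return self.pore_threshold_


def _best_f1_threshold(proba: np.ndarray, truth: np.ndarray, grid_step: float) -> float:
    n_steps = int(round(1.0 / grid_step)) - 1
    grid = np.round(np.arange(1, n_steps + 1) * grid_step, 10)
    best_t, best_f1 = grid[0], -1.0
    n_pos = truth.sum()
    for t in grid:
        pred = proba >= t
        tp = np.count_nonzero(pred & truth)
        denom = pred.sum() + n_pos
        f1 = 2.0 * tp / denom if denom else 0.0
        if f1 > best_f1 + 1e-12:
            best_f1, best_t = f1, t
    return float(best_t)


# -- feature-stack level API -------------------------------------------------


@dataclasses.dataclass
class PredictionMaps:
    proba: np.ndarray  # (n_classes, y, x) in order of model.classes_
    classes: np.ndarray
    pore_mask: np.ndarray  # proba_pore >= pore_threshold_
    nucleus_mask: np.ndarray  # argmax class == nucleus
    nucleolus_mask: np.ndarray  # argmax class == nucleolus


@dataclasses.dataclass
class EvalReport:
    roc: dict[int, tuple[np.ndarray, np.ndarray]]  # class -> (fpr, tpr)
    auroc: dict[int, float]  # NaN when the class is absent from the truth
    f1_pore: float
    confusion: np.ndarray

    def to_dict(self) -> dict:
        return {
            "auroc": {CLASS_CODES[c]: v for c, v in self.auroc.items()},
            "f1_pore": self.f1_pore,
            "roc": {
                CLASS_CODES[c]: {"fpr": f.tolist(), "tpr": t.tolist()}
                for c, (f, t) in self.roc.items()
            },
            "confusion": self.confusion.tolist(),
        }


def train(
    training: TrainingSet,
    n_estimators: int = 200,
    seed: int = 0,
    feature_config: FeatureConfig | None = None,
) -> PixelClassifier:
    """Train the pixel classifier on a training set of annotated slices."""
    if not training.items:
        raise ValueError("empty training set")
    if training.role != "train":
        raise ValueError("training requires a TrainingSet with role='train'")
    X, y = training.as_arrays()
    model = PixelClassifier(n_estimators=n_estimators, random_state=seed)
    model.fit(X, y)
    model.feature_config = feature_config or training.items[0][0].config_echo
    model.feature_names_ = list(training.items[0][0].names)
    model.class_codes = dict(CLASS_CODES)
    return model


def calibrate_threshold(
    model: PixelClassifier, validation: TrainingSet, grid_step: float = 0.01
) -> float:
    if validation.role != "validate":
        raise ValueError("calibration requires role='validate'")
    _check_features(model, validation.items[0][0])
    X, y = validation.as_arrays()
    return model.calibrate_threshold(X, y, grid_step=grid_step)


def _check_features(model: PixelClassifier, fs: FeatureStack) -> None:
    if list(fs.names) != list(model.feature_names_):
        raise ValueError(
            "feature stack does not match the model's feature configuration"
        )


def predict(model: PixelClassifier, features: FeatureStack) -> PredictionMaps:
    """Per-class probability maps plus the thresholded pore mask.

    Requires a calibrated model (``pore_threshold_`` set); nucleus and
    nucleolus masks come from the per-pixel argmax over all classes.
    """
    if not hasattr(model, "pore_threshold_"):
        raise ValueError("uncalibrated model: run calibrate_threshold first")
    _check_features(model, features)
    shape = features.values.shape[1:]
    proba_flat = model.predict_proba(features.as_table())
    proba = proba_flat.T.reshape(len(model.classes_), *shape)
    classes = np.asarray(model.classes_)
    pore_idx = list(classes).index(PORE_CLASS)
    argmax_class = classes[np.argmax(proba, axis=0)]
    return PredictionMaps(
        proba=proba,
        classes=classes,
        pore_mask=proba[pore_idx] >= model.pore_threshold_,
        nucleus_mask=argmax_class == 2,
        nucleolus_mask=argmax_class == 3,
    )


def roc_auroc(scores: np.ndarray, truth: np.ndarray):
    """One-vs-rest ROC by threshold sweep and its trapezoidal area."""
    fpr, tpr, _ = roc_curve(truth.astype(int), scores)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def evaluate(model: PixelClassifier, test: TrainingSet) -> EvalReport:
    """One-vs-rest ROC/AUROC per annotated class and pore F1 on a test set.

    A class absent from the test truth gets AUROC = NaN (undefined), never 0.
    """
    if test.role != "test":
        raise ValueError("evaluation requires role='test'")
    _check_features(model, test.items[0][0])
    X, y = test.as_arrays()
    proba = model.predict_proba(X)
    classes = list(model.classes_)
    roc: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    auroc: dict[int, float] = {}
    for c in (1, 2, 3):
        if c not in classes:
            auroc[c] = float("nan")
            continue
        truth = y == c
        if truth.all() or not truth.any():
            auroc[c] = float("nan")
            continue
        scores = proba[:, classes.index(c)]
        fpr, tpr, a = roc_auroc(scores, truth)
        roc[c] = (fpr, tpr)
        auroc[c] = a
    # pore F1 at the calibrated threshold, if calibrated
    f1 = float("nan")
    if hasattr(model, "pore_threshold_") and PORE_CLASS in classes:
        pred = proba[:, classes.index(PORE_CLASS)] >= model.pore_threshold_
        truth = y == PORE_CLASS
        tp = np.count_nonzero(pred & truth)
        denom = pred.sum() + truth.sum()
        f1 = 2.0 * tp / denom if denom else float("nan")
    n_cls = len(classes)
    pred_class = model.forest_.predict(X)
    confusion = np.zeros((n_cls, n_cls), dtype=int)
    for i, ci in enumerate(classes):
        for j, cj in enumerate(classes):
            confusion[i, j] = np.count_nonzero((y == ci) & (pred_class == cj))
    return EvalReport(roc=roc, auroc=auroc, f1_pore=f1, confusion=confusion)
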