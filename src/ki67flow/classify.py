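"""Tumour vs non-tumour nucleus classification and Ki-67 positivity.

A two-class ensemble of randomized decision trees separates epithelial
tumour nuclei from everything else (stromal nuclei, lymphocytes) using
the measured morphology and staining features, including their spatial
smoothed variants.  The train/test split is "equally spaced": every
k-th object (by list index) is held out, k chosen to give the requested
training fraction, the offset rotating with the seed.

Ki-67 positivity is a fixed threshold on the raw mean nuclear DAB
optical density (``nucleus_dab_od_mean >= 0.15`` by default), applied to
every detection; restricting to tumour nuclei happens downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .detect import NucleusDetection

__all__ = [
    "ClassifierModel",
    "PositivityRule",
    "train_classifier",
    "classify_nuclei",
    "call_positivity",
    "augment_training",
    "feature_matrix",
    "save_model",
    "load_model",
]

TUMOUR = "tumour"
OTHER = "other"


@dataclass(frozen=True)
class PositivityRule:
    """Threshold rule for Ki-67 positivity (inclusive >=)."""

    feature: str = "nucleus_dab_od_mean"
    threshold: float = 0.15

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class ClassifierModel:
    """Trained tumour/non-tumour ensemble with its training state."""

    estimator: RandomForestClassifier
    feature_names: list[str]
    n_objects: int
    split_fraction: float
    seed: int
    holdout_accuracy: float
    training_X: np.ndarray = field(repr=False, default=None)
    training_y: np.ndarray = field(repr=False, default=None)


def _default_feature_names(det: NucleusDetection) -> list[str]:
    names = [n for n in sorted(det.features)
             if n not in ("valid", "nucleus_dab_od_mean")]
    names += [f"{n}|smoothed{r:g}" for (n, r) in sorted(det.smoothed)]
    return names


def feature_matrix(detections, feature_names=None):
    """Numeric (n, p) matrix in a fixed feature order.

    Raises ``KeyError`` naming the first feature a detection lacks.
    """
    if feature_names is None:
        feature_names = _default_feature_names(detections[0])
    rows = np.empty((len(detections), len(feature_names)))
    for i, det in enumerate(detections):
        for j, name in enumerate(feature_names):
            if "|smoothed" in name:
                base, r = name.split("|smoothed")
                key = (base, float(r))
                if key not in det.smoothed:
                    raise KeyError(f"detection {det.id} lacks feature {name}")
                rows[i, j] = det.smoothed[key]
            else:
                if name not in det.features:
                    raise KeyError(f"detection {det.id} lacks feature {name}")
                rows[i, j] = det.features[name]
    return np.nan_to_num(rows, nan=0.0), list(feature_names)


def _equally_spaced_split(n: int, split_fraction: float, seed: int):
    """Train/test index split: every k-th object is a test object."""
    k = max(2, int(round(1.0 / (1.0 - split_fraction))))
    offset = seed % k
    idx = np.arange(n)
    test = idx[offset::k]
    train = np.setdiff1d(idx, test)
    return train, test


def train_classifier(labeled_detections, split_fraction: float = 0.67,
                     seed: int = 0, feature_names=None,
                     n_estimators: int = 200) -> ClassifierModel:
    """Train the two-class ensemble on labeled detections.

    Labels come from ``class_label`` ("tumour" vs anything else).
    Deterministic given the seed; held-out accuracy is stored.
    """
    if len(labeled_detections) < 100:
        raise ValueError("need at least 100 labeled objects")
    y = np.asarray([1 if d.class_label == TUMOUR else 0
                    for d in labeled_detections])
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    X, feature_names = feature_matrix(labeled_detections, feature_names)
    train_idx, test_idx = _equally_spaced_split(len(y), split_fraction, seed)
    est = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                 n_jobs=1)
    est.fit(X[train_idx], y[train_idx])
    acc = float((est.predict(X[test_idx]) == y[test_idx]).mean())
    return ClassifierModel(
        estimator=est, feature_names=feature_names, n_objects=len(y),
        split_fraction=split_fraction, seed=seed, holdout_accuracy=acc,
        training_X=X, training_y=y)


def classify_nuclei(model: ClassifierModel, detections):
    """Label every detection tumour/other with the trained model."""
    if not detections:
        return detections
    X, _ = feature_matrix(detections, model.feature_names)
    pred = model.estimator.predict(X)
    for det, p in zip(detections, pred):
        det.class_label = TUMOUR if p == 1 else OTHER
    return detections


def call_positivity(detections, rule: PositivityRule | None = None):
    """Flag Ki-67 positivity on all detections (class-agnostic)."""
    if rule is None:
        rule = PositivityRule()
    for det in detections:
        if rule.feature in det.features:
            value = det.features[rule.feature]
        else:
            raise KeyError(
                f"detection {det.id} lacks feature {rule.feature}")
        det.ki67_positive = bool(value >= rule.threshold)
    return detections


def save_model(model: ClassifierModel, path) -> None:
    """Serialize the model (estimator + metadata) to one archive file."""
    import joblib

    joblib.dump(model, path)


def load_model(path) -> ClassifierModel:
    import joblib

    model = joblib.load(path)
    if not isinstance(model, ClassifierModel):
        raise ValueError(f"{path} does not contain a ClassifierModel")
    return model


def augment_training(model: ClassifierModel,
                     new_labeled_detections) -> ClassifierModel:
    """Retrain on the union of stored and new training objects."""
    if not new_labeled_detections:
        X = model.training_X
        y = model.training_y
    else:
        X_new, _ = feature_matrix(new_labeled_detections,
                                  model.feature_names)
        y_new = np.asarray([1 if d.class_label == TUMOUR else 0
                            for d in new_labeled_detections])
        X = np.vstack([model.training_X, X_new])
        y = np.concatenate([model.training_y, y_new])
    train_idx, test_idx = _equally_spaced_split(len(y), model.split_fraction,
                                                model.seed)
    est = RandomForestClassifier(
        n_estimators=model.estimator.n_estimators,
        random_state=model.seed, n_jobs=1)
    est.fit(X[train_idx], y[train_idx])
    acc = float((est.predict(X[test_idx]) == y[test_idx]).mean())
    return ClassifierModel(
        estimator=est, feature_names=list(model.feature_names),
        n_objects=len(y), split_fraction=model.split_fraction,
        seed=model.seed, holdout_accuracy=acc, training_X=X, training_y=y)
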