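"""Layer-1 classifier bank: 31 independent six-class AU-intensity classifiers.

Each catalog AU gets its own multiclass classifier mapping a 72-dimensional
nonrigid facial feature vector to one of the six intensity levels O..E.
The default classifier is a linear max-margin model with one-vs-one
multiclass decomposition (scikit-learn's SVC), preceded by feature
standardization fitted on the training data.  A linear kernel is the
right bias here: each AU's intensity is encoded along its own direction
of feature space, so the discriminants are hyperplanes, and an isotropic
radial kernel cannot ignore the thirty other AUs' interfering directions.
The classifier family is pluggable via a factory for other feature
geometries.

The stage that derives the 72 features from images (AAM fitting) is out of
scope; callers — in practice the synthetic generator — supply the feature
vectors directly.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .levels import AU_CATALOG, IntensityLevel, N_AUS
from .matrix import AUFrame

logger = logging.getLogger(__name__)

N_FEATURES = 72


def default_classifier_factory(seed: int) -> BaseEstimator:
    """StandardScaler + linear SVC with one-vs-one decomposition."""
    return make_pipeline(
        StandardScaler(),
        SVC(kernel="linear", C=10.0, random_state=seed),
    )


class _ConstantLevel(BaseEstimator):
    """Degenerate predictor for AUs observed at a single level."""

    def __init__(self, level: int) -> None:
        self.level = int(level)

    def fit(self, X, y):  # noqa: D102 - sklearn protocol
        return self

    def predict(self, X):
        return np.full(len(X), self.level)


def _validate_features(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != N_FEATURES:
        raise ValueError(
            f"feature vectors must have length {N_FEATURES}, "
            f"got {X.shape[1]}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("feature vectors must be finite")
    return X


class ClassifierBank:
    """A fitted bank of 31 per-AU intensity classifiers."""

    def __init__(self, classifiers: dict[str, BaseEstimator], fps: float = 30.0):
        self.classifiers = classifiers
        self.fps = fps

    def classify(self, X) -> np.ndarray:
        """Predict intensity levels for (n, 72) features; returns (n, 31) ints."""
        X = _validate_features(X)
        out = np.empty((len(X), N_AUS), dtype=int)
        for j, au in enumerate(AU_CATALOG):
            out[:, j] = self.classifiers[au].predict(X)
        return out

    def classify_frame(self, x, frame_index: int = 0) -> AUFrame:
        """Predict one frame's 31 intensity levels from its feature vector."""
        levels = self.classify(x)[0]
        return AUFrame.from_levels(
            [IntensityLevel(v) for v in levels],
            frame_index=frame_index,
            fps=self.fps,
        )


def train_bank(
    features,
    labels,
    seed: int = 0,
    classifier_factory: Callable[[int], BaseEstimator] | None = None,
    fps: float = 30.0,
) -> ClassifierBank:
    """Fit the 31-classifier bank.

    Parameters
    ----------
    features
        (n, 72) array of nonrigid feature vectors.
    labels
        (n, 31) integer intensity levels (0..5) in catalog order, or a
        sequence of :class:`AUFrame`.
    seed
        Seeds every per-AU classifier; training is reproducible.
    classifier_factory
        Callable ``seed -> estimator``; defaults to scaler + RBF SVC.

    An AU whose training labels contain a single level degenerates to a
    constant predictor (logged as a warning).
    """
    X = _validate_features(features)
    if len(labels) and isinstance(labels[0], AUFrame):
        Y = np.stack([f.to_array() for f in labels])
    else:
        Y = np.asarray(labels, dtype=int)
    if Y.shape != (len(X), N_AUS):
        raise ValueError(
            f"labels must be ({len(X)}, {N_AUS}), got {Y.shape}"
        )
    factory = classifier_factory or default_classifier_factory

    classifiers: dict[str, BaseEstimator] = {}
    for j, au in enumerate(AU_CATALOG):
        y = Y[:, j]
        if len(np.unique(y)) < 2:
            logger.warning(
                "AU %s has a single training level (%d); using a constant "
                "predictor", au, y[0],
            )
            classifiers[au] = _ConstantLevel(y[0]).fit(X, y)
        else:
            clf = factory(seed)
            clf.fit(X, y)
            classifiers[au] = clf
    return ClassifierBank(classifiers, fps=fps)
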