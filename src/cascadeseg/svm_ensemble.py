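"""Bagged RBF-SVM ensemble refining the CNN presegmentation.

The "integrated" SVM is read as a bagged ensemble: each member is an RBF
kernel SVM, k(u, v) = exp(−‖u−v‖² / (2σ²)), trained on an independent seeded
bootstrap subsample of the pixel rows (capped per member, since kernel-SVM
cost grows quadratically with training size), and predictions aggregate by
the sign of the mean member decision value.  Defaults follow the reference
operating point σ = 0.1, C = 1000, with feature standardization fitted at
train time and replayed at predict time.

The quadratic-programming solver itself is scikit-learn's SVC; the
ensembling, aggregation and σ-parameterization live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import PixelFeatureTable
from .io_formats import LabelMap, LabelScheme

__all__ = ["SVMEnsembleConfig", "SVMEnsembleModel", "train_ensemble",
           "predict_ensemble", "decision_values"]


@dataclass
class SVMEnsembleConfig:
    """Kernel, penalty and bagging tunables.

    ``sigma`` is the kernel *width* (the exponent scale is 1/(2σ²));
    ``subsample`` the bootstrap fraction of training pixels per member;
    ``max_train_pixels`` caps each member's training set.
    """

    sigma: float = 0.1
    C: float = 1000.0
    n_members: int = 5
    subsample: float = 0.5
    max_train_pixels: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if not (0 < self.subsample <= 1):
            raise ValueError("subsample must be in (0, 1]")

    @property
    def gamma(self) -> float:
        return 1.0 / (2.0 * self.sigma ** 2)


@dataclass
class SVMEnsembleModel:
    members: List[SVC]
    config: SVMEnsembleConfig
    scaler: StandardScaler
    classes: np.ndarray = field(default_factory=lambda: np.array([0, 1]))

    @property
    def n_features(self) -> int:
        return int(self.scaler.mean_.shape[0])


def train_ensemble(table: PixelFeatureTable, targets,
                   config: Optional[SVMEnsembleConfig] = None) -> SVMEnsembleModel:
    """Fit the bagged ensemble on feature rows (intensity features + label column).

    Each member sees an independent bootstrap resample of
    ``min(round(subsample·n), max_train_pixels)`` rows drawn from the seeded
    stream.  The degenerate setting n_members=1, subsample=1.0 (with n under
    the cap) trains on all rows as-is and is then exactly a single SVM fit.
    """
    config = config or SVMEnsembleConfig()
    X = np.asarray(table.features, dtype=np.float64)
    y = np.asarray(targets)
    if X.shape[0] == 0:
        raise ValueError("empty feature table")
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} feature rows but {y.shape[0]} targets")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"training targets contain a single class ({classes.tolist()})")

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    size = min(int(round(config.subsample * n)), config.max_train_pixels)
    size = max(size, 2)

    members = []
    for _ in range(config.n_members):
        if config.n_members == 1 and config.subsample == 1.0 and n <= config.max_train_pixels:
            idx = np.arange(n)
        else:
            for _attempt in range(100):
                idx = rng.choice(n, size=size, replace=True)
                if np.unique(y[idx]).size == classes.size:
                    break
            else:
                raise ValueError("could not draw a bootstrap sample containing every class")
        svc = SVC(C=config.C, kernel="rbf", gamma=config.gamma)
        svc.fit(Xs[idx], y[idx])
        members.append(svc)
    return SVMEnsembleModel(members=members, config=config, scaler=scaler, classes=classes)


def decision_values(model: SVMEnsembleModel, table: PixelFeatureTable) -> np.ndarray:
    """Mean member decision value per row (binary case: >0 leans tumor)."""
    X = np.asarray(table.features, dtype=np.float64)
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} feature columns, got {X.shape[1]}")
    Xs = model.scaler.transform(X)
    return np.mean([m.decision_function(Xs) for m in model.members], axis=0)


def predict_ensemble(model: SVMEnsembleModel, table: PixelFeatureTable,
                     shape=None) -> LabelMap:
    """Aggregate member decisions into a label map.

    Binary: label = 1 where the mean decision value ≥ 0 (an exact zero goes
    to the tumor class).  Multiclass: per-member prediction, majority vote,
    ties to the lowest class value.  Rows are painted at their coordinates
    into a zero-initialized grid of ``shape`` (default: the table's source
    shape), so a table restricted to an ROI only fills that ROI.
    """
    X = np.asarray(table.features, dtype=np.float64)
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} feature columns, got {X.shape[1]}")
    if model.classes.size == 2:
        mean_dec = decision_values(model, table)
        labels = np.where(mean_dec >= 0, model.classes[1], model.classes[0])
    else:
        Xs = model.scaler.transform(X)
        votes = np.stack([m.predict(Xs) for m in model.members])  # (members, n)
        counts = np.stack([(votes == c).sum(axis=0) for c in model.classes])
        labels = model.classes[counts.argmax(axis=0)]  # argmax → lowest class on ties

    shape = tuple(shape) if shape is not None else tuple(table.shape)
    if not shape:
        raise ValueError("target shape unknown: table has no source shape")
    grid = np.zeros(shape, dtype=np.int64)
    grid[tuple(table.coords.T)] = labels
    scheme = LabelScheme.BINARY if set(np.unique(grid)) <= {0, 1} else LabelScheme.BRATS
    return LabelMap(data=grid, scheme=scheme)
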