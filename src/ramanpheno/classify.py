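"""Train-only standardization, PCA reduction and MLP classification.

All transforms are fitted on the training partition alone and then applied
unchanged to held-out data, so no information leaks across the split.  The
classifier is a shallow multilayer perceptron (ReLU, Adam); the
architecture search sweeps uniform-width nets of 1-10 hidden layers with a
configurable width grid, scored by stratified cell-grouped k-fold
cross-validation.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.neural_network import MLPClassifier

POSITIVE_CLASS = "pediatric"
DEFAULT_WIDTHS = (2, 5, 10, 20, 50, 100)
DEFAULT_DEPTHS = tuple(range(1, 11))


# ---------------------------------------------------------------------------
# standardization


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature training mean/SD; zero-variance features are dropped."""

    mean: np.ndarray
    sd: np.ndarray
    keep: np.ndarray  # boolean mask over the original feature axis


def fit_scaler(train_features: np.ndarray) -> ScalerParams:
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two training rows to fit a scaler")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    return ScalerParams(mean=mean, sd=sd, keep=keep)


def apply_scaler(params: ScalerParams, features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    return (X[:, params.keep] - params.mean[params.keep]) / params.sd[params.keep]


# ---------------------------------------------------------------------------
# PCA


@dataclass(frozen=True)
class PCAModel:
    """Orthonormal loadings and training mean of a fitted PCA."""

    components: np.ndarray               # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    n_components: int


def fit_pca(train_features: np.ndarray, n_components: int = 20) -> PCAModel:
    X = np.asarray(train_features, dtype=float)
    limit = min(X.shape[0] - 1, X.shape[1])
    if n_components > limit:
        raise ValueError(f"n_components={n_components} exceeds min(rows-1, features)={limit}")
    pca = _SkPCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    return PCAModel(
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean=pca.mean_,
        n_components=n_components,
    )


def apply_pca(model: PCAModel, features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    return (X - model.mean) @ model.components.T


# ---------------------------------------------------------------------------
# MLP


@dataclass(frozen=True)
class MLPConfig:
    """Shallow ReLU/Adam net; stopping is loss-based (Adam defaults).

    ``patience`` is the number of epochs without loss improvement before
    stopping; set ``early_stopping=True`` to hold out a validation fraction
    and stop on its score instead (not the default: on small nets the
    validation criterion can stop training on the initial plateau).
    """

    hidden_layout: tuple = (5, 5, 5, 5, 5)
    learning_rate: float = 1e-3
    max_epochs: int = 500
    patience: int = 20
    early_stopping: bool = False
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= len(self.hidden_layout) <= 10:
            raise ValueError("between 1 and 10 hidden layers")
        if any(w < 1 for w in self.hidden_layout):
            raise ValueError("hidden layer widths must be positive")


def train_mlp(train_scores: np.ndarray, labels: Sequence[str], cfg: MLPConfig = MLPConfig()):
    """Train a ReLU/Adam MLP; deterministic given cfg.seed."""
    X = np.asarray(train_scores, dtype=float)
    y = np.asarray(labels)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite training features")
    clf = MLPClassifier(
        hidden_layer_sizes=cfg.hidden_layout,
        activation="relu",
        solver="adam",
        learning_rate_init=cfg.learning_rate,
        max_iter=cfg.max_epochs,
        early_stopping=cfg.early_stopping,
        validation_fraction=cfg.validation_fraction,
        n_iter_no_change=cfg.patience,
        random_state=cfg.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return clf


def predict(classifier, scores: np.ndarray) -> tuple:
    """Hard labels (0.5 threshold on the pediatric probability) and scores."""
    X = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    proba = classifier.predict_proba(X)
    pos_col = list(classifier.classes_).index(POSITIVE_CLASS)
    p_ped = proba[:, pos_col]
    labels = np.where(p_ped >= 0.5, POSITIVE_CLASS, "adult")
    return labels, p_ped


# ---------------------------------------------------------------------------
# architecture search


def n_parameters(layout: tuple, n_inputs: int, n_outputs: int = 1) -> int:
    """Weight + bias count of a fully connected net."""
    sizes = (n_inputs, *layout, n_outputs)
    return sum(sizes[i] * sizes[i + 1] + sizes[i + 1] for i in range(len(sizes) - 1))


def search_space(
    widths: Sequence[int] = DEFAULT_WIDTHS, depths: Sequence[int] = DEFAULT_DEPTHS
) -> list:
    """Uniform-width layouts (w,)*d for every width/depth combination."""
    if any(not 2 <= w <= 100 for w in widths):
        raise ValueError("search widths must lie in [2, 100]")
    if any(not 1 <= d <= 10 for d in depths):
        raise ValueError("search depths must lie in [1, 10]")
    return [(w,) * d for d in depths for w in widths]


@dataclass
class CVResult:
    """Per-architecture cross-validation accuracies and the selected layout."""

    table: pd.DataFrame  # layout, depth, width, n_params, mean_accuracy, sd_accuracy
    chosen: tuple


def grid_search_mlp(
    train_scores: np.ndarray,
    labels: Sequence[str],
    groups: Sequence,
    widths: Sequence[int] = DEFAULT_WIDTHS,
    depths: Sequence[int] = DEFAULT_DEPTHS,
    k: int = 10,
    seed: int = 0,
    mlp_cfg: MLPConfig = MLPConfig(),
) -> CVResult:
    """Stratified, cell-grouped k-fold CV over uniform-width architectures.

    Folds keep all spectra of a physical cell together.  Ties on mean
    accuracy are resolved toward fewer parameters, then fewer layers.
    """
    X = np.asarray(train_scores, dtype=float)
    y = np.asarray(labels)
    g = np.asarray(groups)
    cv = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y, g))
    for tr, te in folds:
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError("degenerate fold: a CV fold contains a single class")
    rows = []
    for layout in search_space(widths, depths):
        accs = []
        for fold_i, (tr, te) in enumerate(folds):
            cfg = dataclasses.replace(mlp_cfg, hidden_layout=layout, seed=mlp_cfg.seed + fold_i)
            clf = train_mlp(X[tr], y[tr], cfg)
            pred, _ = predict(clf, X[te])
            accs.append(float(np.mean(pred == y[te])))
        rows.append({
            "layout": layout,
            "depth": len(layout),
            "width": layout[0],
            "n_params": n_parameters(layout, X.shape[1]),
            "mean_accuracy": float(np.mean(accs)),
            "sd_accuracy": float(np.std(accs, ddof=0)),
        })
    table = pd.DataFrame(rows)
    ranked = table.sort_values(
        by=["mean_accuracy", "n_params", "depth"], ascending=[False, True, True]
    )
    return CVResult(table=table, chosen=tuple(ranked.iloc[0]["layout"]))
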