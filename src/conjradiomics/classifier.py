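"""SMOTE balancing and the fully connected anemia classifier.

The network mirrors the study architecture: 20 input nodes (the selected
features), two hidden layers of 50 rectified-linear units, a two-way
softmax output trained with cross-entropy under the ADAM optimizer.
Learning rate, batch size and epoch count are found by randomized search
on a participant-level 20% holdout of the training set; SMOTE balances
classes on fitting rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier

from conjradiomics.stats import auc_mann_whitney

__all__ = [
    "NetworkSpec",
    "TrainedModel",
    "DEFAULT_GRID",
    "smote_oversample",
    "tune_hyperparameters",
    "train_classifier",
    "predict_scores",
]

#: Randomized-search grids for the searched hyperparameters.
DEFAULT_GRID = {
    "learning_rate": (1e-2, 1e-3, 1e-4),
    "batch_size": (32, 64, 128),
    "epochs": (50, 100, 200),
}


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and training hyperparameters of the classifier."""

    input_nodes: int = 20
    hidden: tuple[int, int] = (50, 50)
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0


@dataclass
class TrainedModel:
    """Fitted network plus its spec and the feature-name contract."""

    estimator: MLPClassifier
    spec: NetworkSpec
    feature_names: list[str]
    history: dict = field(default_factory=dict)


def smote_oversample(X, y, k_neighbors: int = 5, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by synthetic minority oversampling.

    Each synthetic row is ``x + u * (x_nn - x)`` with ``u ~ U(0, 1)``,
    where ``x`` is a minority row and ``x_nn`` one of its ``k_neighbors``
    minority-class nearest neighbors. The minority class is upsampled to
    the majority count; already balanced input is returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("SMOTE requires both classes present")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return X.copy(), y.copy()
    Xmin = X[y == minority]
    k = k_neighbors
    if n_min <= k:
        k = n_min - 1
        warnings.warn(
            f"minority count {n_min} <= k_neighbors; reduced k to {k}")
    if k < 1:
        raise ValueError("minority class too small for SMOTE interpolation")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
    _, idx = nn.kneighbors(Xmin)  # column 0 is the point itself
    rng = np.random.default_rng(seed)
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, n_new)
    pick = rng.integers(1, k + 1, n_new)
    u = rng.random((n_new, 1))
    neigh = Xmin[idx[base, pick]]
    synthetic = Xmin[base] + u * (neigh - Xmin[base])
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority)])
    return X_out, y_out


def _fit_mlp(X, y, spec: NetworkSpec, apply_smote: bool) -> MLPClassifier:
    if apply_smote:
        X, y = smote_oversample(X, y, seed=spec.seed)
    clf = MLPClassifier(
        hidden_layer_sizes=spec.hidden,
        activation="relu",
        solver="adam",
        learning_rate_init=spec.learning_rate,
        batch_size=min(spec.batch_size, X.shape[0]),
        max_iter=spec.epochs,
        n_iter_no_change=spec.epochs,  # no early stopping by default
        random_state=spec.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return clf


def train_classifier(train: pd.DataFrame, feature_names: list[str],
                     spec: NetworkSpec | None = None,
                     apply_smote: bool = True,
                     target: str = "anemia") -> TrainedModel:
    """Fit the fully connected classifier on the selected training features.

    SMOTE is applied to the training rows (never to holdout or test rows)
    before fitting. Deterministic given ``spec.seed``.
    """
    if spec is None:
        spec = NetworkSpec()
    missing = [c for c in feature_names if c not in train.columns]
    if missing:
        raise KeyError(f"training table lacks selected features: {missing}")
    X = train[list(feature_names)].to_numpy(dtype=float)
    y = train[target].to_numpy(dtype=int)
    spec = replace(spec, input_nodes=len(feature_names))
    clf = _fit_mlp(X, y, spec, apply_smote)
    history = {"loss_curve": [float(v) for v in clf.loss_curve_]}
    return TrainedModel(estimator=clf, spec=spec,
                        feature_names=list(feature_names), history=history)


def predict_scores(model: TrainedModel, rows: pd.DataFrame) -> np.ndarray:
    """Positive-class (anemia) scores in [0, 1] for complete feature rows."""
    missing = [c for c in model.feature_names if c not in rows.columns]
    if missing:
        raise KeyError(f"rows lack selected features: {missing}")
    X = rows[model.feature_names].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("rows must be imputed before scoring")
    proba = model.estimator.predict_proba(X)
    pos_col = int(np.argmax(model.estimator.classes_ == 1))
    return proba[:, pos_col]


def tune_hyperparameters(
    train: pd.DataFrame,
    feature_names: list[str],
    grid: dict | None = None,
    tuning_fraction: float = 0.2,
    n_draws: int = 20,
    seed: int = 0,
    target: str = "anemia",
) -> NetworkSpec:
    """Randomized hyperparameter search on a participant-level holdout.

    ``tuning_fraction`` of training participants form the holdout; each
    candidate spec is fitted (with SMOTE on the fitting portion only) and
    scored by holdout AUC; the best spec is returned, refit-ready.
    """
    from conjradiomics.features import split_cohort

    if grid is None:
        grid = DEFAULT_GRID
    keys = list(grid)
    if any(len(grid[k]) == 0 for k in keys):
        raise ValueError("empty hyperparameter grid")
    rng = np.random.default_rng(seed)
    combos = {tuple(rng.choice(grid[k]) for k in keys) for _ in range(n_draws)}
    fit_part, holdout = split_cohort(
        train, train_fraction=1.0 - tuning_fraction, seed=seed)
    assert not set(fit_part["participant_id"]) & set(holdout["participant_id"])
    results = []
    for combo in sorted(combos):
        params = dict(zip(keys, combo))
        spec = NetworkSpec(
            input_nodes=len(feature_names),
            learning_rate=float(params.get("learning_rate", 1e-3)),
            batch_size=int(params.get("batch_size", 32)),
            epochs=int(params.get("epochs", 100)),
            seed=seed,
        )
        try:
            model = train_classifier(fit_part, feature_names, spec,
                                     target=target)
            scores = predict_scores(model, holdout)
            auc = auc_mann_whitney(scores, holdout[target].to_numpy()).auc
        except Exception as exc:
            results.append((spec, None, str(exc)))
            continue
        results.append((spec, auc, None))
    scored = [(s, a) for s, a, e in results if a is not None]
    if not scored:
        raise RuntimeError(f"all candidates failed: {[e for _, _, e in results]}")
    best = max(scored, key=lambda sa: sa[1])[0]
    return best
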