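"""Target-specific scoring functions: five learners × two modes.

Each scoring function is one (algorithm, mode) pair — random forest,
gradient-boosted trees (XGBoost), support vector machine, and one- or
multi-hidden-layer feed-forward networks (ANN/DNN), each as a binary
classifier (active vs inactive) or a regressor on pIC50. The scoring
direction is fixed: higher output means more likely active
(classification probability) or higher predicted potency (regression
pIC50), so both modes rank screens the same way.

Hyperparameters are tuned by TPE over the documented per-algorithm
search spaces, minimizing a 5-fold cross-validation objective
(1 − PR-AUC for classifiers, RMSE for regressors, both configurable).
Model training, tuning and scoring are deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median

import numpy as np

from . import tuning
from .tuning import choice, loguniform, quniform

logger = logging.getLogger("targetsf.models")

__all__ = [
    "ALGORITHMS",
    "MODES",
    "ScoringModel",
    "TrainedRun",
    "define_search_space",
    "tune",
    "fit",
    "score",
    "repeat_runs",
    "median_nef",
]

ALGORITHMS = ("RF", "XGB", "SVM", "ANN", "DNN")
MODES = ("classification", "regression")


@dataclass
class ScoringModel:
    """One fitted algorithm/mode/hyperparameter/seed combination."""

    algorithm: str
    mode: str
    hyperparams: dict
    seed: int
    estimator: object = None
    n_features: int = 0
    fitted: bool = False


@dataclass
class TrainedRun:
    """One train+score cycle of a repeated-runs experiment."""

    run_index: int
    seed: int
    model: ScoringModel
    test_scores: np.ndarray
    nef: float
    ef: float = float("nan")


# ---------------------------------------------------------------------------
# Search spaces


def define_search_space(algorithm: str, mode: str) -> dict:
    """Default TPE search space for one (algorithm, mode) pair.

    Tree learners expose ensemble size and depth; the SVM exposes
    regularization, kernel and width (plus the ε-tube for regression);
    the networks expose layer widths, L2 penalty and learning rate. The
    concrete ranges are this package's documented defaults.
    """
    _check(algorithm, mode)
    if algorithm == "RF":
        return {
            "n_estimators": quniform(100, 500, 50),
            "max_depth": quniform(4, 30, 2),
            "max_features": choice(["sqrt", "log2", 0.3]),
        }
    if algorithm == "XGB":
        return {
            "n_estimators": quniform(100, 500, 50),
            "max_depth": quniform(3, 10, 1),
            "learning_rate": loguniform(1e-3, 0.3),
            "subsample": tuning.uniform(0.5, 1.0),
        }
    if algorithm == "SVM":
        space = {
            "C": loguniform(1e-2, 1e3),
            "gamma": loguniform(1e-4, 1.0),
            "kernel": choice(["rbf", "linear"]),
        }
        if mode == "regression":
            space["epsilon"] = loguniform(1e-3, 1.0)
        return space
    if algorithm == "ANN":
        return {
            "hidden_size": quniform(16, 256, 16),
            "alpha": loguniform(1e-6, 1e-2),
            "learning_rate_init": loguniform(1e-4, 1e-2),
        }
    # DNN: at least two hidden layers
    return {
        "n_layers": choice([2, 3]),
        "hidden_size": quniform(32, 256, 32),
        "alpha": loguniform(1e-6, 1e-2),
        "learning_rate_init": loguniform(1e-4, 1e-2),
    }


def _check(algorithm: str, mode: str) -> None:
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; "
                         f"expected one of {ALGORITHMS}")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


# ---------------------------------------------------------------------------
# Estimator construction


def _build_estimator(algorithm: str, mode: str, hp: dict, seed: int,
                     needs_proba: bool = True):
    cls = mode == "classification"
    if algorithm == "RF":
        from sklearn.ensemble import (RandomForestClassifier,
                                      RandomForestRegressor)
        klass = RandomForestClassifier if cls else RandomForestRegressor
        return klass(
            n_estimators=int(hp.get("n_estimators", 300)),
            max_depth=hp.get("max_depth"),
            max_features=hp.get("max_features", "sqrt"),
            random_state=seed, n_jobs=1)
    if algorithm == "XGB":
        from xgboost import XGBClassifier, XGBRegressor
        common = dict(
            n_estimators=int(hp.get("n_estimators", 300)),
            max_depth=int(hp.get("max_depth", 6)),
            learning_rate=float(hp.get("learning_rate", 0.1)),
            subsample=float(hp.get("subsample", 1.0)),
            random_state=seed, n_jobs=1, verbosity=0)
        if cls:
            return XGBClassifier(eval_metric="logloss", **common)
        return XGBRegressor(**common)
    if algorithm == "SVM":
        from sklearn.svm import SVC, SVR
        kernel = hp.get("kernel", "rbf")
        gamma = hp.get("gamma", "scale")
        if cls:
            return SVC(C=float(hp.get("C", 1.0)), kernel=kernel, gamma=gamma,
                       probability=needs_proba, random_state=seed)
        return SVR(C=float(hp.get("C", 1.0)), kernel=kernel, gamma=gamma,
                   epsilon=float(hp.get("epsilon", 0.1)))
    if algorithm in ("ANN", "DNN"):
        from sklearn.neural_network import MLPClassifier, MLPRegressor
        width = int(hp.get("hidden_size", 64))
        if algorithm == "ANN":
            layers = (width,)
        else:
            layers = tuple([width] * int(hp.get("n_layers", 2)))
            if len(layers) < 2:
                raise ValueError("a DNN needs at least two hidden layers")
        klass = MLPClassifier if cls else MLPRegressor
        return klass(
            hidden_layer_sizes=layers,
            alpha=float(hp.get("alpha", 1e-4)),
            learning_rate_init=float(hp.get("learning_rate_init", 1e-3)),
            max_iter=int(hp.get("max_iter", 400)),
            random_state=seed)
    _check(algorithm, "classification")


# ---------------------------------------------------------------------------
# Tuning


def tune(space: dict, X, y, mode: str, algorithm: str, folds: int = 5,
         max_evals: int = 50, seed: int = 0,
         objective: str | None = None) -> tuning.TuningResult:
    """TPE search of ``space`` minimizing a k-fold CV objective.

    Objectives: ``"one_minus_prauc"`` (classification default) and
    ``"rmse"`` (regression default). Deterministic given ``seed`` (the
    same seed drives the TPE trajectory and the CV fold shuffling).
    """
    from sklearn.model_selection import KFold, StratifiedKFold, cross_val_score

    X = np.asarray(X)
    y = np.asarray(y)
    if X.shape[0] != len(y):
        raise ValueError("X rows and y length differ")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if mode == "classification" and len(np.unique(y)) < 2:
        raise ValueError("degenerate labels: single class")
    objective = objective or (
        "one_minus_prauc" if mode == "classification" else "rmse")

    if mode == "classification":
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        scoring = "average_precision"
    else:
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
        scoring = "neg_root_mean_squared_error"

    def cv_loss(params: dict) -> float:
        est = _build_estimator(algorithm, mode, params, seed,
                               needs_proba=False)
        vals = cross_val_score(est, X, y, cv=cv, scoring=scoring,
                               error_score="raise")
        if objective == "one_minus_prauc":
            return 1.0 - float(np.mean(vals))
        if objective == "rmse":
            return -float(np.mean(vals))
        raise ValueError(f"unknown objective {objective!r}")

    return tuning.tpe_minimize(cv_loss, space, max_evals=max_evals, seed=seed)


# ---------------------------------------------------------------------------
# Fit / score


def fit(algorithm: str, mode: str, hyperparams: dict, X, y,
        seed: int = 0) -> ScoringModel:
    """Train one scoring function; reproducible given ``seed``."""
    _check(algorithm, mode)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != len(y):
        raise ValueError("X rows and y length differ")
    bad_rows = np.flatnonzero(~np.isfinite(X).all(axis=1))
    if len(bad_rows):
        raise ValueError(f"non-finite features in rows {bad_rows.tolist()[:10]}")
    if mode == "classification":
        y = y.astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate labels: single class")
    else:
        y = y.astype(float)
    est = _build_estimator(algorithm, mode, hyperparams, seed,
                           needs_proba=True)
    est.fit(X, y)
    return ScoringModel(algorithm=algorithm, mode=mode,
                        hyperparams=dict(hyperparams), seed=seed,
                        estimator=est, n_features=X.shape[1], fitted=True)


def score(model: ScoringModel, X) -> np.ndarray:
    """Score complexes: P(active) for classifiers, predicted pIC50 for
    regressors. Higher is better in both modes."""
    if not model.fitted:
        raise ValueError("model is not fitted")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature count mismatch: model expects {model.n_features}, "
            f"got {X.shape[1] if X.ndim == 2 else 'non-2D'}")
    if model.mode == "classification":
        return model.estimator.predict_proba(X)[:, 1]
    return np.asarray(model.estimator.predict(X), dtype=float)


# ---------------------------------------------------------------------------
# Repeated runs


def repeat_runs(algorithm: str, mode: str, hyperparams: dict,
                X_train, y_train, X_test, test_labels,
                n_runs: int = 10, base_seed: int = 0,
                f: float = 0.01,
                test_ids=None) -> list[TrainedRun]:
    """Repeat fit+score ``n_runs`` times with seeds base_seed..+n_runs−1.

    The train/test membership is fixed (the split is deterministic); the
    per-run randomness is the model seed. Each run records its test
    scores and its EF/NEF at fraction ``f``.
    """
    from . import evaluation

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    test_labels = np.asarray(test_labels, dtype=bool)
    ids = ([str(i) for i in range(len(test_labels))]
           if test_ids is None else list(test_ids))
    runs = []
    for k in range(n_runs):
        seed = base_seed + k
        model = fit(algorithm, mode, hyperparams, X_train, y_train, seed=seed)
        s = score(model, X_test)
        screen = evaluation.rank(ids, s, test_labels)
        runs.append(TrainedRun(
            run_index=k + 1, seed=seed, model=model, test_scores=s,
            nef=evaluation.nef_fraction(screen, f),
            ef=evaluation.ef_fraction(screen, f)))
    return runs


def median_nef(runs) -> float:
    """Median NEF across repeated runs."""
    return float(np.median([r.nef for r in runs]))
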