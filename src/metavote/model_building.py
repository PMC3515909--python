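"""Classifier building: importance ranking, 10x10 CV, forward selection.

Seven classification methods are supported: random forest (RF), logistic
regression (LR), support vector machines with radial (R-SVM), linear
(L-SVM), polynomial (P-SVM) and sigmoid (S-SVM) kernels, and a
single-hidden-layer neural network (NNET).

Model building follows a "top-down" forward protocol: the candidate gene
pool is ordered by random-forest permutation variable importance (the
drop in prediction accuracy when a feature's values are permuted), then
for every prefix length k = 1..max_features and every hyperparameter grid
point the ten-times repeated stratified 10-fold cross-validated balanced
accuracy is computed, and the model is refit on the full training set at
the jointly best (k, grid point).  Ties in bAcc prefer the candidate with
the more balanced sensitivity/specificity, then fewer features, then the
earlier grid point — all deterministic.

Two leakage regimes are available.  ``mode='paper'`` ranks features once
on the full training set before cross-validation, which leaks test-fold
information into the ranking and inflates internal estimates;
``mode='clean'`` redoes the ranking inside every CV training fold.
"""

from __future__ import annotations

import math
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .types import (
    ConfigurationError,
    ExpressionStudy,
    InputError,
    PerformanceSummary,
    child_seed,
)
from .evaluation import performance
from .voting import METHOD_NAMES

MTRY_TOKENS = ("1", "0.5sqrt", "sqrt", "2sqrt", "all")

#: Hyperparameter grids matching the original protocol.
PAPER_GRIDS: dict[str, dict[str, tuple]] = {
    "RF": {"ntree": (2000, 3000, 4000, 5000), "mtry": MTRY_TOKENS},
    "LR": {},
    "R-SVM": {"C": (0.01, 0.1, 1.0, 10.0), "gamma": (0.001, 0.01, 0.1, 1.0)},
    "L-SVM": {"C": (0.01, 0.1, 1.0, 10.0)},
    "P-SVM": {
        "C": (0.01, 0.1, 1.0, 10.0),
        "gamma": (0.001, 0.01, 0.1, 1.0),
        "degree": (2, 3, 4),
    },
    "S-SVM": {"C": (0.01, 0.1, 1.0, 10.0), "gamma": (0.001, 0.01, 0.1, 1.0)},
    "NNET": {"hidden_units": (1, 3, 5), "weight_decay": (0.0, 0.01, 0.1)},
}

#: Small grids for fast experiment re-enactments and test runs.  Each SVM
#: grid still spans its full-scale ranges (a reduced search, not a fixed
#: point): a single arbitrary (C, gamma) can leave a kernel degenerate.
REDUCED_GRIDS: dict[str, dict[str, tuple]] = {
    "RF": {"ntree": (50,), "mtry": ("sqrt",)},
    "LR": {},
    "R-SVM": {"C": (1.0, 10.0), "gamma": (0.1, 1.0)},
    "L-SVM": {"C": (0.1, 1.0, 10.0)},
    "P-SVM": {"C": (1.0, 10.0), "gamma": (1.0,), "degree": (2, 3)},
    "S-SVM": {"C": (1.0, 10.0), "gamma": (0.1, 1.0)},
    "NNET": {"hidden_units": (3,), "weight_decay": (0.01,)},
}


def _resolve_mtry(token, k: int) -> int:
    if token == "1":
        return 1
    if token == "all":
        return k
    mult = {"0.5sqrt": 0.5, "sqrt": 1.0, "2sqrt": 2.0}[token]
    return int(min(max(round(mult * math.sqrt(k)), 1), k))


@dataclass
class MethodSpec:
    """One classification method plus its hyperparameter grid."""

    name: str
    grid: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in METHOD_NAMES:
            raise ConfigurationError(
                f"unknown method {self.name!r}; choose from {METHOD_NAMES}"
            )
        legal = set(PAPER_GRIDS[self.name])
        illegal = set(self.grid) - legal
        if illegal:
            raise ConfigurationError(
                f"{self.name}: illegal grid axes {sorted(illegal)}; legal: {sorted(legal)}"
            )

    def grid_points(self, n_features: int) -> list[dict]:
        """Expand the grid for a model of ``n_features`` features.

        RF's mtry tokens resolve to feature counts (multiples of sqrt(k),
        clipped to [1, k]) and duplicates collapse, order preserved.
        """
        grid = self.grid or PAPER_GRIDS[self.name]
        if not grid:
            return [{}]
        axes = sorted(grid)  # deterministic axis order
        points = []
        seen = set()
        for combo in itertools.product(*(grid[a] for a in axes)):
            hp = dict(zip(axes, combo))
            if "mtry" in hp:
                hp["mtry"] = _resolve_mtry(hp["mtry"], n_features)
            key = tuple(sorted(hp.items()))
            if key not in seen:
                seen.add(key)
                points.append(hp)
        return points


def default_method_specs(reduced: bool = False) -> list[MethodSpec]:
    """One MethodSpec per method, with paper-scale or reduced grids."""
    grids = REDUCED_GRIDS if reduced else PAPER_GRIDS
    return [MethodSpec(name, dict(grids[name])) for name in METHOD_NAMES]


def make_estimator(name: str, hyperparams: dict, seed: int):
    """Instantiate the scikit-learn estimator for one method.

    Probabilistic methods classify at the 0.5 probability threshold; SVMs
    at the sign of the decision function; no class weighting (balance is
    enforced through the bAcc selection criterion instead).
    """
    hp = hyperparams
    if name == "RF":
        return RandomForestClassifier(
            n_estimators=int(hp.get("ntree", 500)),
            max_features=int(hp["mtry"]) if "mtry" in hp else "sqrt",
            random_state=seed,
            n_jobs=1,
        )
    if name == "LR":
        # Unpenalized maximum likelihood (C=inf); separation is handled by
        # the iteration cap (scikit-learn emits a ConvergenceWarning then).
        return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=200)
    kernels = {"R-SVM": "rbf", "L-SVM": "linear", "P-SVM": "poly", "S-SVM": "sigmoid"}
    if name in kernels:
        return SVC(
            kernel=kernels[name],
            C=float(hp.get("C", 1.0)),
            gamma=float(hp["gamma"]) if "gamma" in hp else "scale",
            degree=int(hp.get("degree", 3)),
        )
    if name == "NNET":
        return MLPClassifier(
            hidden_layer_sizes=(int(hp.get("hidden_units", 3)),),
            activation="logistic",
            alpha=float(hp.get("weight_decay", 0.01)),
            solver="lbfgs",
            max_iter=int(hp.get("max_iter", 300)),
            random_state=seed,
        )
    raise ConfigurationError(f"unknown method {name!r}")


def _study_matrix(study: ExpressionStudy, features) -> tuple[np.ndarray, np.ndarray]:
    missing = [g for g in features if g not in study.expression.index]
    if missing:
        raise InputError(
            f"study {study.study_id}: model feature(s) missing: {missing}"
        )
    X = study.expression.loc[list(features)].to_numpy(dtype=float).T
    y = study.outcome.to_numpy()
    return X, y


def _rank_columns(
    X: np.ndarray, y: np.ndarray, seed: int, n_trees: int, n_repeats: int
) -> np.ndarray:
    """Column order by decreasing RF permutation importance (stable ties)."""
    rf = RandomForestClassifier(
        n_estimators=n_trees, random_state=child_seed(seed, "rf"), n_jobs=1
    )
    rf.fit(X, y)
    imp = permutation_importance(
        rf, X, y, n_repeats=n_repeats, random_state=child_seed(seed, "perm"), n_jobs=1
    )
    return np.argsort(-imp.importances_mean, kind="stable")


def importance_rank(
    train: ExpressionStudy,
    pool,
    seed: int,
    n_trees: int = 500,
    n_repeats: int = 10,
) -> list[str]:
    """Order ``pool`` by random-forest permutation variable importance.

    A forest is fit on the full training study and each feature's
    importance is the mean drop in accuracy over ``n_repeats`` permutations
    of its values.  Deterministic given ``seed``; exact ties keep pool
    order.
    """
    pool = list(pool)
    if not pool:
        raise InputError("feature pool is empty")
    if not train.has_both_classes():
        raise InputError(f"study {train.study_id}: both classes required")
    if len(pool) == 1:
        return pool
    X, y = _study_matrix(train, pool)
    order = _rank_columns(X, y, seed, n_trees, n_repeats)
    return [pool[i] for i in order]


def cv_folds(
    y: np.ndarray, seed: int, n_repeats: int = 10, n_splits: int = 10
) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Stratified fold assignments for repeated CV: (repeat, train, test).

    Folds are stratified by outcome with a repeat-specific shuffle; every
    sample appears in exactly one test fold per repeat.
    """
    if len(y) < 20:
        raise InputError("cross-validation requires >= 20 samples")
    folds = []
    for r in range(n_repeats):
        skf = StratifiedKFold(
            n_splits=n_splits, shuffle=True, random_state=child_seed(seed, "cv", r)
        )
        for tr, te in skf.split(np.zeros((len(y), 1)), y):
            if len(np.unique(y[tr])) < 2:
                raise ConfigurationError(
                    "a CV training fold lost a class despite stratification; "
                    "sample size too small"
                )
            folds.append((r, tr, te))
    return folds


def _cv_vote_matrix(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    hyperparams: dict,
    seed: int,
    folds,
    fold_columns,
) -> np.ndarray:
    """(n_samples, n_repeats) out-of-fold predictions."""
    n_repeats = max(r for r, _, _ in folds) + 1
    votes = np.empty((len(y), n_repeats), dtype=np.int64)
    for fi, (r, tr, te) in enumerate(folds):
        cols = fold_columns[fi]
        est = make_estimator(method, hyperparams, child_seed(seed, "fit", fi))
        est.fit(X[np.ix_(tr, cols)], y[tr])
        votes[te, r] = est.predict(X[np.ix_(te, cols)])
    return votes


def _vote_performance(y: np.ndarray, votes: np.ndarray) -> PerformanceSummary:
    """Aggregate sensitivity/specificity/bAcc over all out-of-fold votes."""
    reps = votes.shape[1]
    return performance(np.tile(y, reps), votes.T.ravel())


def cv10x10(
    train: ExpressionStudy,
    method: "MethodSpec | str",
    features,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, PerformanceSummary]:
    """Ten-times repeated stratified 10-fold CV for a fixed feature set.

    Returns the per-sample vote matrix (samples x 10, columns ordered by
    repetition index — exactly 10 votes per sample) and the performance
    pooled over all out-of-fold predictions.
    """
    name = method.name if isinstance(method, MethodSpec) else method
    hp = dict(hyperparams or {})
    if "mtry" in hp and isinstance(hp["mtry"], str):
        hp["mtry"] = _resolve_mtry(hp["mtry"], len(list(features)))
    X, y = _study_matrix(train, features)
    if len(np.unique(y)) < 2:
        raise InputError(f"study {train.study_id}: both classes required")
    folds = cv_folds(y, seed)
    cols = np.arange(X.shape[1])
    votes = _cv_vote_matrix(X, y, name, hp, seed, folds, [cols] * len(folds))
    frame = pd.DataFrame(votes, index=train.sample_ids, columns=range(votes.shape[1]))
    return frame, _vote_performance(y, votes)


@dataclass
class FittedModel:
    """A trained classifier: the transferable unit of external validation.

    ``features`` is a prefix of the importance ranking the model was built
    from; ``cv_votes`` holds the winning candidate's 10x10 CV votes
    (samples x 10) on the training study; the estimator is refit on the
    full training set and is deterministic given the stored seed.
    """

    method: str
    features: list[str]
    hyperparams: dict
    cv_performance: PerformanceSummary
    cv_votes: pd.DataFrame
    estimator: object
    train_study_id: str
    seed: int
    mode: str = "paper"

    def predict(self, study: ExpressionStudy) -> pd.Series:
        """One hard label per sample; errors name any missing feature."""
        X, _ = _study_matrix(study, self.features)
        return pd.Series(
            self.estimator.predict(X).astype(int),
            index=study.sample_ids,
            name=self.method,
        )


def predict(model: FittedModel, study: ExpressionStudy) -> pd.Series:
    """Functional alias for :meth:`FittedModel.predict`."""
    return model.predict(study)


def forward_select(
    train: ExpressionStudy,
    method: MethodSpec,
    ranked_features,
    seed: int = 0,
    max_features: int = 40,
    mode: str = "paper",
    rank_trees: int = 200,
    rank_repeats: int = 5,
) -> FittedModel:
    """Importance-ranked forward model building with joint grid search.

    Evaluates every (prefix length k, grid point) candidate by 10x10 CV
    balanced accuracy and refits the winner on the full training set.  In
    ``clean`` mode the feature ranking is recomputed inside every CV
    training fold (the supplied global ranking still defines the final
    model's features).
    """
    ranked = list(ranked_features)
    if not ranked:
        raise InputError("ranked_features is empty")
    if mode not in ("paper", "clean"):
        raise ConfigurationError("mode must be 'paper' or 'clean'")
    max_features = min(max_features, len(ranked))
    if max_features < 1:
        raise ConfigurationError("max_features must be >= 1")

    X, y = _study_matrix(train, ranked)
    if len(np.unique(y)) < 2:
        raise InputError(f"study {train.study_id}: both classes required")
    folds = cv_folds(y, seed)

    if mode == "paper":
        fold_orders = [np.arange(X.shape[1])] * len(folds)
    else:
        fold_orders = [
            _rank_columns(
                X[tr], y[tr], child_seed(seed, "foldrank", fi), rank_trees, rank_repeats
            )
            for fi, (r, tr, te) in enumerate(folds)
        ]

    best = None  # (bacc, -|sens-spec|), votes, perf, k, hp
    for k in range(1, max_features + 1):
        fold_cols = [order[:k] for order in fold_orders]
        for hp in method.grid_points(k):
            votes = _cv_vote_matrix(X, y, method.name, hp, seed, folds, fold_cols)
            perf = _vote_performance(y, votes)
            key = (perf.bacc, -abs(perf.sensitivity - perf.specificity))
            if best is None or key > best[0]:
                best = (key, votes, perf, k, hp)

    _, votes, perf, k, hp = best
    est = make_estimator(method.name, hp, child_seed(seed, "final"))
    est.fit(X[:, :k], y)
    return FittedModel(
        method=method.name,
        features=ranked[:k],
        hyperparams=hp,
        cv_performance=perf,
        cv_votes=pd.DataFrame(votes, index=train.sample_ids, columns=range(votes.shape[1])),
        estimator=est,
        train_study_id=train.study_id,
        seed=seed,
        mode=mode,
    )
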