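"""Classifier families, hyperparameter grids and the nested tuning contract.

Six families are benchmarked: shrinkage LDA, k-nearest neighbors, linear-
and RBF-kernel SVMs, random forests, and a small feed-forward neural
network (one hidden layer of 4 ReLU units, LBFGS-trained, best of 100
random restarts).  Each family carries a fixed hyperparameter grid;
tuning is an exhaustive search scored by mean stratified 3-fold
cross-validation accuracy on the training rows only, jointly over the grid
and over the number of MI-selected features ``n_sel``.  Ties keep the first
grid point encountered, the winner is refitted on all training rows, and a
grid point that fails to converge is scored as chance (0.5) rather than
aborting the search.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .features import FeatureTable, MIRanking, select_top

logger = logging.getLogger(__name__)

__all__ = [
    "FAMILIES",
    "DEFAULT_N_SEL_GRID",
    "ClassifierSpec",
    "TunedModel",
    "build_grid",
    "make_estimator",
    "tune_and_fit",
    "nn_fit_restarts",
]

FAMILIES = ("LDA", "KNN", "SVM_LIN", "SVM_RBF", "RF", "NN")

#: Candidate feature counts tuned jointly with each family's grid; 9 is the
#: preliminary value used before tuning.
DEFAULT_N_SEL_GRID = (3, 6, 9, 12, 15)
PRELIMINARY_N_SEL = 9

SVM_MAX_ITER = 100_000
NN_HIDDEN_UNITS = 4
NN_RESTARTS = 100


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family plus its tuning configuration.

    ``grid`` overrides the family default (see :func:`build_grid`) when
    given; ``n_sel_grid`` is the joint feature-count dimension and
    ``restarts`` applies to the NN family only.
    """

    family: str
    grid: tuple[dict, ...] | None = None
    n_sel_grid: tuple[int, ...] = DEFAULT_N_SEL_GRID
    tuning_folds: int = 3
    restarts: int = NN_RESTARTS
    seed: int = 0
    #: total event count sizing the KNN grid; inferred from the training
    #: rows (plus the held-out event) when None
    n_events: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.tuning_folds < 2:
            raise ValueError("tuning_folds must be >= 2")


def knn_neighbor_cap(n_events: int) -> int:
    """Largest neighbor count searched: round(4 (N_e - 1) / 3) - 1."""
    return int(round(4 * (n_events - 1) / 3)) - 1


def build_grid(family: str, n_events: int,
               n_features: int | None = None) -> list[dict]:
    """Enumerate the default hyperparameter grid of one family.

    Grid points are dicts of sklearn keyword arguments, in a fixed
    deterministic order (itertools.product over the parameter lists in
    declaration order).  ``n_events`` sizes the KNN neighbor range;
    ``n_features`` clamps the RF max-features dimension when known.
    """
    if n_events < 3:
        raise ValueError("need at least 3 events to size the grids")

    def product(**lists):
        keys = list(lists)
        return [dict(zip(keys, combo)) for combo in itertools.product(*lists.values())]

    if family == "LDA":
        # parameterless: Ledoit-Wolf shrinkage needs no tuning
        return [{}]
    if family == "KNN":
        cap = knn_neighbor_cap(n_events)
        return product(
            n_neighbors=list(range(1, max(cap, 1) + 1)),
            p=[1, 2, 3, 4, 5],
            weights=["uniform", "distance"],
        )
    if family == "SVM_LIN":
        return product(
            C=[10.0 ** e for e in range(-4, 47, 5)],
            shrinking=[True, False],
            tol=[1e-1, 1e-3, 1e-5],
        )
    if family == "SVM_RBF":
        exps = list(range(-3, 20, 2))
        return product(
            C=[10.0 ** e for e in exps],
            gamma=[10.0 ** e for e in exps],
            shrinking=[True, False],
            tol=[1e-1, 1e-3, 1e-5],
        )
    if family == "RF":
        max_features = list(range(1, 140, 10))  # 1, 11, ..., 131
        if n_features is not None:
            clamped = sorted({min(v, n_features) for v in max_features})
            max_features = clamped
        return product(
            # the printed range starts at 1, an impossible split size; 2 is
            # the smallest meaningful value
            min_samples_split=[2, 4, 7, 10, 13],
            criterion=["gini", "entropy"],
            n_estimators=list(range(1, 100, 5)),
            oob_score=[True, False],
            max_features=max_features,
        )
    if family == "NN":
        # architecture is fixed; the stochastic dimension is the restart
        return [{}]
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")


def make_estimator(family: str, params: dict, seed: int = 0):
    """Instantiate the sklearn estimator for one grid point."""
    params = dict(params)
    params.pop("n_sel", None)
    restart_seed = params.pop("restart_seed", seed)
    if family == "LDA":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if family == "KNN":
        return KNeighborsClassifier(metric="minkowski", **params)
    if family == "SVM_LIN":
        return SVC(kernel="linear", max_iter=SVM_MAX_ITER, **params)
    if family == "SVM_RBF":
        return SVC(kernel="rbf", max_iter=SVM_MAX_ITER, **params)
    if family == "RF":
        return RandomForestClassifier(bootstrap=True, random_state=seed, **params)
    if family == "NN":
        return MLPClassifier(
            hidden_layer_sizes=(NN_HIDDEN_UNITS,),
            activation="relu",
            solver="lbfgs",
            max_iter=1000,
            random_state=restart_seed,
            **params,
        )
    raise ValueError(f"unknown family {family!r}")


@dataclass
class TunedModel:
    """Result of a grid search: chosen point, CV score, refitted estimator."""

    family: str
    params: dict
    n_sel: int
    cv_accuracy: float
    estimator: object
    feature_indices: np.ndarray

    def predict(self, table: FeatureTable) -> np.ndarray:
        x = table.values[:, self.feature_indices]
        return self.estimator.predict(x)


def _cv_accuracy(family: str, params: dict, x: np.ndarray, y: np.ndarray,
                 folds: int, seed: int) -> float:
    """Mean stratified k-fold accuracy; non-convergent points score chance."""
    skf = StratifiedKFold(n_splits=folds, shuffle=False)
    scores = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            for tr, te in skf.split(x, y):
                est = make_estimator(family, params, seed=seed)
                est.fit(x[tr], y[tr])
                scores.append(float(np.mean(est.predict(x[te]) == y[te])))
    except Exception as exc:
        logger.warning("grid point %s failed (%s); scored as chance", params, exc)
        return 0.5
    return float(np.mean(scores))


def tune_and_fit(table: FeatureTable, ranking: MIRanking,
                 spec: ClassifierSpec) -> TunedModel:
    """Exhaustive grid search over (n_sel, hyperparameters) on training rows.

    ``table`` must be the standardized training table and ``ranking`` the MI
    ranking fitted on the same rows.  The best point by mean stratified
    3-fold accuracy wins (ties: first encountered, n_sel outermost), and is
    refitted on all training rows before being returned.
    """
    y = np.asarray(table.labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("tuning requires exactly two classes")
    if counts.min() < spec.tuning_folds:
        raise ValueError(
            f"need at least {spec.tuning_folds} trials per class for "
            f"{spec.tuning_folds}-fold tuning"
        )
    n_events = spec.n_events if spec.n_events is not None else int(counts.min()) + 1
    grid = list(spec.grid) if spec.grid is not None else build_grid(
        spec.family, n_events=n_events, n_features=table.n_features)
    if spec.family == "NN":
        # restart index is the grid dimension: independent initializations
        rng = np.random.default_rng(spec.seed)
        restart_seeds = rng.integers(0, 2**31 - 1, size=spec.restarts)
        grid = [dict(g, restart_seed=int(s)) for g in grid for s in restart_seeds]

    n_sel_values = [n for n in spec.n_sel_grid if 1 <= n <= table.n_features]
    if not n_sel_values:
        n_sel_values = [table.n_features]

    best = None  # (score, n_sel, params)
    for n_sel in n_sel_values:
        cols = ranking.top(n_sel)
        x = table.values[:, cols]
        for params in grid:
            score = _cv_accuracy(spec.family, params, x, y,
                                 spec.tuning_folds, spec.seed)
            if best is None or score > best[0]:
                best = (score, n_sel, params)
    score, n_sel, params = best
    cols = np.asarray(ranking.top(n_sel))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        est = make_estimator(spec.family, params, seed=spec.seed)
        est.fit(table.values[:, cols], y)
    return TunedModel(
        family=spec.family,
        params=dict(params),
        n_sel=int(n_sel),
        cv_accuracy=score,
        estimator=est,
        feature_indices=cols,
    )


def nn_fit_restarts(table: FeatureTable, ranking: MIRanking,
                    spec: ClassifierSpec | None = None,
                    restarts: int = NN_RESTARTS, seed: int = 0) -> TunedModel:
    """Best-of-N random restarts of the 4-unit network (see tune_and_fit).

    Each restart is an independently initialized LBFGS training, scored by
    the same 3-fold cross-validation as every other family; the best
    restart is kept and refitted on all training rows.
    """
    if spec is None:
        spec = ClassifierSpec(family="NN", restarts=restarts, seed=seed)
    if spec.family != "NN":
        raise ValueError("nn_fit_restarts applies to the NN family")
    return tune_and_fit(table, ranking, spec)
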