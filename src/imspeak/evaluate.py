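"""Classification benchmarking: repeated nested CV, AUC, rank aggregation.

The benchmarking protocol is repeated stratified 10-fold cross-validation
(50 repetitions by default).  Classifiers with hyperparameters are tuned
by an inner 10-fold CV on each outer training set, so the outer test
folds never influence parameter choice.  Per repetition one AUC is
computed from the pooled out-of-fold scores; the median over repetitions
summarises a pipeline on a dataset.  Pipelines are compared across
datasets by summing their per-dataset AUC ranks (lower is better), and
clustering methods are compared per picker by a rank sum normalised over
classifiers.

The design-space enumerator reproduces the feasibility bookkeeping of
the full method registry, including the two VisualNow entries that exist
only as declared (commercial / manual) methods: the automated VisualNow
clustering can follow only VisualNow picking, and the manual combined
approach pairs only with itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .core_data import FeatureMatrix

__all__ = [
    "ClassifierSpec",
    "CVPlan",
    "CVResult",
    "CLASSIFIERS",
    "classifier_spec",
    "stratified_folds",
    "auc",
    "run_cv",
    "rank_sum_table",
    "mean_rank_sum",
    "MethodRegistry",
    "default_registry",
    "enumerate_design",
]

CLASSIFIERS = ("svm_lin", "svm_rbf", "knn", "ct", "gbm", "rf")


@dataclass
class ClassifierSpec:
    """One of the six benchmarked classifiers plus its tuning grid.

    ``tuning_grid`` maps parameter name → candidate values; an empty
    grid (random forest) means no inner CV is run.  Grids follow
    conventional ranges and are fully configurable.
    """

    name: str
    fixed_params: dict = field(default_factory=dict)
    tuning_grid: dict = field(default_factory=dict)

    def grid_points(self) -> list[dict]:
        """Cartesian product of the tuning grid, in deterministic order."""
        if not self.tuning_grid:
            return [{}]
        keys = sorted(self.tuning_grid)
        points = [{}]
        for k in keys:
            points = [dict(p, **{k: v}) for p in points for v in self.tuning_grid[k]]
        return points


def classifier_spec(name: str) -> ClassifierSpec:
    """Default specification for each supported classifier."""
    if name == "svm_lin":
        return ClassifierSpec(name, tuning_grid={"C": [0.1, 1.0, 10.0, 100.0]})
    if name == "svm_rbf":
        return ClassifierSpec(
            name,
            tuning_grid={"C": [0.1, 1.0, 10.0, 100.0], "gamma_scale": [0.1, 1.0, 10.0]},
        )
    if name == "knn":
        return ClassifierSpec(name, tuning_grid={"n_neighbors": [1, 3, 5, 7, 9, 15]})
    if name == "ct":
        return ClassifierSpec(name, tuning_grid={"ccp_alpha": [0.001, 0.01, 0.1]})
    if name == "gbm":
        # boosted trees on a 50% subsample per iteration
        return ClassifierSpec(
            name,
            fixed_params={"subsample": 0.5},
            tuning_grid={
                "n_estimators": [50, 100, 500],
                "max_depth": [1, 2, 3],
                "learning_rate": [0.01, 0.1],
            },
        )
    if name == "rf":
        # 500 trees, sqrt(p) candidate variables per split, no tuning
        return ClassifierSpec(name, fixed_params={"n_estimators": 500, "max_features": "sqrt"})
    raise ValueError(f"unknown classifier {name!r}; expected one of {CLASSIFIERS}")


def _make_estimator(spec: ClassifierSpec, params: dict, n_features: int, seed: int):
    p = dict(spec.fixed_params)
    p.update(params)
    name = spec.name
    if name == "svm_lin":
        est = SVC(kernel="linear", C=p.get("C", 1.0))
    elif name == "svm_rbf":
        gamma = p.get("gamma_scale", 1.0) / max(n_features, 1)
        est = SVC(kernel="rbf", C=p.get("C", 1.0), gamma=gamma)
    elif name == "knn":
        est = KNeighborsClassifier(n_neighbors=p.get("n_neighbors", 5))
    elif name == "ct":
        est = DecisionTreeClassifier(ccp_alpha=p.get("ccp_alpha", 0.0), random_state=seed)
    elif name == "gbm":
        est = GradientBoostingClassifier(
            n_estimators=p.get("n_estimators", 100),
            max_depth=p.get("max_depth", 3),
            learning_rate=p.get("learning_rate", 0.1),
            subsample=p.get("subsample", 0.5),
            random_state=seed,
        )
    elif name == "rf":
        est = RandomForestClassifier(
            n_estimators=p.get("n_estimators", 500),
            max_features=p.get("max_features", "sqrt"),
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown classifier {name!r}")
    if name in ("svm_lin", "svm_rbf", "knn"):
        # distance-based methods get per-fold standardisation (fit on train only)
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def _score(est, X: np.ndarray) -> np.ndarray:
    """Case-class score: decision value for SVMs, case probability otherwise."""
    if hasattr(est, "predict_proba"):
        proba = est.predict_proba(X)
        case_col = int(np.where(est.classes_ == 1)[0][0])
        return proba[:, case_col]
    return est.decision_function(X)


@dataclass
class CVPlan:
    """Repeated stratified k-fold plan; repetition r uses seed ``seed + r``."""

    k_folds: int = 10
    repetitions: int = 50
    seed: int = 0
    stratified: bool = True


@dataclass
class CVResult:
    pipeline: str
    auc_per_rep: list[float]
    chosen_params: list[dict] = field(default_factory=list)

    @property
    def median_auc(self) -> float:
        return float(np.median(self.auc_per_rep))


def stratified_folds(labels: Sequence[int], k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Deterministic stratified partition into k folds.

    Fold sizes differ by at most one, and each fold's class counts are
    within one of exact proportionality, so the case/control percentage
    of every fold is nearly that of the whole cohort.
    """
    y = np.asarray(labels, dtype=int)
    for cls in np.unique(y):
        if np.sum(y == cls) < k:
            raise ValueError(f"class {cls} has fewer than {k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros_like(y), y)]


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve in its Mann-Whitney form.

    The probability that a random case scores above a random control,
    counting ties as 1/2.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def run_cv(
    X: FeatureMatrix,
    clf: ClassifierSpec | str,
    plan: CVPlan | None = None,
    row_hook: Callable[[int, int, str, np.ndarray], None] | None = None,
) -> CVResult:
    """Repeated stratified 10-fold CV with nested hyperparameter tuning.

    Per repetition the cohort is split afresh; per outer fold, a
    non-empty tuning grid triggers an inner 10-fold CV on the outer
    training set only, selecting the grid point with the best mean inner
    AUC.  The model is refit on the full outer training set and scored
    on the held-out fold; pooling all out-of-fold scores gives one AUC
    per repetition.

    ``row_hook(rep, fold, stage, rows)`` is called with every row-index
    set used for inner tuning, outer fitting and outer scoring — an
    instrumentation point for verifying that tuning never sees test rows.
    """
    if isinstance(clf, str):
        clf = classifier_spec(clf)
    plan = plan or CVPlan()
    values, y = X.values, X.labels
    n, p = values.shape
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    grid = clf.grid_points()
    aucs: list[float] = []
    chosen: list[dict] = []
    for rep in range(plan.repetitions):
        rep_seed = plan.seed + rep
        folds = stratified_folds(y, plan.k_folds, seed=rep_seed)
        scores = np.empty(n)
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            y_tr = y[train_idx]
            if len(np.unique(y_tr)) < 2:
                raise ValueError(f"degenerate single-class training set in fold {f}")
            params = {}
            if len(grid) > 1:
                params = _tune(values, y, train_idx, clf, grid, plan.k_folds,
                               rep_seed, rep, f, row_hook)
            chosen.append(params)
            if row_hook is not None:
                row_hook(rep, f, "outer_fit", train_idx)
            est = _make_estimator(clf, params, p, seed=rep_seed)
            est.fit(values[train_idx], y_tr)
            if row_hook is not None:
                row_hook(rep, f, "outer_score", test_idx)
            scores[test_idx] = _score(est, values[test_idx])
        aucs.append(auc(scores, y))
    return CVResult(pipeline=clf.name, auc_per_rep=aucs, chosen_params=chosen)


def _tune(values, y, train_idx, clf, grid, k, seed, rep, fold, row_hook) -> dict:
    """Inner 10-fold CV over the tuning grid; best mean AUC wins, first
    grid point breaks ties (deterministic order)."""
    y_tr = y[train_idx]
    inner = stratified_folds(y_tr, k, seed=seed + 1000)
    mean_aucs = []
    for params in grid:
        fold_aucs = []
        for inner_test in inner:
            inner_train = np.setdiff1d(np.arange(len(train_idx)), inner_test)
            tr_rows = train_idx[inner_train]
            te_rows = train_idx[inner_test]
            if row_hook is not None:
                row_hook(rep, fold, "inner", np.concatenate([tr_rows, te_rows]))
            est = _make_estimator(clf, params, values.shape[1], seed=seed)
            est.fit(values[tr_rows], y[tr_rows])
            try:
                fold_aucs.append(auc(_score(est, values[te_rows]), y[te_rows]))
            except ValueError:
                continue  # inner fold with one class contributes nothing
        mean_aucs.append(np.mean(fold_aucs) if fold_aucs else -np.inf)
    return grid[int(np.argmax(mean_aucs))]


# ---------------------------------------------------------------------------
# Rank aggregation
# ---------------------------------------------------------------------------


def rank_sum_table(median_auc: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Order pipelines by summed per-dataset AUC ranks.

    ``median_auc`` maps pipeline → {dataset → median AUC}; every pipeline
    must cover every dataset.  Within a dataset, rank 1 is the highest
    AUC and ties share the minimum rank.  The output has one row per
    pipeline with its per-dataset ranks, rank sum (ascending sort key)
    and the arithmetic mean of its per-dataset median AUCs.
    """
    pipelines = list(median_auc)
    datasets: list[str] = sorted({d for v in median_auc.values() for d in v})
    for pl in pipelines:
        for d in datasets:
            if d not in median_auc[pl]:
                raise ValueError(f"missing AUC for pipeline {pl!r} on dataset {d!r}")
    ranks = {}
    for d in datasets:
        vals = np.array([median_auc[pl][d] for pl in pipelines])
        ranks[d] = rankdata(-vals, method="min").astype(int)
    df = pd.DataFrame(
        {
            "pipeline": pipelines,
            "mean_auc": [float(np.mean([median_auc[pl][d] for d in datasets]))
                         for pl in pipelines],
            **{f"rank_{d}": ranks[d] for d in datasets},
        }
    )
    df["rank_sum"] = sum(df[f"rank_{d}"] for d in datasets)
    return df.sort_values(["rank_sum", "pipeline"], kind="stable").reset_index(drop=True)


def mean_rank_sum(ranks: Sequence[float], n_classifiers: int = 6) -> float:
    """Normalised rank sum of one clustering method across classifiers.

    The method's ranks (one per classification algorithm) are summed and
    divided by the minimum possible rank sum — ``n_classifiers``, i.e. a
    method ranked first under every classifier scores exactly 1.  With R
    competing clustering methods values lie in [1, R].
    """
    ranks = list(ranks)
    if len(ranks) != n_classifiers:
        raise ValueError(f"expected {n_classifiers} ranks, got {len(ranks)}")
    return float(sum(ranks) / n_classifiers)


# ---------------------------------------------------------------------------
# Design-space enumeration
# ---------------------------------------------------------------------------

VN_A, VN_M = "vn_a", "vn_m"


@dataclass(frozen=True)
class MethodRegistry:
    """Declared pickers, clusterers and classifiers plus feasibility rules.

    ``implemented`` flags which methods this package can actually run;
    the others (the commercial VisualNow routines, the model-based PME
    and OPME pickers, and the manual combined approach) exist only so
    the design-space bookkeeping covers the full benchmark.
    """

    pickers: tuple[str, ...] = ("lm", "pme", "pdsa", "sgltr", "opme", VN_A)
    clusterers: tuple[str, ...] = ("gs", "dbscan", "ce", "em", VN_A, VN_M)
    classifiers: tuple[str, ...] = CLASSIFIERS
    implemented: frozenset[str] = frozenset(
        {"lm", "pdsa", "sgltr", "gs", "dbscan", "ce", "em", *CLASSIFIERS}
    )

    def combos(self) -> list[tuple[str, str]]:
        """All feasible (picker, clusterer) combinations.

        The automated VisualNow clusterer can only consume VisualNow
        picks; the manual combined approach does not separate picking
        from clustering and pairs only with itself.
        """
        out: list[tuple[str, str]] = []
        for c in self.clusterers:
            if c == VN_M:
                out.append((VN_M, VN_M))
            elif c == VN_A:
                if VN_A in self.pickers:
                    out.append((VN_A, VN_A))
            else:
                out.extend((p, c) for p in self.pickers)
        return out

    def implemented_combos(self) -> list[tuple[str, str]]:
        return [(p, c) for p, c in self.combos()
                if p in self.implemented and c in self.implemented]


def default_registry() -> MethodRegistry:
    return MethodRegistry()


def enumerate_design(registry: MethodRegistry | None = None) -> dict[str, int]:
    """Exact combination counts implied by the registry's feasibility rules.

    Returns the number of (picker, clusterer) combinations, the subset
    that is fully automated (excludes the manual combined approach), and
    both multiplied by the number of classifiers (full pipelines).
    """
    reg = registry or default_registry()
    known_pickers = {"lm", "pme", "pdsa", "sgltr", "opme", VN_A}
    known_clusterers = {"gs", "dbscan", "ce", "em", VN_A, VN_M}
    for group, known in (
        (reg.pickers, known_pickers),
        (reg.clusterers, known_clusterers),
        (reg.classifiers, set(CLASSIFIERS)),
    ):
        unknown = sorted(set(group) - known)
        if unknown:
            raise ValueError(f"unknown method name(s) {unknown}")
    combos = reg.combos()
    automated = [(p, c) for p, c in combos if VN_M not in (p, c)]
    n_clf = len(reg.classifiers)
    return {
        "picker_clusterer_combos": len(combos),
        "automated_combos": len(automated),
        "pipelines": len(combos) * n_clf,
        "automated_pipelines": len(automated) * n_clf,
    }
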