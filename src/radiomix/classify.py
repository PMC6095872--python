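"""Repeated stratified nested cross-validation of dichotomized outcomes.

Binary tasks are recurrence-free survival at 1-5 year cutoffs (1 = still
recurrence free at the cutoff) and dichotomized tumor grade (grades 1-2 vs
3-4). Each repetition draws a stratified 3-fold outer split; on every outer
training set the features are z-scored with training statistics, the
hyperparameters are chosen by inner stratified 3-fold mean AUC, and the
refitted model is scored on the outer test fold. AUC means and percentile
bootstrap confidence intervals summarize the reps x folds AUC list, and
per-feature coefficient tallies over all outer fits rank feature importance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "CLASSIFIER_MENU",
    "NestedCVResult",
    "dichotomize_outcomes",
    "nested_cv_auc",
    "bootstrap_summary",
    "tally_feature_importance",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """One entry of the classifier menu with its hyperparameter grid."""

    classifier_id: str
    family: str  # "logistic" | "SVM" | "random_forest"
    regularization: str = "none"  # "L1" | "L2" | "ElasticNet" | "none"
    solver: str = ""
    grid: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in ("logistic", "SVM", "random_forest"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.regularization == "ElasticNet" and "l1_ratio" not in self.grid:
            raise ValueError("ElasticNet grid needs an l1_ratio axis")

    @property
    def has_coefficients(self) -> bool:
        return self.family == "logistic"

    def grid_points(self) -> list[dict]:
        keys = sorted(self.grid)
        pts = [{}]
        for key in keys:
            pts = [{**p, key: v} for p in pts for v in self.grid[key]]
        return pts

    def build(self, params: dict, seed: int):
        if self.family == "logistic":
            # stochastic solvers need more epochs on small folds to meet tol
            max_iter = 8000 if self.solver in ("saga", "sag") else 2000
            kwargs = dict(solver=self.solver or "lbfgs", max_iter=max_iter, tol=1e-4)
            if self.regularization == "L1":
                kwargs["l1_ratio"] = 1.0
            elif self.regularization == "L2":
                kwargs["l1_ratio"] = 0.0
            elif self.regularization == "ElasticNet":
                kwargs["l1_ratio"] = params["l1_ratio"]
            else:
                kwargs["C"] = np.inf
            if "C" in params:
                kwargs["C"] = params["C"]
            if self.solver in ("saga", "sag", "liblinear"):
                kwargs["random_state"] = seed
            return LogisticRegression(**kwargs)
        if self.family == "SVM":
            return SVC(
                C=params.get("C", 1.0),
                gamma=params.get("gamma", "scale"),
                kernel=params.get("kernel", "rbf"),
                random_state=seed,
            )
        return RandomForestClassifier(
            n_estimators=int(params.get("n_estimators", 100)), random_state=seed
        )


_C_GRID = (0.01, 0.1, 1.0, 10.0)

#: Default classifier menu mirroring the study's [Reg][Solver]LogReg naming.
CLASSIFIER_MENU: dict[str, ClassifierSpec] = {
    s.classifier_id: s
    for s in (
        ClassifierSpec("L1LiblinearLogReg", "logistic", "L1", "liblinear", {"C": _C_GRID}),
        ClassifierSpec("L1SagaLogReg", "logistic", "L1", "saga", {"C": _C_GRID}),
        ClassifierSpec("L2LiblinearLogReg", "logistic", "L2", "liblinear", {"C": _C_GRID}),
        ClassifierSpec("L2LbfgsLogReg", "logistic", "L2", "lbfgs", {"C": _C_GRID}),
        ClassifierSpec("L2NewtoncgLogReg", "logistic", "L2", "newton-cg", {"C": _C_GRID}),
        ClassifierSpec("L2SagLogReg", "logistic", "L2", "sag", {"C": _C_GRID}),
        ClassifierSpec(
            "ElasticNetLogReg",
            "logistic",
            "ElasticNet",
            "saga",
            {"C": _C_GRID, "l1_ratio": (0.2, 0.5, 0.8)},
        ),
        ClassifierSpec("SVM", "SVM", "none", "", {"C": _C_GRID}),
        ClassifierSpec("RandomForest", "random_forest", "none", "", {"n_estimators": (100,)}),
    )
}


def dichotomize_outcomes(
    clinical: pd.DataFrame, task: str
) -> pd.Series:
    """Binary labels for a classification task, dropping missing outcomes.

    ``task`` is ``"grade"`` (grades 1-2 -> 0, grades 3-4 -> 1) or ``"rfs{y}"``
    for y in 1..5 (recurrence free beyond the cutoff year -> 1, else 0). RFS
    labels come from an ``rfs_free_at_{y}`` column when present, otherwise
    they are derived from a ``recurrence_years`` time-to-recurrence column
    (NaN meaning no recurrence observed).
    """
    if task == "grade":
        grade = pd.to_numeric(clinical["grade"], errors="coerce")
        ok = grade.notna() & grade.isin([1, 2, 3, 4])
        labels = (grade[ok] >= 3).astype(int)
    elif task.startswith("rfs"):
        year = int(task[3:])
        if not 1 <= year <= 5:
            raise ValueError("RFS cutoff must lie in 1..5 years")
        col = f"rfs_free_at_{year}"
        if col in clinical.columns:
            raw = pd.to_numeric(clinical[col], errors="coerce")
            labels = raw.dropna().astype(int)
        else:
            t = pd.to_numeric(clinical["recurrence_years"], errors="coerce")
            labels = pd.Series(
                np.where(t.isna() | (t > year), 1, 0), index=clinical.index
            )
    else:
        raise ValueError(f"unknown task {task!r}")
    dropped = len(clinical) - len(labels)
    if dropped:
        logger.info("task %s: %d rows without outcome excluded", task, dropped)
    return labels.rename(task)


@dataclass
class NestedCVResult:
    """Outer-fold AUCs, bootstrap summary and feature-selection tallies."""

    classifier_id: str
    task: str
    aucs: np.ndarray  # reps * outer_folds values
    mean_auc: float
    ci95: tuple[float, float]
    tallies: pd.Series  # per-feature count of outer fits selecting it
    max_cv_count: int
    chosen_params: list[dict]
    has_coefficients: bool = True

    @property
    def top_features(self) -> list[tuple[str, float]]:
        props = (self.tallies / self.max_cv_count).sort_values(ascending=False)
        # ties broken alphabetically for a stable ranking
        ordered = sorted(props.items(), key=lambda kv: (-kv[1], kv[0]))
        return [(name, float(p)) for name, p in ordered[:10]]


def _zscore_fit(x: np.ndarray):
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def _score(model, x: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(x)[:, 1]
    return model.decision_function(x)


def _coef_selected(model, regularization: str) -> np.ndarray:
    coef = np.abs(np.ravel(model.coef_))
    threshold = 0.01 if regularization == "L2" else 0.0
    return coef > threshold


def nested_cv_auc(
    x: pd.DataFrame,
    y: pd.Series,
    spec: ClassifierSpec,
    outer_folds: int = 3,
    inner_folds: int = 3,
    reps: int = 1000,
    seed: int = 0,
) -> NestedCVResult:
    """Repeated stratified nested cross-validation AUC for one classifier.

    Per repetition and outer fold: z-score with outer-train statistics
    (population SD), pick the grid point with the best inner-CV mean AUC
    (ties to the smallest C, i.e. the strongest penalty), refit on the outer
    training set and score AUC on the outer test fold. All reps*outer_folds
    AUCs are kept; coefficient-bearing models contribute to the selection
    tallies. Deterministic for a fixed seed.
    """
    x = x.loc[y.index]
    xv = x.to_numpy(dtype=np.float64)
    yv = y.to_numpy(dtype=int)
    classes = np.unique(yv)
    if classes.size != 2:
        raise ValueError("nested CV needs both classes present")
    rng = np.random.default_rng(seed)
    grid = spec.grid_points()
    aucs: list[float] = []
    tallies = np.zeros(xv.shape[1])
    chosen: list[dict] = []

    rep = 0
    attempts = 0
    while rep < reps:
        attempts += 1
        if attempts > 10 * reps + 10:
            raise RuntimeError("could not form stratified folds with both classes")
        split_seed = int(rng.integers(2**31 - 1))
        outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=split_seed)
        folds = list(outer.split(xv, yv))
        if any(np.unique(yv[te]).size < 2 for _, te in folds):
            logger.warning("a fold lost a class; reshuffling repetition")
            continue
        rep += 1
        for train_idx, test_idx in folds:
            xtr_raw, ytr = xv[train_idx], yv[train_idx]
            mu, sd = _zscore_fit(xtr_raw)
            xtr = (xtr_raw - mu) / sd
            xte = (xv[test_idx] - mu) / sd
            fit_seed = int(rng.integers(2**31 - 1))
            if len(grid) == 1:
                best = grid[0]
            else:
                best, best_score = None, -np.inf
                inner = StratifiedKFold(
                    n_splits=inner_folds, shuffle=True, random_state=fit_seed
                )
                inner_folds_idx = list(inner.split(xtr, ytr))
                for params in grid:
                    scores = []
                    for itr, ite in inner_folds_idx:
                        if np.unique(ytr[ite]).size < 2:
                            continue
                        model = spec.build(params, fit_seed)
                        model.fit(xtr[itr], ytr[itr])
                        scores.append(roc_auc_score(ytr[ite], _score(model, xtr[ite])))
                    mean_score = float(np.mean(scores)) if scores else -np.inf
                    if mean_score > best_score + 1e-12:
                        best, best_score = params, mean_score
            chosen.append(best)
            model = spec.build(best, fit_seed)
            model.fit(xtr, ytr)
            aucs.append(float(roc_auc_score(yv[test_idx], _score(model, xte))))
            if spec.has_coefficients:
                tallies += _coef_selected(model, spec.regularization)

    aucs_arr = np.asarray(aucs)
    mean, ci = bootstrap_summary(aucs_arr, seed=int(rng.integers(2**31 - 1)))
    return NestedCVResult(
        classifier_id=spec.classifier_id,
        task=str(y.name),
        aucs=aucs_arr,
        mean_auc=mean,
        ci95=ci,
        tallies=pd.Series(tallies, index=x.columns, dtype=int),
        max_cv_count=reps * outer_folds,
        chosen_params=chosen,
        has_coefficients=spec.has_coefficients,
    )


def bootstrap_summary(
    aucs, n_boot: int = 1000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Mean AUC and percentile 95% CI from bootstrap resamples of the AUC list."""
    aucs = np.asarray(aucs, dtype=np.float64)
    if aucs.size < 2:
        raise ValueError("need >= 2 AUC values")
    rng = np.random.default_rng(seed)
    means = rng.choice(aucs, size=(n_boot, aucs.size), replace=True).mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(aucs.mean()), (float(lo), float(hi))


def tally_feature_importance(result: NestedCVResult, top: int = 10) -> pd.DataFrame:
    """Ranked selection proportions (count / max_cv_count) for the top features."""
    if not result.has_coefficients:
        raise ValueError(
            "coefficient tallies exist only for logistic families; use permutation "
            "importance for kernel SVM / random forest"
        )
    if result.tallies.sum() == 0 and result.max_cv_count > 0:
        logger.warning("no feature was ever selected")
    props = result.tallies / result.max_cv_count
    frame = pd.DataFrame(
        {"count": result.tallies, "proportion": props}
    ).sort_index()
    frame = frame.sort_values(
        by=["proportion", "count"], ascending=False, kind="stable"
    )
    return frame.head(top)
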