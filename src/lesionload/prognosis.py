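"""Prognostic modelling of long-term IPS outcome from lesion-load features.

A linear maximum-margin classifier with recursive feature elimination
(SVM-RFE) classifies recovered (+1) versus not-recovered (-1) patients;
validation is leave-one-subject-out cross-validation (LOOCV), repeated
random subsampling (test sizes 1..8) for confidence intervals, and a
label-permutation test for significance.  Support vector regression
predicts continuous neuropsychological scores with the classifier's
feature subset.  Serum cytokine features can be concatenated as a second
predictor domain, and a frozen model is applied once to an external
replicate cohort.

Conventions fixed throughout: features are z-standardized inside each
training fold (RFE weight ranking is scale dependent); sensitivity is
anchored to the -1 not-recovered class as the clinically positive class;
the permutation p-value uses add-one smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, SVR

__all__ = [
    "SVMRFEClassifier",
    "RFEResult",
    "ModelReport",
    "RegressionReport",
    "GroupStats",
    "ImportanceFilterResult",
    "rfe_select",
    "loocv_classify",
    "repeated_subsampling",
    "subsampling_report",
    "permutation_test",
    "svr_predict",
    "combine_domains",
    "external_validate",
    "importance_filter",
    "group_stats",
]

POSITIVE_CLASS = -1  # not recovered: the clinically positive class
_POSITIVE_NOTE = "sensitivity anchored to the -1 (not-recovered) class"


def _svc(C: float) -> SVC:
    """Linear maximum-margin classifier used throughout.

    Class weights are balanced: the not-recovered class is the clinically
    positive minority (~33%), and an unweighted hinge loss would default
    to majority-class predictions whenever the signal is weak, both
    hurting sensitivity and pinning null-data accuracy at the majority
    rate instead of chance.
    """
    return SVC(kernel="linear", C=C, class_weight="balanced")


def _as_matrix(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), [str(c) for c in features.columns]
    X = np.asarray(features, dtype=float)
    return X, [str(i) for i in range(X.shape[1])]


def _as_labels(y, n: int) -> np.ndarray:
    y = np.asarray(y).astype(int).ravel()
    if y.size != n:
        raise ValueError(f"{n} samples but {y.size} labels")
    if not set(np.unique(y)) <= {-1, 1}:
        raise ValueError("labels must be coded +1 (recovered) / -1 (not recovered)")
    return y


def _zfit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


def _inner_accuracy(
    X: np.ndarray, y: np.ndarray, C: float, inner_cv, seed: int
) -> float:
    """Cross-validated accuracy with per-fold standardization."""
    n = y.size
    if inner_cv == "loo":
        splits = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    else:
        counts = np.bincount((y > 0).astype(int), minlength=2)
        n_splits = int(min(inner_cv, counts.min()))
        if n_splits < 2:
            return np.nan
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
    correct = 0
    total = 0
    for tr, te in splits:
        if np.unique(y[tr]).size < 2:
            continue
        mean, sd = _zfit(X[tr])
        clf = _svc(C)
        clf.fit((X[tr] - mean) / sd, y[tr])
        correct += int(np.sum(clf.predict((X[te] - mean) / sd) == y[te]))
        total += te.size
    return correct / total if total else np.nan


class SVMRFEClassifier(BaseEstimator, ClassifierMixin):
    """Linear SVM with recursive feature elimination.

    At each step a linear-kernel SVM is fit on the standardized surviving
    features, the feature with the smallest absolute weight is removed,
    and the step's cross-validated accuracy (on training data only) is
    recorded; the surviving subset with the best accuracy wins, ties
    broken toward fewer features.  The final model is refit on that subset
    and its absolute weights are max-normalized, so the top-ranked feature
    always has weight 1.

    Parameters
    ----------
    C : float
        Margin regularization constant (default 1).
    inner_cv : int or "loo"
        Folds of the per-step accuracy estimate; stratified k-fold by
        default, exhaustive leave-one-out with ``"loo"``.
    seed : int
        Shuffling seed of the inner folds.
    """

    def __init__(self, C: float = 1.0, inner_cv=5, seed: int = 0):
        self.C = C
        self.inner_cv = inner_cv
        self.seed = seed

    def fit(self, X, y) -> "SVMRFEClassifier":
        X, names = _as_matrix(X)
        y = _as_labels(y, X.shape[0])
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("both classes must be present to fit the classifier")
        if X.shape[1] < 1:
            raise ValueError("at least one feature is required")
        self.feature_names_in_ = np.array(names)
        self.classes_ = classes

        remaining = list(range(X.shape[1]))
        elimination: list[int] = []
        path: list[tuple[int, float, list[int]]] = []
        while remaining:
            acc = _inner_accuracy(X[:, remaining], y, self.C, self.inner_cv, self.seed)
            path.append((len(remaining), acc, list(remaining)))
            mean, sd = _zfit(X[:, remaining])
            clf = _svc(self.C)
            clf.fit((X[:, remaining] - mean) / sd, y)
            w = np.abs(clf.coef_).ravel()
            worst = remaining[int(np.argmin(w))]
            elimination.append(worst)
            remaining.remove(worst)

        # best cross-validated accuracy; ties -> fewer features
        best = max(path, key=lambda t: (np.nan_to_num(t[1], nan=-1.0), -t[0]))
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[best[2]] = True
        self.elimination_order_ = np.array(elimination)
        self.step_scores_ = pd.DataFrame(
            [(n, a) for n, a, _ in path], columns=["n_features", "cv_accuracy"]
        )
        sub = np.flatnonzero(self.support_)
        self.scaler_mean_, self.scaler_sd_ = _zfit(X[:, sub])
        self.svm_ = _svc(self.C)
        self.svm_.fit((X[:, sub] - self.scaler_mean_) / self.scaler_sd_, y)
        w = np.abs(self.svm_.coef_).ravel()
        self.weights_ = w / w.max()
        self.n_features_in_ = X.shape[1]
        return self

    def _matrix_for_predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            # column-order invariance: align on names seen at fit time
            missing = [c for c in self.feature_names_in_ if c not in X.columns]
            if missing:
                raise ValueError(f"missing catalogue features: {missing}")
            return X.loc[:, list(self.feature_names_in_)].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def decision_function(self, X) -> np.ndarray:
        X = self._matrix_for_predict(X)
        sub = np.flatnonzero(self.support_)
        return self.svm_.decision_function((X[:, sub] - self.scaler_mean_) / self.scaler_sd_)

    def predict(self, X) -> np.ndarray:
        X = self._matrix_for_predict(X)
        sub = np.flatnonzero(self.support_)
        return self.svm_.predict((X[:, sub] - self.scaler_mean_) / self.scaler_sd_)


@dataclass
class RFEResult:
    """Outcome of one recursive-feature-elimination run."""

    elimination_order: list[str]  # worst first
    step_accuracies: pd.DataFrame  # n_features, cv_accuracy
    subset: list[str]  # optimal feature subset
    weights: pd.Series  # max-normalized |w| on the subset
    estimator: SVMRFEClassifier

    def __post_init__(self) -> None:
        if not self.subset:
            raise ValueError("optimal subset must be non-empty")
        if not np.isclose(self.weights.max(), 1.0):
            raise ValueError("max normalized weight must be 1")


def rfe_select(
    features: pd.DataFrame, labels, C: float = 1.0, inner_cv=5, seed: int = 0
) -> RFEResult:
    """Rank features by SVM weight and keep the best-accuracy subset."""
    if features.shape[1] < 2:
        raise ValueError("RFE needs at least 2 features")
    est = SVMRFEClassifier(C=C, inner_cv=inner_cv, seed=seed).fit(features, labels)
    names = est.feature_names_in_
    subset = [str(n) for n in names[est.support_]]
    return RFEResult(
        elimination_order=[str(names[i]) for i in est.elimination_order_],
        step_accuracies=est.step_scores_,
        subset=subset,
        weights=pd.Series(est.weights_, index=subset, name="weight"),
        estimator=est,
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


@dataclass
class ModelReport:
    """Classification performance with the study's reporting conventions."""

    accuracy: float  # percent
    sensitivity: float  # percent, recall of the -1 class
    specificity: float  # percent, recall of the +1 class
    confusion: dict  # tp / tn / fp / fn with positive = -1
    predictions: pd.Series
    ci: dict = field(default_factory=dict)  # metric -> (lo, hi) percent
    permutation_p: float | None = None
    subsampling: pd.DataFrame | None = None  # per-n accuracy summaries
    notes: list[str] = field(default_factory=lambda: [_POSITIVE_NOTE])

    def __post_init__(self) -> None:
        c = self.confusion
        n = sum(c.values())
        if n and not np.isclose(self.accuracy, 100.0 * (c["tp"] + c["tn"]) / n):
            raise ValueError("accuracy inconsistent with confusion counts")
        for lo, hi in self.ci.values():
            if lo > hi:
                raise ValueError("CI bounds out of order")

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion": self.confusion,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "permutation_p": self.permutation_p,
            "notes": self.notes,
        }


def _report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray, index) -> ModelReport:
    pos = y_true == POSITIVE_CLASS
    tp = int(np.sum(pos & (y_pred == POSITIVE_CLASS)))
    fn = int(np.sum(pos & (y_pred != POSITIVE_CLASS)))
    tn = int(np.sum(~pos & (y_pred != POSITIVE_CLASS)))
    fp = int(np.sum(~pos & (y_pred == POSITIVE_CLASS)))
    n = y_true.size
    return ModelReport(
        accuracy=100.0 * (tp + tn) / n,
        sensitivity=100.0 * tp / (tp + fn) if tp + fn else np.nan,
        specificity=100.0 * tn / (tn + fp) if tn + fp else np.nan,
        confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
        predictions=pd.Series(y_pred, index=index, name="predicted"),
    )


@dataclass
class RegressionReport:
    """Predicted-vs-actual continuous scores with Spearman correlation."""

    predicted: pd.Series
    actual: pd.Series
    rho: float
    rho_ci: tuple[float, float]
    p_value: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0 + 1e-12:
            raise ValueError("|rho| must not exceed 1")

    def to_dict(self) -> dict:
        return {"rho": self.rho, "rho_ci": list(self.rho_ci), "p_value": self.p_value}


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _subset_matrix(features: pd.DataFrame, subset: list[str]) -> np.ndarray:
    missing = [c for c in subset if c not in features.columns]
    if missing:
        raise ValueError(f"missing catalogue features: {missing}")
    return features.loc[:, list(subset)].to_numpy(dtype=float)


def _loocv_predictions(
    X: np.ndarray, y: np.ndarray, C: float
) -> np.ndarray:
    """LOOCV with a fixed feature set; standardization refit in each fold."""
    n = y.size
    pred = np.empty(n, dtype=int)
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        mean, sd = _zfit(X[tr])
        clf = _svc(C)
        clf.fit((X[tr] - mean) / sd, y[tr])
        pred[i] = clf.predict(((X[i] - mean) / sd)[None, :])[0]
    return pred


def loocv_classify(
    features: pd.DataFrame,
    labels,
    subset: list[str] | None = None,
    refit_rfe: bool = False,
    C: float = 1.0,
    inner_cv=5,
    seed: int = 0,
) -> ModelReport:
    """Leave-one-subject-out cross-validated classification report.

    With ``subset`` given, each fold standardizes and refits the SVM on
    that fixed feature set (the feature list itself was chosen elsewhere).
    With ``refit_rfe=True`` the whole selection pipeline -- RFE included --
    is rerun inside every fold, which is the leakage-free mode.
    """
    X, names = _as_matrix(features)
    y = _as_labels(labels, X.shape[0])
    if y.size < 4:
        raise ValueError("need at least 4 subjects for LOOCV")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    index = features.index if isinstance(features, pd.DataFrame) else np.arange(y.size)
    if refit_rfe:
        pred = np.empty(y.size, dtype=int)
        for i in range(y.size):
            tr = np.delete(np.arange(y.size), i)
            est = SVMRFEClassifier(C=C, inner_cv=inner_cv, seed=seed)
            est.fit(pd.DataFrame(X[tr], columns=names), y[tr])
            pred[i] = est.predict(pd.DataFrame(X[i : i + 1], columns=names))[0]
        report = _report_from_predictions(y, pred, index)
        report.notes.append("RFE refit inside every LOOCV fold")
        return report
    if subset is None or not list(subset):
        raise ValueError("feature subset must be non-empty (or pass refit_rfe=True)")
    Xs = _subset_matrix(
        features if isinstance(features, pd.DataFrame) else pd.DataFrame(X, columns=names),
        list(subset),
    )
    return _report_from_predictions(y, _loocv_predictions(Xs, y, C), index)


def repeated_subsampling(
    features: pd.DataFrame,
    labels,
    subset: list[str],
    n_test: int,
    reps: int = 1000,
    seed: int = 0,
    C: float = 1.0,
    exhaustive: bool = False,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Random test sets of size ``n_test``; per-rep metrics and 95% CI.

    Returns a per-rep DataFrame (accuracy / sensitivity / specificity, in
    percent; sensitivity or specificity is NaN when the test draw lacks
    that class) and the 2.5/97.5 percentile CI of the accuracy
    distribution.  Deterministic given ``seed``.  With
    ``exhaustive=True`` and ``n_test=1`` every subject is held out exactly
    once, which reduces to LOOCV.
    """
    X = _subset_matrix(features, list(subset))
    y = _as_labels(labels, X.shape[0])
    n = y.size
    if n_test >= n:
        raise ValueError(f"n_test={n_test} must be smaller than n={n}")
    if exhaustive:
        if n_test != 1:
            raise ValueError("exhaustive mode requires n_test=1")
        draws = [np.array([i]) for i in range(n)]
    else:
        if reps < 100:
            raise ValueError("reps must be >= 100")
        draws = None
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(len(draws) if draws is not None else reps):
        if draws is not None:
            te = draws[r]
            tr = np.setdiff1d(np.arange(n), te)
        else:
            while True:
                te = rng.choice(n, size=n_test, replace=False)
                tr = np.setdiff1d(np.arange(n), te)
                if np.unique(y[tr]).size == 2:
                    break
        mean, sd = _zfit(X[tr])
        clf = _svc(C)
        clf.fit((X[tr] - mean) / sd, y[tr])
        pred = clf.predict((X[te] - mean) / sd)
        pos = y[te] == POSITIVE_CLASS
        rows.append(
            {
                "accuracy": 100.0 * np.mean(pred == y[te]),
                "sensitivity": 100.0 * np.mean(pred[pos] == POSITIVE_CLASS) if pos.any() else np.nan,
                "specificity": 100.0 * np.mean(pred[~pos] != POSITIVE_CLASS) if (~pos).any() else np.nan,
            }
        )
    dist = pd.DataFrame(rows)
    ci = tuple(np.percentile(dist["accuracy"], [2.5, 97.5]))
    return dist, (float(ci[0]), float(ci[1]))


def subsampling_report(
    features: pd.DataFrame,
    labels,
    subset: list[str],
    n_values=range(1, 9),
    reps: int = 200,
    seed: int = 0,
    C: float = 1.0,
) -> pd.DataFrame:
    """Accuracy distribution summaries for each test-set size n."""
    rows = []
    for i, n_test in enumerate(n_values):
        dist, ci = repeated_subsampling(
            features, labels, subset, n_test, reps=reps, seed=seed + i, C=C
        )
        rows.append(
            {
                "n_test": n_test,
                "mean_accuracy": float(dist["accuracy"].mean()),
                "ci_lo": ci[0],
                "ci_hi": ci[1],
                "mean_sensitivity": float(dist["sensitivity"].mean(skipna=True)),
                "mean_specificity": float(dist["specificity"].mean(skipna=True)),
            }
        )
    return pd.DataFrame(rows)


def permutation_test(
    features: pd.DataFrame,
    labels,
    subset: list[str] | None = None,
    n_perm: int = 5000,
    seed: int = 0,
    mode: str = "fast",
    C: float = 1.0,
    inner_cv=5,
) -> tuple[float, float, np.ndarray]:
    """Label-permutation null of the LOOCV accuracy.

    ``mode='full'`` reruns feature selection inside every permutation (the
    conservative, expensive null); ``mode='fast'`` keeps the given subset
    fixed and is labelled as such in reports.  Permutations preserve class
    counts; p uses add-one smoothing: (1 + #{perm >= observed}) / (1 + n_perm).
    Returns (p, observed accuracy %, permuted accuracies %).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("fast", "full"):
        raise ValueError("mode must be 'fast' or 'full'")
    y = _as_labels(labels, len(features))
    rng = np.random.default_rng(seed)

    def acc(y_cur: np.ndarray) -> float:
        if mode == "full":
            rep = loocv_classify(
                features, y_cur, refit_rfe=True, C=C, inner_cv=inner_cv, seed=seed
            )
        else:
            rep = loocv_classify(features, y_cur, subset=subset, C=C)
        return rep.accuracy

    observed = acc(y)
    perm = np.empty(n_perm)
    for b in range(n_perm):
        perm[b] = acc(rng.permutation(y))
    p = (1.0 + np.sum(perm >= observed)) / (1.0 + n_perm)
    return float(p), observed, perm


def svr_predict(
    features: pd.DataFrame,
    scores,
    subset: list[str],
    C: float = 1.0,
    epsilon: float = 0.1,
    n_boot: int = 1000,
    seed: int = 0,
) -> RegressionReport:
    """LOOCV support-vector regression of a continuous score.

    Uses the classification-selected subset unchanged (no re-selection for
    a second score).  Features and the score are standardized per training
    fold (epsilon is therefore in SD units of the score); Spearman rho of
    predicted vs actual carries a subject-bootstrap percentile CI.
    """
    s = np.asarray(scores, dtype=float).ravel()
    if np.ptp(s) == 0:
        raise ValueError("scores are constant: rank correlation undefined")
    X = _subset_matrix(features, list(subset))
    n = s.size
    if X.shape[0] != n:
        raise ValueError(f"{X.shape[0]} feature rows but {n} scores")
    pred = np.empty(n)
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        mean, sd = _zfit(X[tr])
        s_mean, s_sd = s[tr].mean(), s[tr].std() or 1.0
        reg = SVR(kernel="linear", C=C, epsilon=epsilon)
        reg.fit((X[tr] - mean) / sd, (s[tr] - s_mean) / s_sd)
        pred[i] = reg.predict(((X[i] - mean) / sd)[None, :])[0] * s_sd + s_mean
    rho, p = stats.spearmanr(pred, s)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if np.ptp(s[idx]) == 0 or np.ptp(pred[idx]) == 0:
            continue
        boots.append(stats.spearmanr(pred[idx], s[idx]).statistic)
    ci = tuple(np.percentile(boots, [2.5, 97.5])) if boots else (np.nan, np.nan)
    index = features.index
    return RegressionReport(
        predicted=pd.Series(pred, index=index, name="predicted"),
        actual=pd.Series(s, index=index, name="actual"),
        rho=float(rho),
        rho_ci=(float(ci[0]), float(ci[1])),
        p_value=float(p),
    )


# ---------------------------------------------------------------------------
# domains, external validation, importance filtering, group stats
# ---------------------------------------------------------------------------


def combine_domains(
    fa_features: pd.DataFrame, cytokine_features: pd.DataFrame | None
) -> pd.DataFrame:
    """Concatenate imaging and cytokine domains, each standardized apart.

    Both tables must cover the same subjects in the same order; each
    domain is z-scored column-wise before concatenation so neither
    dominates by raw scale.  ``df.attrs['domain']`` records the domain of
    every column.
    """
    if cytokine_features is None or cytokine_features.shape[1] == 0:
        out = fa_features.copy()
        out.attrs = dict(fa_features.attrs)
        out.attrs.setdefault("domain", {c: "fa" for c in out.columns})
        return out
    if list(fa_features.index) != list(cytokine_features.index):
        diff = set(fa_features.index).symmetric_difference(cytokine_features.index)
        raise ValueError(f"subject mismatch between domains: {sorted(map(str, diff))}")

    def z(df: pd.DataFrame) -> pd.DataFrame:
        sd = df.std(ddof=0).replace(0, 1.0)
        return (df - df.mean()) / sd

    out = pd.concat([z(fa_features), z(cytokine_features)], axis=1)
    out.attrs["clusters"] = dict(fa_features.attrs.get("clusters", {}))
    out.attrs["domain"] = {
        **{c: "fa" for c in fa_features.columns},
        **{c: "cytokine" for c in cytokine_features.columns},
    }
    return out


def external_validate(
    model: SVMRFEClassifier, features: pd.DataFrame, labels
) -> ModelReport:
    """Apply a frozen, already-fitted model once to an external cohort.

    No refitting of any kind: the original standardization, subset and
    weight vector are reused, so identical inputs give bit-identical
    reports.  Replicate features must have been cut with the original
    cohort's catalogue and normative model.
    """
    y = _as_labels(labels, len(features))
    pred = model.predict(features)  # raises if any catalogue feature is missing
    report = _report_from_predictions(y, pred, features.index)
    report.notes.append("frozen model: external validation, no refitting")
    return report


@dataclass
class GroupStats:
    """Two-sample comparison with the normality-gated test choice."""

    test: str  # "t" | "ranksum"
    statistic: float
    p_value: float
    cohens_d: float
    mean_diff_ci: tuple[float, float]
    shapiro_p: tuple[float, float]


def group_stats(
    x, y, alpha_normality: float = 0.05, n_boot: int = 2000, seed: int = 0
) -> GroupStats:
    """Compare two groups the way the clinical tables are compared.

    Shapiro-Wilk on each group selects Student's t (both normal) or the
    Mann-Whitney rank-sum test; Cohen's d uses the pooled SD; the mean
    difference carries a percentile-bootstrap CI.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least 3 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("zero variance in both groups")
    sw = []
    normal = []
    for g in (x, y):
        if np.ptp(g) == 0:
            sw.append(0.0)
            normal.append(False)
        else:
            p = float(stats.shapiro(g).pvalue)
            sw.append(p)
            normal.append(p >= alpha_normality)
    if all(normal):
        test, res = "t", stats.ttest_ind(x, y)
    else:
        test, res = "ranksum", stats.mannwhitneyu(x, y, alternative="two-sided")
    pooled = np.sqrt(
        ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
        / (x.size + y.size - 2)
    )
    d = (x.mean() - y.mean()) / pooled if pooled > 0 else 0.0
    rng = np.random.default_rng(seed)
    diffs = [
        x[rng.integers(0, x.size, x.size)].mean() - y[rng.integers(0, y.size, y.size)].mean()
        for _ in range(n_boot)
    ]
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return GroupStats(
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        cohens_d=float(d),
        mean_diff_ci=(float(lo), float(hi)),
        shapiro_p=(sw[0], sw[1]),
    )


@dataclass
class ImportanceFilterResult:
    """Top-weight clusters surviving Bonferroni-corrected group tests."""

    selected: list[str]
    table: pd.DataFrame
    n_fibers: int
    n_top: int
    p_threshold: float


def importance_filter(
    rfe_result: RFEResult,
    features: pd.DataFrame,
    group_labels,
    seed: int = 0,
) -> ImportanceFilterResult:
    """Reduce the selected clusters to the most important predictors.

    Keeps clusters whose normalized weight ranks in the top 25% of the
    distinct fiber count (m = floor(0.25 * n_fibers), at least 1), then
    requires each to differ between not-recovered and recovered patients
    AND between not-recovered patients and controls at the Bonferroni
    level p < 0.05 / m.

    ``group_labels`` maps each feature row to one of
    {"nonrecovered", "recovered", "control"}.
    """
    groups = pd.Series(group_labels, index=features.index)
    masks = {g: groups == g for g in ("nonrecovered", "recovered", "control")}
    for g, m in masks.items():
        if not m.any():
            raise ValueError(f"group '{g}' is empty")
    meta = features.attrs.get("clusters", {})
    fibers = {
        meta.get(c, {}).get("tract_name", str(c).rsplit("_", 2)[0])
        for c in rfe_result.subset
    }
    n_fibers = len(fibers)
    n_top = max(1, int(np.floor(0.25 * n_fibers)))
    top = list(rfe_result.weights.sort_values(ascending=False).index[:n_top])
    p_threshold = 0.05 / n_top
    rows = []
    selected = []
    for cid in top:
        vals = features[cid]
        p1 = group_stats(
            vals[masks["nonrecovered"]], vals[masks["recovered"]], seed=seed
        ).p_value
        p2 = group_stats(
            vals[masks["nonrecovered"]], vals[masks["control"]], seed=seed
        ).p_value
        keep = (p1 < p_threshold) and (p2 < p_threshold)
        if keep:
            selected.append(cid)
        rows.append(
            {
                "cluster": cid,
                "weight": float(rfe_result.weights[cid]),
                "p_vs_recovered": p1,
                "p_vs_controls": p2,
                "selected": keep,
            }
        )
    return ImportanceFilterResult(
        selected=selected,
        table=pd.DataFrame(rows),
        n_fibers=n_fibers,
        n_top=n_top,
        p_threshold=p_threshold,
    )
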