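"""Diagnostic validation of the phenotype similarity score.

The question answered here: does the mean phenotype similarity score
discriminate patients with an mt-aaRS diagnosis from patients with other
molecular diagnoses?  Two classifiers are fitted on a labelled cohort —
a logistic regression on the similarity score alone, and a 500-tree random
forest on similarity + term count + average IC — with a stratified 80/20
split, optional class balancing, and 5-fold cross-validation.  Performance
is summarised with confusion metrics, ROC curves, AUC with DeLong 95%
confidence intervals, and the Youden-optimal operating threshold mapped
back to the similarity scale.

The API follows the Model/Results convention: build a
:class:`DiagnosticModel` from a labelled DataFrame, call :meth:`fit`, and
interrogate the returned :class:`DiagnosticResults` (``summary()``,
``evaluate()``, ``roc()``, ``youden()``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "PREDICTORS_GLM",
    "PREDICTORS_RF",
    "MetricsSet",
    "RocResult",
    "build_modelling_dataset",
    "confusion_metrics",
    "roc_auc_delong",
    "youden_threshold",
    "DiagnosticModel",
    "DiagnosticResults",
    "fit_logistic",
    "fit_random_forest",
]

PREDICTORS_GLM: tuple[str, ...] = ("mean_similarity",)
PREDICTORS_RF: tuple[str, ...] = ("mean_similarity", "term_count", "average_ic")


# ---------------------------------------------------------------------------
# dataset assembly


def build_modelling_dataset(
    positives: pd.DataFrame,
    negatives: pd.DataFrame,
    balance: bool = True,
    seed: int = 0,
    train_fraction: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble and split the labelled modelling dataset.

    ``positives``/``negatives`` carry one row per individual with at least
    the predictor columns (``mean_similarity``, ``term_count``,
    ``average_ic``).  With ``balance`` the larger class is subsampled
    without replacement (seeded) to the size of the smaller one.  The 80/20
    split is stratified, rounding the per-class training count to the
    nearest integer.  Returns ``(train, test)`` frames with a binary
    ``label`` column (1 = positive class).
    """
    if len(positives) == 0 or len(negatives) == 0:
        raise ValueError("both classes must be non-empty")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    pos = positives.copy()
    neg = negatives.copy()
    pos["label"] = 1
    neg["label"] = 0
    if balance and len(neg) != len(pos):
        target = min(len(pos), len(neg))
        larger = neg if len(neg) > len(pos) else pos
        keep = rng.choice(len(larger), size=target, replace=False)
        subsampled = larger.iloc[np.sort(keep)]
        if larger is neg:
            neg = subsampled
        else:
            pos = subsampled

    train_parts, test_parts = [], []
    for frame in (pos, neg):
        order = rng.permutation(len(frame))
        n_train = int(round(train_fraction * len(frame)))
        n_train = min(max(n_train, 1), len(frame) - 1) if len(frame) > 1 else n_train
        train_parts.append(frame.iloc[order[:n_train]])
        test_parts.append(frame.iloc[order[n_train:]])
    train = pd.concat(train_parts, ignore_index=True)
    test = pd.concat(test_parts, ignore_index=True)
    return train, test


# ---------------------------------------------------------------------------
# confusion metrics


@dataclass(frozen=True)
class MetricsSet:
    """Confusion-matrix summary; undefined ratios surface as NaN."""

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    balanced_accuracy: float
    kappa: float
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "balanced_accuracy": self.balanced_accuracy,
            "kappa": self.kappa,
        }


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", RuntimeWarning)
        return float("nan")
    return num / den


def confusion_metrics(y_true: Sequence[int], y_pred: Sequence[int]) -> MetricsSet:
    """Accuracy, sensitivity, specificity, PPV, NPV, balanced accuracy, kappa."""
    t = np.asarray(y_true, dtype=int)
    yhat = np.asarray(y_pred, dtype=int)
    if t.shape != yhat.shape:
        raise ValueError("prediction/truth length mismatch")
    if len(set(t.tolist())) < 2:
        raise ValueError("both classes must be present in the truth labels")
    tp = int(np.sum((t == 1) & (yhat == 1)))
    fn = int(np.sum((t == 1) & (yhat == 0)))
    fp = int(np.sum((t == 0) & (yhat == 1)))
    tn = int(np.sum((t == 0) & (yhat == 0)))
    n = tp + fn + fp + tn
    sens = _safe_ratio(tp, tp + fn, "sensitivity")
    spec = _safe_ratio(tn, tn + fp, "specificity")
    p_o = (tp + tn) / n
    p_e = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / (n * n)
    kappa = _safe_ratio(p_o - p_e, 1 - p_e, "kappa")
    return MetricsSet(
        accuracy=p_o,
        sensitivity=sens,
        specificity=spec,
        ppv=_safe_ratio(tp, tp + fp, "PPV"),
        npv=_safe_ratio(tn, tn + fn, "NPV"),
        balanced_accuracy=0.5 * (sens + spec),
        kappa=kappa,
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
    )


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong / Youden


@dataclass(frozen=True)
class RocResult:
    """ROC points, Mann-Whitney AUC and its DeLong confidence interval."""

    thresholds: np.ndarray  # cutpoints: -inf, midpoints, +inf
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_variance: float
    ci_lower: float
    ci_upper: float

    def points_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def roc_auc_delong(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """AUC as the normalised Mann-Whitney statistic with a DeLong 95% CI.

    Ties across classes count one half.  The variance comes from the sample
    covariance of the DeLong placement values; constant scores yield AUC 0.5
    with a degenerate interval and a warning.  ROC points are evaluated at
    midpoints between consecutive distinct scores plus the two infinite
    endpoints, predicting positive at ``score >= threshold``.
    """
    y = np.asarray(labels, dtype=int)
    x = np.asarray(scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("scores/labels length mismatch")
    pos = x[y == 1]
    neg = x[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")

    allx = np.concatenate([pos, neg])
    tz = _midrank(allx)
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # placement values of positives
    v10 = 1.0 - (tz[m:] - ty) / m  # placement values of negatives
    if m > 1 and n > 1:
        var = np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n
    else:
        var = float("nan")
    if np.all(allx == allx[0]):
        warnings.warn("constant scores: degenerate ROC, AUC 0.5", RuntimeWarning)
    if not math.isnan(var) and var > 0:
        half = 1.96 * math.sqrt(var)
        lo, hi = max(0.0, auc - half), min(1.0, auc + half)
    else:
        if var == 0:
            warnings.warn("zero DeLong variance: degenerate CI", RuntimeWarning)
        lo = hi = auc
        var = 0.0 if math.isnan(var) else var

    distinct = np.unique(allx)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        auc_variance=float(var),
        ci_lower=float(lo),
        ci_upper=float(hi),
    )


def youden_threshold(
    roc: RocResult,
    similarity: Sequence[float] | None = None,
    scores: Sequence[float] | None = None,
    logistic_params: tuple[float, float] | None = None,
) -> dict[str, float]:
    """Youden-optimal cutpoint and its similarity-scale operating point.

    Maximises ``J = sensitivity + specificity - 1`` over the ROC cutpoints,
    breaking ties toward the lowest threshold.  The similarity value at the
    operating point is the closed-form inverse of the fitted logit when
    ``logistic_params = (intercept, slope)`` is given (slope > 0); otherwise
    it is found by quantile matching: the similarity value whose exceedance
    fraction equals the fraction of model scores at or above the threshold.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    idx = int(np.argmax(j))  # argmax returns the first (lowest) maximiser
    thr = float(roc.thresholds[idx])
    out = {
        "threshold": thr,
        "sensitivity": float(roc.sensitivity[idx]),
        "specificity": float(roc.specificity[idx]),
        "j": float(j[idx]),
    }
    sim_value = float("nan")
    if logistic_params is not None and np.isfinite(thr) and 0.0 < thr < 1.0:
        intercept, slope = logistic_params
        if slope > 0:
            sim_value = (logit(thr) - intercept) / slope
    if math.isnan(sim_value) and similarity is not None and scores is not None:
        sims = np.asarray(similarity, dtype=float)
        sc = np.asarray(scores, dtype=float)
        frac_above = float((sc >= thr).mean())
        if frac_above <= 0.0:
            sim_value = float(sims.max())
        elif frac_above >= 1.0:
            sim_value = float(sims.min())
        else:
            sim_value = float(np.quantile(sims, 1.0 - frac_above, method="midpoint"))
    out["similarity_at_threshold"] = sim_value
    return out


# ---------------------------------------------------------------------------
# Model / Results


class DiagnosticModel:
    """A diagnostic classifier specification bound to a training set.

    Parameters
    ----------
    train
        Labelled DataFrame (``label`` in {0, 1} plus predictor columns).
    kind
        ``"logistic"`` (similarity-only GLM) or ``"random_forest"``
        (similarity + term count + average IC, 500 trees by default).
    """

    def __init__(
        self,
        train: pd.DataFrame,
        kind: str = "logistic",
        predictors: Sequence[str] | None = None,
        n_trees: int = 500,
        folds: int = 5,
        seed: int = 0,
    ) -> None:
        if kind not in ("logistic", "random_forest"):
            raise ValueError(f"unknown model kind {kind!r}")
        if predictors is None:
            predictors = PREDICTORS_GLM if kind == "logistic" else PREDICTORS_RF
        missing = [c for c in (*predictors, "label") if c not in train.columns]
        if missing:
            raise ValueError(f"training frame missing columns: {missing}")
        y = train["label"].to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.train = train.reset_index(drop=True)
        self.kind = kind
        self.predictors = tuple(predictors)
        self.n_trees = n_trees
        self.folds = folds
        self.seed = seed

    @classmethod
    def from_cohorts(
        cls,
        positives: pd.DataFrame,
        negatives: pd.DataFrame,
        kind: str = "logistic",
        balance: bool = True,
        seed: int = 0,
        **kwargs,
    ) -> tuple["DiagnosticModel", pd.DataFrame]:
        """Build (model bound to the train split, held-out test frame)."""
        train, test = build_modelling_dataset(positives, negatives, balance, seed)
        return cls(train, kind=kind, seed=seed, **kwargs), test

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "DiagnosticResults":
        X = self.train[list(self.predictors)].to_numpy(dtype=float)
        y = self.train["label"].to_numpy(dtype=int)
        params: dict[str, float] = {}
        bse: dict[str, float] = {}
        importances: pd.Series | None = None
        guard = False

        if self.kind == "logistic":
            exog = sm.add_constant(X, has_constant="add")
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("error")
                    res = sm.Logit(y, exog).fit(disp=0)
                if not res.mle_retvals.get("converged", True) or not np.all(
                    np.isfinite(res.params)
                ):
                    raise RuntimeError("non-finite or non-converged MLE")
                coef = np.asarray(res.params, dtype=float)
                se = np.asarray(res.bse, dtype=float)
            except Exception:
                # separation guard: near-unpenalised ridge fit
                warnings.warn(
                    "logistic MLE failed (likely complete separation); "
                    "falling back to a weakly penalised fit",
                    RuntimeWarning,
                )
                guard = True
                clf = LogisticRegression(C=1e4, solver="lbfgs", max_iter=5000)
                clf.fit(X, y)
                coef = np.concatenate([clf.intercept_, clf.coef_[0]])
                se = np.full(len(coef), np.nan)
            names = ["intercept", *self.predictors]
            params = dict(zip(names, coef.tolist()))
            bse = dict(zip(names, se.tolist()))
            estimator = None
        else:
            estimator = RandomForestClassifier(
                n_estimators=self.n_trees, random_state=self.seed, n_jobs=1
            )
            estimator.fit(X, y)
            importances = pd.Series(
                estimator.feature_importances_, index=list(self.predictors)
            ).sort_values(ascending=False)

        cv_acc = self._cross_validate(X, y)
        return DiagnosticResults(
            model=self,
            params=params,
            bse=bse,
            estimator=estimator,
            importances=importances,
            cv_accuracies=cv_acc,
            separation_guard=guard,
        )

    def _cross_validate(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Seeded stratified k-fold accuracy of refits (no tuning)."""
        counts = np.bincount(y)
        n_splits = min(self.folds, counts.min())
        if n_splits < 2:
            return np.array([])
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=self.seed)
        accs = []
        for tr, te in skf.split(X, y):
            if len(np.unique(y[tr])) < 2:
                continue
            if self.kind == "logistic":
                clf = LogisticRegression(C=1e4, solver="lbfgs", max_iter=5000)
            else:
                clf = RandomForestClassifier(
                    n_estimators=self.n_trees, random_state=self.seed, n_jobs=1
                )
            clf.fit(X[tr], y[tr])
            accs.append(float((clf.predict(X[te]) == y[te]).mean()))
        return np.asarray(accs)


@dataclass
class DiagnosticResults:
    """Fitted diagnostic model: estimates, CV summary and evaluation tools."""

    model: DiagnosticModel
    params: Mapping[str, float]
    bse: Mapping[str, float]
    estimator: RandomForestClassifier | None
    importances: pd.Series | None
    cv_accuracies: np.ndarray
    separation_guard: bool = False

    # -- prediction --------------------------------------------------------

    def predict_proba(self, data: pd.DataFrame) -> np.ndarray:
        X = data[list(self.model.predictors)].to_numpy(dtype=float)
        if self.model.kind == "logistic":
            eta = self.params["intercept"] + X @ np.array(
                [self.params[p] for p in self.model.predictors]
            )
            return expit(eta)
        return self.estimator.predict_proba(X)[:, 1]

    def predict(self, data: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(data) >= threshold).astype(int)

    # -- evaluation --------------------------------------------------------

    def evaluate(self, test: pd.DataFrame, threshold: float = 0.5) -> MetricsSet:
        return confusion_metrics(
            test["label"].to_numpy(dtype=int), self.predict(test, threshold)
        )

    def roc(self, test: pd.DataFrame) -> RocResult:
        return roc_auc_delong(
            self.predict_proba(test), test["label"].to_numpy(dtype=int)
        )

    def youden(self, test: pd.DataFrame) -> dict[str, float]:
        roc = self.roc(test)
        logistic_params = None
        if self.model.kind == "logistic" and self.model.predictors == PREDICTORS_GLM:
            logistic_params = (
                self.params["intercept"],
                self.params["mean_similarity"],
            )
        return youden_threshold(
            roc,
            similarity=test["mean_similarity"].to_numpy(dtype=float),
            scores=self.predict_proba(test),
            logistic_params=logistic_params,
        )

    @property
    def cv_accuracy_mean(self) -> float:
        return float(self.cv_accuracies.mean()) if self.cv_accuracies.size else float("nan")

    @property
    def cv_accuracy_std(self) -> float:
        return float(self.cv_accuracies.std(ddof=1)) if self.cv_accuracies.size > 1 else float("nan")

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Diagnostic model results",
            "=" * 48,
            f"kind:           {self.model.kind}",
            f"predictors:     {', '.join(self.model.predictors)}",
            f"n train:        {len(self.model.train)}",
            f"CV accuracy:    {self.cv_accuracy_mean:.3f} "
            f"(+/- {self.cv_accuracy_std:.3f}, {self.cv_accuracies.size} folds)",
        ]
        if self.model.kind == "logistic":
            lines.append("-" * 48)
            lines.append(f"{'term':<18}{'coef':>12}{'std err':>12}")
            for name in ("intercept", *self.model.predictors):
                lines.append(
                    f"{name:<18}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}"
                )
            if self.separation_guard:
                lines.append("note: separation guard active; std errors unavailable")
        else:
            lines.append("-" * 48)
            lines.append(f"{'predictor':<18}{'importance':>12}")
            for name, value in self.importances.items():
                lines.append(f"{name:<18}{value:>12.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers


def fit_logistic(
    train: pd.DataFrame, folds: int = 5, seed: int = 0
) -> DiagnosticResults:
    """Similarity-only logistic regression with seeded stratified CV."""
    return DiagnosticModel(train, kind="logistic", folds=folds, seed=seed).fit()


def fit_random_forest(
    train: pd.DataFrame, n_trees: int = 500, folds: int = 5, seed: int = 0
) -> DiagnosticResults:
    """Three-predictor random forest (500 trees) with seeded stratified CV."""
    return DiagnosticModel(
        train, kind="random_forest", n_trees=n_trees, folds=folds, seed=seed
    ).fit()
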