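"""Fusion of the five acoustic parameters into a fat-fraction estimate and
the statistical evaluation toolkit (correlation, RMSE, ROC/Youden,
repeated holdout validation).

The cohort container is a pandas DataFrame with columns
``subject_id, echo_attenuation, elasticity, dispersion_slope,
shear_attenuation, shear_absorption, fat_fraction`` (fat fraction in %,
the MR-derived ground truth). The fusion model consumes the features in
the fixed order x1..x5 = (shear_absorption, echo_attenuation, elasticity,
dispersion_slope, shear_attenuation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateRocError,
    InsufficientDataError,
    SplitError,
    UndefinedCorrelationError,
)
from .models import AcousticParameterSet
from .tree import RegressionTree

#: x1..x5 feature order of the fusion model
FEATURE_ORDER = (
    "shear_absorption",
    "echo_attenuation",
    "elasticity",
    "dispersion_slope",
    "shear_attenuation",
)

COHORT_COLUMNS = (
    "subject_id",
    "echo_attenuation",
    "elasticity",
    "dispersion_slope",
    "shear_attenuation",
    "shear_absorption",
    "fat_fraction",
)

#: fat-fraction threshold (%) defining fatty-liver disease labels
DISEASE_THRESHOLD_PCT = 5.0


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, missing values and the fat-fraction range."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing columns: {missing}")
    if len(cohort) == 0:
        raise InsufficientDataError("empty cohort")
    numeric = list(COHORT_COLUMNS[1:])
    if cohort[numeric].isna().any().any():
        raise ValueError("cohort contains missing parameter values")
    ff = cohort["fat_fraction"].to_numpy(dtype=float)
    if np.any((ff < 0) | (ff > 100)):
        raise ValueError("fat_fraction must lie within [0, 100] %")
    return cohort


def cohort_features(cohort: pd.DataFrame) -> np.ndarray:
    """Feature matrix in the fixed x1..x5 order."""
    return cohort[list(FEATURE_ORDER)].to_numpy(dtype=float)


def fit_regression_tree(
    cohort: pd.DataFrame,
    max_depth: int = 4,
    min_leaf: int = 3,
    seed: int | None = None,
) -> RegressionTree:
    """Fit the CART fusion model on a cohort table.

    The fit is fully deterministic (exhaustive split search with fixed tie
    breaking); ``seed`` is accepted for interface symmetry but unused.
    """
    del seed
    validate_cohort(cohort)
    X = cohort_features(cohort)
    y = cohort["fat_fraction"].to_numpy(dtype=float)
    return RegressionTree(max_depth=max_depth, min_leaf=min_leaf).fit(X, y)


def predict_fat_fraction(model: RegressionTree, params) -> float:
    """Predicted fat fraction (%) for one subject's parameter set.

    ``params`` may be an AcousticParameterSet, a mapping with the five
    parameter names, or an array already in x1..x5 order.
    """
    if isinstance(params, AcousticParameterSet):
        x = np.array([getattr(params, k) for k in FEATURE_ORDER])
    elif isinstance(params, dict):
        x = np.array([float(params[k]) for k in FEATURE_ORDER])
    else:
        x = np.asarray(params, dtype=float)
        if x.shape != (len(FEATURE_ORDER),):
            raise ValueError(f"expected {len(FEATURE_ORDER)} features")
    return float(model.predict_one(x))


# ---------------------------------------------------------------------------
# statistics


def correlation_with_ci(
    x, y, alpha: float = 0.05
) -> tuple[float, tuple[float, float], float]:
    """Pearson correlation with Fisher-z confidence interval and t-test p.

    Returns ``(r, (lo, hi), p)``; the CI uses the Fisher transform with
    standard error 1/sqrt(n-3) and the two-sided p-value comes from
    t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise InsufficientDataError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        half = stats.norm.ppf(1.0 - alpha / 2.0) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (r, r)
    return r, ci, p


def rmse(pred, truth) -> float:
    """Root mean square error, in the units of the inputs."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1 or pred.size == 0:
        raise ValueError("pred and truth must be equal-length non-empty vectors")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


@dataclass
class RocResult:
    """ROC analysis at the Youden-optimal cutoff (SEN..ACC in percent)."""

    auc: float
    optimal_cutoff: float
    sen: float
    spc: float
    ppv: float
    npv: float
    acc: float
    youden_j: float


def roc_analysis(scores, labels, positive_direction: int = 1) -> RocResult:
    """ROC curve, trapezoid AUC and Youden-optimal operating point.

    A subject is called positive when ``positive_direction * score`` is at
    or above the cutoff; use ``positive_direction=-1`` for parameters that
    decrease with disease (shear attenuation/absorption) so the AUC is
    >= 0.5 by construction. The optimal cutoff maximizes
    J = SEN + SPC - 1, with ties resolved toward the lowest cutoff on the
    direction-adjusted scale; the returned cutoff is on the original scale.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateRocError("both classes must be present")
    if positive_direction not in (1, -1):
        raise ValueError("positive_direction must be +1 or -1")

    s = positive_direction * scores
    cutoffs = np.unique(s)  # ascending; each is an achievable operating point
    # TPR/FPR as a function of cutoff c: positive when s >= c
    tpr = np.array([(s[labels == 1] >= c).mean() for c in cutoffs])
    fpr = np.array([(s[labels == 0] >= c).mean() for c in cutoffs])
    # complete the curve with the all-positive (c = -inf) and all-negative ends
    fpr_curve = np.concatenate(([1.0], fpr, [0.0]))
    tpr_curve = np.concatenate(([1.0], tpr, [0.0]))
    auc = float(np.trapezoid(tpr_curve[::-1], fpr_curve[::-1]))

    j = tpr + (1.0 - fpr) - 1.0
    best = int(np.flatnonzero(j == j.max())[0])  # lowest cutoff on ties
    c = cutoffs[best]

    pred = s >= c
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = n_pos - tp
    tn = n_neg - fp
    sen = 100.0 * tp / n_pos
    spc = 100.0 * tn / n_neg
    ppv = 100.0 * tp / (tp + fp) if tp + fp else float("nan")
    npv = 100.0 * tn / (tn + fn) if tn + fn else float("nan")
    acc = 100.0 * (tp + tn) / labels.size
    return RocResult(
        auc=auc,
        optimal_cutoff=float(positive_direction * c),
        sen=sen,
        spc=spc,
        ppv=ppv,
        npv=npv,
        acc=acc,
        youden_j=float(j[best]),
    )


@dataclass
class EvalReport:
    """Correlation, error and diagnostic metrics for one method's outputs."""

    cc: float
    cc_ci95: tuple[float, float]
    p_value: float
    rmse: float
    auc: float
    optimal_cutoff: float
    sen: float
    spc: float
    ppv: float
    npv: float
    acc: float

    def to_dict(self) -> dict:
        return {
            "cc": self.cc,
            "cc_ci95": list(self.cc_ci95),
            "p_value": self.p_value,
            "rmse": self.rmse,
            "auc": self.auc,
            "optimal_cutoff": self.optimal_cutoff,
            "sen": self.sen,
            "spc": self.spc,
            "ppv": self.ppv,
            "npv": self.npv,
            "acc": self.acc,
        }


def evaluate_predictions(
    pred,
    truth,
    threshold_pct: float = DISEASE_THRESHOLD_PCT,
    positive_direction: int = 1,
) -> EvalReport:
    """Full evaluation of predictions against ground-truth fat fractions.

    Labels are ``truth >= threshold_pct`` (fatty-liver disease at 5% by
    default); predictions serve as the ROC score.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    cc, ci, p = correlation_with_ci(pred, truth)
    err = rmse(pred, truth)
    labels = (truth >= threshold_pct).astype(int)
    roc = roc_analysis(pred, labels, positive_direction=positive_direction)
    return EvalReport(
        cc=cc,
        cc_ci95=ci,
        p_value=p,
        rmse=err,
        auc=roc.auc,
        optimal_cutoff=roc.optimal_cutoff,
        sen=roc.sen,
        spc=roc.spc,
        ppv=roc.ppv,
        npv=roc.npv,
        acc=roc.acc,
    )


# ---------------------------------------------------------------------------
# repeated random holdout validation


@dataclass
class CrossValidationResult:
    """Summary of repeated random-holdout validation at one test fraction."""

    test_fraction: float  # percent
    repeats: int
    per_repeat_cc: np.ndarray
    pooled_cc: float
    pooled_ci95: tuple[float, float]
    pooled_p: float
    pooled_rmse: float

    def to_dict(self) -> dict:
        return {
            "test_fraction": self.test_fraction,
            "repeats": self.repeats,
            "per_repeat_cc": [float(v) for v in self.per_repeat_cc],
            "pooled_cc": self.pooled_cc,
            "pooled_ci95": list(self.pooled_ci95),
            "pooled_p": self.pooled_p,
            "pooled_rmse": self.pooled_rmse,
        }


def cross_validate(
    cohort: pd.DataFrame,
    test_fraction: float = 10.0,
    repeats: int = 10,
    seed: int | None = None,
    max_depth: int = 4,
    min_leaf: int = 3,
) -> CrossValidationResult:
    """Repeated random holdout validation of the fusion model.

    For each repeat a random ``test_fraction`` % of subjects is held out,
    the tree is fitted on the remainder and the holdout predictions are
    scored. Per-repeat CC is undefined (NaN) when the holdout response is
    constant; the summary CC pools all holdout predictions across repeats.
    """
    validate_cohort(cohort)
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    n = len(cohort)
    n_test = int(round(n * test_fraction / 100.0))
    if n_test < 2:
        raise SplitError(
            f"holdout of {n_test} subjects (test_fraction={test_fraction}%) is below 2"
        )
    if n - n_test < 2 * min_leaf:
        raise SplitError("training split too small for the tree")

    X = cohort_features(cohort)
    y = cohort["fat_fraction"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    per_repeat = np.full(repeats, np.nan)
    pooled_pred: list[float] = []
    pooled_truth: list[float] = []
    for r in range(repeats):
        perm = rng.permutation(n)
        test_idx = perm[:n_test]
        train_idx = perm[n_test:]
        model = RegressionTree(max_depth=max_depth, min_leaf=min_leaf).fit(
            X[train_idx], y[train_idx]
        )
        pred = model.predict(X[test_idx])
        truth = y[test_idx]
        pooled_pred.extend(pred)
        pooled_truth.extend(truth)
        if np.std(pred) > 0 and np.std(truth) > 0:
            per_repeat[r] = np.corrcoef(pred, truth)[0, 1]

    cc, ci, p = correlation_with_ci(pooled_pred, pooled_truth)
    return CrossValidationResult(
        test_fraction=float(test_fraction),
        repeats=repeats,
        per_repeat_cc=per_repeat,
        pooled_cc=cc,
        pooled_ci95=ci,
        pooled_p=p,
        pooled_rmse=rmse(pooled_pred, pooled_truth),
    )
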