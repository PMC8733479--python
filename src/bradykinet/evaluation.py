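"""Classification and statistical evaluation on two-value (left, right) inputs.

Each classifier receives exactly two inputs per subject: one feature's value
for the left hand and for the right hand, which encodes both overall slowing
and the left-right asymmetry typical of PD. Three classifiers are compared —
logistic regression, Gaussian naive Bayes, and a 100-tree random forest —
under stratified 4-fold cross-validation. Per-fold ROC curves are averaged
vertically on a fixed 101-point false-positive-rate grid; the area under the
mean curve is the comparison metric, and the reported sensitivity/specificity
sit at the Youden-optimal point of the mean curve. Group contrasts use the
Mann-Whitney U test on side-stratified features (PD most-affected side vs
HS dominant side).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_NAMES",
    "CVResult",
    "ValidationResult",
    "GroupComparison",
    "build_feature_table",
    "make_classifier",
    "train_classifier",
    "cross_validate",
    "external_validate",
    "group_compare",
]

MODEL_NAMES = ("logistic_regression", "gaussian_naive_bayes", "random_forest")
FPR_GRID = np.linspace(0.0, 1.0, 101)
FEATURE_NAMES = ("amplitude_mean", "amplitude_std", "speed", "fatigue")


@dataclass(frozen=True)
class CVResult:
    model: str
    fold_fpr: List[np.ndarray]
    fold_tpr: List[np.ndarray]
    fold_auc: List[float]
    mean_fpr: np.ndarray
    mean_tpr: np.ndarray
    auc: float
    sensitivity: float
    specificity: float
    seed: int

    def summary(self) -> dict:
        return {
            "model": self.model,
            "auc": self.auc,
            "fold_auc": list(self.fold_auc),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class ValidationResult:
    model: str
    auc: float
    accuracy: float
    n_cases: int
    n_controls: int


@dataclass(frozen=True)
class GroupComparison:
    feature_name: str
    task: str
    condition: str
    group1_label: str  # e.g. "PD_MAS"
    group1_median: float
    group1_iqr: float
    group2_label: str  # e.g. "HS_DS"
    group2_median: float
    group2_iqr: float
    p_value: float
    side_stats: Dict[str, Tuple[float, float]] = field(default_factory=dict)


def build_feature_table(
    features: pd.DataFrame,
    feature_name: str,
    task: str,
    condition: str,
) -> pd.DataFrame:
    """Pivot a tidy per-hand feature frame into one (left, right) row per
    subject for one feature/task/condition.

    Input columns: subject_id, group, task, condition, hand, and the feature
    columns. Rows whose left or right value is missing are dropped and logged
    (an undefined feature must not be imputed as 0).
    """
    if feature_name not in features.columns:
        raise KeyError(f"feature {feature_name!r} not in table")
    sub = features[(features["task"] == task) & (features["condition"] == condition)]
    if sub.empty:
        raise ValueError(f"no rows for task={task!r} condition={condition!r}")
    wide = sub.pivot_table(
        index=["subject_id", "group"],
        columns="hand",
        values=feature_name,
        aggfunc="first",
    ).reset_index()
    for hand in ("left", "right"):
        if hand not in wide.columns:
            wide[hand] = np.nan
    wide = wide.rename(columns={"left": "left_value", "right": "right_value"})
    complete = wide.dropna(subset=["left_value", "right_value"])
    dropped = set(wide["subject_id"]) - set(complete["subject_id"])
    if dropped:
        logger.warning(
            "dropping %d subject(s) with undefined %s (%s/%s): %s",
            len(dropped), feature_name, task, condition, sorted(dropped),
        )
    out = complete[["subject_id", "group", "left_value", "right_value"]].reset_index(drop=True)
    counts = out["group"].value_counts()
    if counts.get("PD", 0) < 2 or counts.get("HS", 0) < 2:
        raise ValueError(
            f"need at least 2 subjects per class, got {dict(counts)} for "
            f"{feature_name}/{task}/{condition}"
        )
    return out


def make_classifier(model: str, seed: int = 0):
    """Instantiate one of the three two-input classifiers."""
    if model == "logistic_regression":
        return LogisticRegression()
    if model == "gaussian_naive_bayes":
        return GaussianNB()
    if model == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")


def _xy(rows: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray]:
    X = rows[["left_value", "right_value"]].to_numpy(dtype=float)
    y = (rows["group"] == "PD").to_numpy(dtype=int)
    return X, y


def train_classifier(rows: pd.DataFrame, model: str, seed: int = 0):
    """Fit one classifier on the full table; returns the fitted estimator
    whose ``predict_proba(X)[:, 1]`` is the PD probability."""
    X, y = _xy(rows)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    clf = make_classifier(model, seed)
    clf.fit(X, y)
    return clf


def cross_validate(rows: pd.DataFrame, model: str, k: int = 4, seed: int = 0) -> CVResult:
    """Stratified k-fold cross-validation with vertically averaged ROC.

    Per fold the classifier is refit and its ROC computed; true-positive
    rates are interpolated onto a fixed 101-point FPR grid and averaged. The
    reported AUC is the area under the mean curve (trapezoidal);
    sensitivity/specificity are read at the Youden-optimal grid point.
    """
    X, y = _xy(rows)
    class_sizes = np.bincount(y, minlength=2)
    if class_sizes.min() < k:
        raise ValueError(
            f"smallest class has {class_sizes.min()} members < k={k}; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_fpr, fold_tpr, fold_auc, tprs = [], [], [], []
    for train_idx, test_idx in skf.split(X, y):
        clf = make_classifier(model, seed)
        clf.fit(X[train_idx], y[train_idx])
        scores = clf.predict_proba(X[test_idx])[:, 1]
        fpr, tpr, _ = roc_curve(y[test_idx], scores)
        fold_fpr.append(fpr)
        fold_tpr.append(tpr)
        fold_auc.append(float(roc_auc_score(y[test_idx], scores)))
        interp = np.interp(FPR_GRID, fpr, tpr)
        interp[0] = 0.0
        tprs.append(interp)
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[-1] = 1.0
    auc = float(np.trapezoid(mean_tpr, FPR_GRID))
    youden = int(np.argmax(mean_tpr - FPR_GRID))
    return CVResult(
        model=model,
        fold_fpr=fold_fpr,
        fold_tpr=fold_tpr,
        fold_auc=fold_auc,
        mean_fpr=FPR_GRID.copy(),
        mean_tpr=mean_tpr,
        auc=auc,
        sensitivity=float(mean_tpr[youden]),
        specificity=float(1.0 - FPR_GRID[youden]),
        seed=seed,
    )


def external_validate(fitted, rows: pd.DataFrame, model: str = "") -> ValidationResult:
    """Score a model fitted on the training cohort against held-out rows
    (no refitting); accuracy uses the 0.5 probability threshold."""
    X, y = _xy(rows)
    scores = fitted.predict_proba(X)[:, 1]
    auc = float(roc_auc_score(y, scores))
    accuracy = float(np.mean((scores >= 0.5).astype(int) == y))
    return ValidationResult(
        model=model or type(fitted).__name__,
        auc=auc,
        accuracy=accuracy,
        n_cases=int(y.sum()),
        n_controls=int(len(y) - y.sum()),
    )


def _median_iqr(values: np.ndarray) -> Tuple[float, float]:
    if len(values) == 0:
        return (float("nan"), float("nan"))
    q1, q3 = np.percentile(values, [25, 75])
    return (float(np.median(values)), float(q3 - q1))


def group_compare(
    features: pd.DataFrame,
    side_meta: pd.DataFrame,
    feature_names: Sequence[str] = FEATURE_NAMES,
    tasks: Optional[Sequence[str]] = None,
    conditions: Optional[Sequence[str]] = None,
) -> List[GroupComparison]:
    """Side-stratified PD vs HS contrasts with the Mann-Whitney U test.

    ``side_meta`` maps subject_id -> (group, most_affected_side,
    dominant_side). For each feature/task/condition the primary contrast is
    PD most-affected-side values vs HS dominant-side values (two-sided);
    medians and IQRs are reported for all four side-groups (MAS/LAS/DS/NDS).
    """
    meta = side_meta.set_index("subject_id")
    tasks = tasks or sorted(features["task"].unique())
    conditions = conditions or sorted(features["condition"].unique())
    out: List[GroupComparison] = []
    for task in tasks:
        for condition in conditions:
            sub = features[(features["task"] == task) & (features["condition"] == condition)]
            if sub.empty:
                continue
            for name in feature_names:
                groups: Dict[str, List[float]] = {"MAS": [], "LAS": [], "DS": [], "NDS": []}
                for _, row in sub.iterrows():
                    value = row[name]
                    if not np.isfinite(value):
                        continue
                    m = meta.loc[row["subject_id"]]
                    if m["group"] == "PD":
                        key = "MAS" if row["hand"] == m["most_affected_side"] else "LAS"
                    else:
                        key = "DS" if row["hand"] == m["dominant_side"] else "NDS"
                    groups[key].append(float(value))
                mas, ds = np.asarray(groups["MAS"]), np.asarray(groups["DS"])
                if len(mas) == 0 or len(ds) == 0:
                    continue
                if np.ptp(np.concatenate([mas, ds])) == 0:
                    p = 1.0  # identical constant samples
                else:
                    p = float(stats.mannwhitneyu(mas, ds, alternative="two-sided").pvalue)
                m1, i1 = _median_iqr(mas)
                m2, i2 = _median_iqr(ds)
                out.append(
                    GroupComparison(
                        feature_name=name,
                        task=task,
                        condition=condition,
                        group1_label="PD_MAS",
                        group1_median=m1,
                        group1_iqr=i1,
                        group2_label="HS_DS",
                        group2_median=m2,
                        group2_iqr=i2,
                        p_value=p,
                        side_stats={k: _median_iqr(np.asarray(v)) for k, v in groups.items()},
                    )
                )
    return out
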