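"""Combined biomarker response model, concordance scoring and
earliest-detection-week analysis.

The headline model is a logistic regression of binary pathological response
(good G1/G2 vs bad G3) on z-standardized predictors: the normalized CA19-9
change and the changes of the selected delta radiomic features, each
summarized at the last observed week. Model quality is the concordance
index (for a binary outcome, identical to the area under the ROC curve),
with ties credited 0.5. The reported c-index is in-sample unless the
leave-one-out variant is requested; in-sample concordance is optimistic,
and adding even a pure-noise predictor cannot decrease it.

Weekly detection uses a label-free combined biomarker: the mean of
per-biomarker z-scores within a week (both biomarker families share the
sign convention positive = decline from baseline = benefit, so no
orientation step is needed). Detection is the start of *sustained*
between-group significance: the earliest week from which every subsequent
tested week has Welch-t p < alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .simulate import week_of_fraction

__all__ = [
    "ResponseModelResult",
    "DetectionWeekResult",
    "concordance_index",
    "fit_response_model",
    "build_predictor_set",
    "combined_weekly_biomarker",
    "weekly_group_pvalues",
    "earliest_detection_week",
]

_RIDGE_LAMBDA = 1e-4  # on the standardized scale; flagged when it binds


@dataclass
class ResponseModelResult:
    coefficients: dict[str, float]
    intercept: float
    scores: pd.Series  # per-patient risk score (higher = predicted good)
    c_index: float
    n: int
    separation_flag: bool
    predictors: list[str] = field(default_factory=list)


@dataclass
class DetectionWeekResult:
    detection_week: int | None
    p_by_week: dict[int, float]
    skipped_weeks: list[int]
    mode: str = "sustained"


def concordance_index(scores, labels) -> float:
    """Concordance between scores and a binary outcome.

    c = (#concordant + 0.5 #tied) / #(positive, negative) pairs; equals the
    ROC AUC. Raises if either class is absent.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("concordance undefined: one outcome class is absent")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def fit_response_model(
    predictors: pd.DataFrame, labels: pd.Series
) -> ResponseModelResult:
    """Logistic regression of response on z-standardized predictors.

    A small L2 penalty (lambda = 1e-4 per observation on the standardized
    scale) keeps the fit defined under perfect separation; when the data
    are separated the result is flagged. Deterministic given its inputs.
    """
    y = labels.astype(int).to_numpy()
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need >= 2 patients per response class")
    X = _zscore(predictors.to_numpy(dtype=float))
    clf = LogisticRegression(C=1.0 / (_RIDGE_LAMBDA * len(y)), solver="lbfgs", max_iter=2000)
    clf.fit(X, y)
    scores = clf.decision_function(X)
    # perfect separation: every case scores above every control
    separated = bool(scores[y == 0].max() < scores[y == 1].min())
    return ResponseModelResult(
        coefficients=dict(zip(predictors.columns, clf.coef_[0])),
        intercept=float(clf.intercept_[0]),
        scores=pd.Series(scores, index=predictors.index),
        c_index=concordance_index(scores, y),
        n=len(y),
        separation_flag=separated,
        predictors=list(predictors.columns),
    )


def loo_c_index(predictors: pd.DataFrame, labels: pd.Series) -> float:
    """Leave-one-out concordance (clearly labelled out-of-sample variant)."""
    y = labels.astype(int).to_numpy()
    X = _zscore(predictors.to_numpy(dtype=float))
    scores = np.empty(len(y))
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        clf = LogisticRegression(
            C=1.0 / (_RIDGE_LAMBDA * (len(y) - 1)), solver="lbfgs", max_iter=2000
        )
        clf.fit(X[keep], y[keep])
        scores[i] = clf.decision_function(X[i : i + 1])[0]
    return concordance_index(scores, y)


def build_predictor_set(
    drf: pd.DataFrame,
    ca199_changes: pd.DataFrame,
    labels: pd.DataFrame,
    selected_features: list[str],
    up_to_week: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-patient predictor matrix and response labels.

    Each selected DRF is summarized as its mean change over the last
    observed week (restricted to weeks <= ``up_to_week`` when given); the
    CA19-9 predictor is the latest available normalized change under the
    same restriction. Patients missing any predictor are dropped.
    """
    drf = drf.copy()
    drf["week"] = week_of_fraction(drf["fraction"])
    ca = ca199_changes.copy()
    ca["week"] = week_of_fraction(ca["fraction"])
    if up_to_week is not None:
        drf = drf[drf["week"] <= up_to_week]
        ca = ca[ca["week"] <= up_to_week]

    cols = {}
    for feat in selected_features:
        sub = drf[drf["feature"] == feat]
        last_week = sub.groupby("patient_id")["week"].max()
        summ = {}
        for pid, w in last_week.items():
            vals = sub[(sub["patient_id"] == pid) & (sub["week"] == w)]["value"]
            summ[pid] = float(vals.mean())
        cols[f"drf_{feat}"] = pd.Series(summ)
    last = ca.sort_values("fraction").groupby("patient_id").tail(1)
    cols["ca199_change"] = last.set_index("patient_id")["value"]

    X = pd.DataFrame(cols).dropna()
    lab = labels.set_index("patient_id")["group"].reindex(X.index)
    keep = lab.notna()
    return X[keep], (lab[keep] == "good").astype(int)


def combined_weekly_biomarker(weekly_values: pd.DataFrame) -> pd.DataFrame:
    """Label-free combined biomarker per (patient, week).

    ``weekly_values`` columns: patient_id, week, biomarker, value — one
    summarized change per patient per biomarker per week (for daily DRFs,
    the within-week mean; for sparse CA19-9, the latest draw of the week).
    Each biomarker is z-scored across patients within the week and the
    z-scores averaged. Because both families use the decline-positive sign
    convention, no per-biomarker orientation is needed.
    """
    rows = []
    for (week, biom), sub in weekly_values.groupby(["week", "biomarker"]):
        v = sub["value"].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        z = (v - v.mean()) / (sd if sd > 0 else 1.0)
        for pid, zz in zip(sub["patient_id"], z):
            rows.append((pid, week, biom, zz))
    zdf = pd.DataFrame(rows, columns=["patient_id", "week", "biomarker", "z"])
    return (
        zdf.groupby(["patient_id", "week"])["z"].mean().reset_index()
        .rename(columns={"z": "value"})
    )


def weekly_group_pvalues(
    values: pd.DataFrame, labels: pd.DataFrame
) -> tuple[dict[int, float], list[int]]:
    """Two-sided Welch t-test between response groups for every week.

    ``values`` columns: patient_id, week, value. Weeks with fewer than two
    observations in either group are skipped (reported separately).
    """
    df = values.merge(labels[["patient_id", "group"]], on="patient_id")
    pvals: dict[int, float] = {}
    skipped: list[int] = []
    for week, sub in df.groupby("week"):
        a = sub.loc[sub["group"] == "good", "value"].to_numpy(dtype=float)
        b = sub.loc[sub["group"] == "bad", "value"].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            skipped.append(int(week))
            continue
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            pvals[int(week)] = 1.0 if a.mean() == b.mean() else 0.0
        else:
            pvals[int(week)] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return pvals, skipped


def earliest_detection_week(
    values: pd.DataFrame,
    labels: pd.DataFrame,
    alpha: float = 0.05,
    mode: str = "sustained",
) -> DetectionWeekResult:
    """Earliest treatment week at which the groups separate.

    mode="sustained" (default): the first week from which *all* subsequent
    tested weeks are significant — the week significance "begins".
    mode="first": the first week with p < alpha, ignoring later weeks.
    """
    pvals, skipped = weekly_group_pvalues(values, labels)
    weeks = sorted(pvals)
    detection = None
    if mode == "first":
        for w in weeks:
            if pvals[w] < alpha:
                detection = w
                break
    elif mode == "sustained":
        for i, w in enumerate(weeks):
            if all(pvals[v] < alpha for v in weeks[i:]):
                detection = w
                break
    else:
        raise ValueError(f"unknown detection mode {mode!r}")
    return DetectionWeekResult(
        detection_week=detection, p_by_week=pvals, skipped_weeks=skipped, mode=mode
    )
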