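"""Diagnostic cutoff derivation and validation for brain-lesion detection.

The diagnostic score is the per-sample percentage of GFAP+CD16+ monocytes.
A ROC curve is built on a training split of lesion patients only (healthy
controls never train; they all go to validation), the cutoff is the candidate
threshold where sensitivity and specificity are closest, and the frozen
cutoff is validated on the held-out samples with a 2x2 cross-tabulation,
Wilson 95% confidence intervals and Pearson's chi-square (df=1, no continuity
correction).

Conventions, recorded in every report: a positive call is score >= threshold;
candidate thresholds are midpoints between adjacent distinct scores plus
-inf/+inf sentinels; ties in |sens - spec| break by larger sens + spec, then
by the smaller threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "ROCCurve",
    "CutoffModel",
    "ValidationReport",
    "split_train_validation",
    "roc_curve",
    "closest_sens_spec_cutoff",
    "evaluate_cutoff",
    "ClosestSensSpecCutoff",
]


@dataclass
class ROCCurve:
    """Empirical ROC: candidate thresholds with sensitivity/specificity each."""

    thresholds: np.ndarray  # descending sensitivity order (ascending threshold)
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


@dataclass
class CutoffModel:
    cutoff: float
    criterion: str
    sensitivity: float
    specificity: float
    auc: float
    tie_break: str = "max sens+spec, then smaller threshold"
    training_ids: tuple = ()
    seed: int | None = None


@dataclass
class ValidationReport:
    """2x2 cross-tabulation of test result against lesion status."""

    table: np.ndarray  # rows: test +/-, cols: lesion +/-
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    chi_square: float | None
    chi_square_df: int
    p: float | None
    n: int
    cutoff: float
    positive_rule: str = "score >= cutoff"
    ci_method: str = "wilson"
    notes: list[str] = field(default_factory=list)


def split_train_validation(
    cohort: pd.DataFrame,
    train_fraction: float = 0.33,
    seed: int = 0,
    lesion_groups: tuple[str, ...] | None = None,
) -> tuple[list[str], list[str]]:
    """Patient-level train/validation split; healthy controls all validate.

    The sampling unit is the patient: all samples of one patient land on one
    side. The training draw is stratified by diagnosis group over lesion
    patients to avoid degenerate splits. Returns (train_ids, validation_ids)
    as sample_id lists, reproducible under the seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if lesion_groups is None:
        lesion_groups = tuple(g for g in cohort["diagnosis_group"].unique()
                              if g not in ("healthy", "AIS"))
    lesion = cohort[cohort["diagnosis_group"].isin(lesion_groups)]
    if lesion.empty:
        raise ValueError("no lesion patients available for training")
    rng = np.random.default_rng(seed)
    train_patients: list[str] = []
    for group, sub in lesion.groupby("diagnosis_group"):
        patients = sorted(sub["patient_id"].unique())
        n_train = int(round(train_fraction * len(patients)))
        chosen = rng.choice(len(patients), size=n_train, replace=False)
        train_patients.extend(patients[i] for i in sorted(chosen))
    train_set = set(train_patients)
    train_ids = lesion.loc[lesion["patient_id"].isin(train_set), "sample_id"].tolist()
    validation_ids = cohort.loc[
        ~cohort["patient_id"].isin(train_set)
        & cohort["diagnosis_group"].isin(lesion_groups + ("healthy",)),
        "sample_id"].tolist()
    return train_ids, validation_ids


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    return np.concatenate([[-np.inf], mids, [np.inf]])


def roc_curve(scores, labels) -> ROCCurve:
    """Empirical ROC with AUC in the rank-statistic (Mann-Whitney) form.

    ``labels`` are truthy for lesion-positive. The AUC equals
    (concordant + 0.5 * ties) / (n_pos * n_neg), which coincides with the
    trapezoidal area under the empirical curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    thr = _candidate_thresholds(scores)
    sens = np.array([(pos >= t).mean() for t in thr])
    spec = np.array([(neg < t).mean() for t in thr])
    diff = pos[:, None] - neg[None, :]
    auc = ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (pos.size * neg.size)
    return ROCCurve(thr, sens, spec, float(auc), pos.size, neg.size)


def trapezoidal_auc(roc: ROCCurve) -> float:
    """Trapezoid rule over the empirical (FPR, TPR) points."""
    # descending threshold order: FPR and TPR are both non-decreasing, which
    # keeps vertical/diagonal tie segments in the correct traversal order
    x = (1.0 - roc.specificity)[::-1]
    y = roc.sensitivity[::-1]
    return float(np.trapezoid(y, x))


def closest_sens_spec_cutoff(roc: ROCCurve) -> CutoffModel:
    """Cutoff where sensitivity and specificity are closest.

    argmin |sens - spec| over candidate thresholds; ties break by maximal
    sens + spec, then by the smaller threshold.
    """
    diff = np.abs(roc.sensitivity - roc.specificity)
    total = roc.sensitivity + roc.specificity
    best = 0
    for i in range(1, roc.thresholds.size):
        if (diff[i] < diff[best] - 1e-12
                or (abs(diff[i] - diff[best]) <= 1e-12
                    and (total[i] > total[best] + 1e-12
                         or (abs(total[i] - total[best]) <= 1e-12
                             and roc.thresholds[i] < roc.thresholds[best])))):
            best = i
    return CutoffModel(
        cutoff=float(roc.thresholds[best]),
        criterion="closest-sens-spec",
        sensitivity=float(roc.sensitivity[best]),
        specificity=float(roc.specificity[best]),
        auc=roc.auc,
    )


def evaluate_cutoff(scores, labels, cutoff: float) -> ValidationReport:
    """Apply a frozen cutoff: cross-tab, Wilson CIs, Pearson chi-square (df 1)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be non-empty")
    test_pos = scores >= cutoff
    a = int(np.sum(test_pos & labels))      # true positive
    b = int(np.sum(test_pos & ~labels))     # false positive
    c = int(np.sum(~test_pos & labels))     # false negative
    d = int(np.sum(~test_pos & ~labels))    # true negative
    table = np.array([[a, b], [c, d]])
    n = a + b + c + d

    sens = a / (a + c)
    spec = d / (b + d)
    sens_ci = sps.binomtest(a, a + c).proportion_ci(0.95, method="wilson")
    spec_ci = sps.binomtest(d, b + d).proportion_ci(0.95, method="wilson")

    notes: list[str] = []
    chi2 = p = None
    margins = [a + b, c + d, a + c, b + d]
    if min(margins) == 0:
        notes.append("chi-square undefined: zero margin")
    else:
        chi2_res = sps.chi2_contingency(table, correction=False)
        chi2, p = float(chi2_res.statistic), float(chi2_res.pvalue)

    return ValidationReport(
        table=table,
        sensitivity=sens,
        specificity=spec,
        sensitivity_ci=(float(sens_ci.low), float(sens_ci.high)),
        specificity_ci=(float(spec_ci.low), float(spec_ci.high)),
        chi_square=chi2,
        chi_square_df=1,
        p=p,
        n=n,
        cutoff=float(cutoff),
        notes=notes,
    )


class ClosestSensSpecCutoff(BaseEstimator, ClassifierMixin):
    """Threshold classifier fitted by the closest sensitivity-specificity rule.

    Scikit-learn estimator over a single score column: ``fit(X, y)`` builds
    the training ROC and freezes ``cutoff_``; ``predict`` calls a sample
    positive when its score is at or above the cutoff.
    """

    def __init__(self) -> None:
        pass

    @staticmethod
    def _scores(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("expects a single score column")
            X = X[:, 0]
        return X

    def fit(self, X, y) -> "ClosestSensSpecCutoff":
        scores = self._scores(X)
        y = np.asarray(y).astype(bool)
        self.roc_ = roc_curve(scores, y)
        model = closest_sens_spec_cutoff(self.roc_)
        self.cutoff_ = model.cutoff
        self.sensitivity_ = model.sensitivity
        self.specificity_ = model.specificity
        self.auc_ = model.auc
        self.classes_ = np.array([False, True])
        return self

    def predict(self, X) -> np.ndarray:
        return self._scores(X) >= self.cutoff_

    def decision_function(self, X) -> np.ndarray:
        return self._scores(X) - self.cutoff_
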