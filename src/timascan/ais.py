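"""Acute-ischaemic-stroke time-course classification.

A stroke patient's blood is sampled repeatedly after symptom onset and the
GFAP+CD16+ monocyte percentage is tracked against the diagnostic cutoff
(default 0.6%). Large infarcts (>= 100 cm^3) produce multiple exceedances
within the first hours; the classifier calls an infarct large when at least
``min_points`` (default 2, encoding "multiple") in-window exceedances occur
within ``window_hours`` (default 8 h) of onset. Exceedance is strict
(pct > cutoff): a value exactly at the cutoff does not count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "TimecourseFlags",
    "InfarctCall",
    "LARGE_INFARCT_CM3",
    "flag_timecourse",
    "classify_infarct_size",
    "classify_cohort",
    "InfarctSizeClassifier",
]

LARGE_INFARCT_CM3 = 100.0  # >= convention


@dataclass
class TimecourseFlags:
    patient_id: str
    hours: np.ndarray
    pct: np.ndarray
    exceeds_cutoff: np.ndarray
    cutoff: float = 0.6
    window_hours: float = 8.0

    @property
    def in_window_exceedances(self) -> int:
        return int(np.sum(self.exceeds_cutoff & (self.hours <= self.window_hours)))


@dataclass
class InfarctCall:
    patient_id: str
    predicted_large: bool
    n_exceedances_in_window: int
    min_points: int
    truth_large: bool | None = None

    @property
    def concordant(self) -> bool | None:
        if self.truth_large is None:
            return None
        return self.predicted_large == self.truth_large


def flag_timecourse(
    series: pd.DataFrame,
    cutoff: float = 0.6,
    window_hours: float = 8.0,
    patient_id: str | None = None,
) -> TimecourseFlags:
    """Per-timepoint exceedance flags for one patient's series.

    ``series`` needs columns ``hours_since_onset`` and ``pct_gfap_cd16``,
    strictly increasing in time with hours >= 0.
    """
    hours = series["hours_since_onset"].to_numpy(dtype=float)
    pct = series["pct_gfap_cd16"].to_numpy(dtype=float)
    if hours.size == 0 or np.any(hours < 0):
        raise ValueError("need at least one timepoint with hours >= 0")
    if np.any(np.diff(hours) <= 0):
        raise ValueError("time stamps must be strictly increasing")
    pid = patient_id or (str(series["patient_id"].iloc[0])
                         if "patient_id" in series else "patient")
    return TimecourseFlags(pid, hours, pct, pct > cutoff, cutoff, window_hours)


def classify_infarct_size(
    flags: TimecourseFlags,
    min_points: int = 2,
    infarct_volume: float | None = None,
) -> InfarctCall:
    """Call the infarct large iff >= min_points in-window exceedances."""
    n_exc = flags.in_window_exceedances
    truth = None
    if infarct_volume is not None and np.isfinite(infarct_volume):
        truth = infarct_volume >= LARGE_INFARCT_CM3
    return InfarctCall(flags.patient_id, n_exc >= min_points, n_exc,
                       min_points, truth)


def classify_cohort(
    timecourses: pd.DataFrame,
    cutoff: float = 0.6,
    window_hours: float = 8.0,
    min_points: int = 2,
) -> pd.DataFrame:
    """Classify every patient in a long-format time-course table."""
    rows = []
    for pid, series in timecourses.groupby("patient_id", sort=True):
        series = series.sort_values("hours_since_onset")
        vol = (float(series["infarct_volume"].iloc[0])
               if "infarct_volume" in series else None)
        call = classify_infarct_size(
            flag_timecourse(series, cutoff, window_hours, patient_id=str(pid)),
            min_points=min_points, infarct_volume=vol)
        rows.append({
            "patient_id": call.patient_id,
            "predicted_large": call.predicted_large,
            "n_exceedances_in_window": call.n_exceedances_in_window,
            "truth_large": call.truth_large,
            "concordant": call.concordant,
        })
    return pd.DataFrame(rows)


class InfarctSizeClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based large-infarct classifier over time-course tables.

    Parameters are the decision rule itself (cutoff, window, minimum number
    of exceedances); ``fit`` only validates them, keeping the scikit-learn
    protocol so the classifier composes with sklearn tooling.
    """

    def __init__(self, cutoff: float = 0.6, window_hours: float = 8.0,
                 min_points: int = 2):
        self.cutoff = cutoff
        self.window_hours = window_hours
        self.min_points = min_points

    def fit(self, X=None, y=None) -> "InfarctSizeClassifier":
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")
        self.classes_ = np.array([False, True])
        self.fitted_ = True
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """X: long-format table (patient_id, hours_since_onset, pct_gfap_cd16)."""
        if not hasattr(self, "fitted_"):
            self.fit()
        calls = classify_cohort(X, self.cutoff, self.window_hours, self.min_points)
        return calls["predicted_large"].to_numpy(dtype=bool)
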