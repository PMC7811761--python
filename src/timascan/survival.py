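"""Survival analysis: Kaplan-Meier, log-rank, Cox regression, and the
prognostic-cutoff scan by maximal median-survival difference.

The prognostic dichotomization proceeds in two stages. First a continuous
Cox screen of the marker against overall survival; only when that screen is
significant (p < 0.05, overridable) does the cutoff scan run. The scan walks
a grid of candidate cutoffs (the unique observed marker values by default),
dichotomizes the cohort at each (marker >= cutoff is test-positive), computes
both arms' Kaplan-Meier median survivals, and selects the admissible cutoff
maximizing the absolute between-arm median difference (ties break to the
smaller cutoff). Candidates where either arm is smaller than a minimum
fraction of the cohort, or where a median is undefined, are skipped with a
recorded reason. The selected cutoff is then evaluated by log-rank and by a
covariate-adjusted Cox model. The selected-cutoff log-rank p is reported
unadjusted; every result carries a multiple-testing warning noting the
selection-induced optimism.

Kaplan-Meier estimation and the log-rank test wrap lifelines. Cox regression
is a Newton-Raphson partial-likelihood maximizer supporting Breslow (default)
and Efron tie handling, iterated to gradient norm < 1e-8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps
from sklearn.base import BaseEstimator

__all__ = [
    "KMCurve",
    "CoxFit",
    "SurvivalCutoffResult",
    "SurvivalError",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "max_median_diff_cutoff",
    "MaxMedianDiffCutoff",
]

SELECTION_WARNING = (
    "cutoff selected by scanning the marker grid; the reported log-rank p is "
    "unadjusted for this selection and is anti-conservative"
)


class SurvivalError(RuntimeError):
    """A survival quantity is undefined or a fit failed."""


@dataclass
class KMCurve:
    """Product-limit estimate; median = first time S(t) <= 0.5, else None."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median_survival: float | None

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxFit:
    covariates: list[str]
    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    model_chi_square: float
    df: int
    model_p: float
    ties: str
    n: int
    n_events: int
    n_excluded_missing: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": self.covariates,
            "coef": self.coefficients,
            "hazard_ratio": self.hazard_ratios,
            "se": self.standard_errors,
            "p": self.p_values,
        })


@dataclass
class SurvivalCutoffResult:
    marker: str
    cutoff: float
    n_high: int
    n_low: int
    median_high: float
    median_low: float
    logrank_chi_square: float
    logrank_df: int
    logrank_p: float
    screen_p: float
    screen_coef: float
    adjusted_cox: CoxFit | None
    scan_table: pd.DataFrame
    skipped: list[str] = field(default_factory=list)
    multiple_testing_warning: str = SELECTION_WARNING


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier curve; events precede censorings at tied times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if times.size == 0 or np.any(times < 0):
        raise ValueError("times must be non-empty and >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    grid = tab.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
    at_risk = tab["at_risk"].to_numpy(dtype=float)
    # tolerance absorbs float round-off when S(t) hits 0.5 exactly
    below = np.where(surv <= 0.5 + 1e-9)[0]
    median = float(grid[below[0]]) if below.size else None
    return KMCurve(grid, surv, at_risk, median)


def logrank_test(times, events, group) -> tuple[float, int, float]:
    """Two-sample Mantel-Cox test; returns (chi_square, df=1, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    group = np.asarray(group).astype(bool)
    if group.all() or (~group).all():
        raise ValueError("both groups need at least one subject")
    if not events.any():
        raise SurvivalError("log-rank undefined: no events observed")
    res = _ll_logrank(times[group], times[~group], events[group], events[~group])
    return float(res.test_statistic), 1, float(res.p_value)


def _cox_loglik(beta, x, times, events, ties):
    """Negative log partial likelihood with gradient and Hessian.

    Rows must be sorted by descending time so that the risk set of an event
    time is a prefix cumulative sum.
    """
    n, p = x.shape
    eta = x @ beta
    # guard against overflow during line search
    eta = np.clip(eta, -200, 200)
    w = np.exp(eta)
    wx = w[:, None] * x
    wxx = w[:, None, None] * (x[:, :, None] * x[:, None, :])
    cum_w = np.cumsum(w)
    cum_wx = np.cumsum(wx, axis=0)
    cum_wxx = np.cumsum(wxx, axis=0)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        dead = [k for k in range(i, j) if events[k]]
        if dead:
            d = len(dead)
            s_x = x[dead].sum(axis=0)
            r_w = cum_w[j - 1]
            r_wx = cum_wx[j - 1]
            r_wxx = cum_wxx[j - 1]
            ll += eta[dead].sum()
            if ties == "breslow":
                ll -= d * np.log(r_w)
                mu = r_wx / r_w
                grad += s_x - d * mu
                hess += d * (r_wxx / r_w - np.outer(mu, mu))
            else:  # efron
                d_w = w[dead].sum()
                d_wx = wx[dead].sum(axis=0)
                d_wxx = wxx[dead].sum(axis=0)
                for m in range(d):
                    f = m / d
                    wm = r_w - f * d_w
                    wxm = r_wx - f * d_wx
                    wxxm = r_wxx - f * d_wxx
                    ll -= np.log(wm)
                    mu = wxm / wm
                    grad += -mu
                    hess += wxxm / wm - np.outer(mu, mu)
                grad += s_x
        i = j
    return ll, grad, hess


def cox_fit(
    cohort: pd.DataFrame,
    time_col: str,
    event_col: str,
    covariates: list[str],
    ties: str = "breslow",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxFit:
    """Cox proportional-hazards fit by Newton iteration.

    Rows with missing values in the time, event or covariate columns are
    excluded and counted. The model chi-square is the likelihood-ratio
    statistic against the null model with df = number of covariates.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    cols = [time_col, event_col] + covariates
    sub = cohort[cols].dropna()
    n_excluded = len(cohort) - len(sub)
    x = sub[covariates].to_numpy(dtype=float)
    if any(np.ptp(x[:, j]) == 0 for j in range(x.shape[1])):
        raise ValueError("covariate with zero variance")
    times = sub[time_col].to_numpy(dtype=float)
    events = sub[event_col].to_numpy(dtype=bool)
    if not events.any():
        raise SurvivalError("no events observed")

    # standardize internally for numerical stability; back-transform at the end
    center = x.mean(axis=0)
    scale = x.std(axis=0)
    xs = (x - center) / scale

    order = np.argsort(-times, kind="stable")
    xs_o, t_o, e_o = xs[order], times[order], events[order]

    p = xs.shape[1]
    beta = np.zeros(p)
    ll0, _, _ = _cox_loglik(np.zeros(p), xs_o, t_o, e_o, ties)
    ll = ll0
    # gradient tolerance relative to the likelihood's float64 scale
    tol = tol * max(1.0, abs(ll0))
    converged = False
    for _ in range(max_iter):
        ll, grad, hess = _cox_loglik(beta, xs_o, t_o, e_o, ties)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise SurvivalError(f"singular Hessian at beta={beta}") from exc
        # halving line search keeps the partial likelihood non-decreasing
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, _, _ = _cox_loglik(cand, xs_o, t_o, e_o, ties)
            if ll_new >= ll - 1e-12:
                beta = cand
                break
            factor /= 2.0
        else:
            break
    else:
        ll, grad, hess = _cox_loglik(beta, xs_o, t_o, e_o, ties)
        converged = np.linalg.norm(grad) < tol
    if not converged:
        _, grad, _ = _cox_loglik(beta, xs_o, t_o, e_o, ties)
        if np.linalg.norm(grad) >= tol:
            raise SurvivalError(
                f"Newton iteration did not converge in {max_iter} iterations "
                f"(|grad|={np.linalg.norm(grad):.2e}, beta={beta})")

    if np.any(np.abs(beta / scale.clip(min=1e-300)) > 50):
        raise SurvivalError("apparent complete separation: diverging coefficient")

    _, _, hess = _cox_loglik(beta, xs_o, t_o, e_o, ties)
    cov_s = np.linalg.inv(hess)
    coef = beta / scale
    se = np.sqrt(np.diag(cov_s)) / scale
    z = coef / se
    chi2 = 2.0 * (ll - ll0)
    return CoxFit(
        covariates=list(covariates),
        coefficients=coef,
        hazard_ratios=np.exp(coef),
        standard_errors=se,
        p_values=2.0 * sps.norm.sf(np.abs(z)),
        model_chi_square=float(chi2),
        df=p,
        model_p=float(sps.chi2.sf(chi2, p)),
        ties=ties,
        n=len(sub),
        n_events=int(events.sum()),
        n_excluded_missing=n_excluded,
    )


def _km_median(times, events) -> float | None:
    return km_estimate(times, events).median_survival


def max_median_diff_cutoff(
    cohort: pd.DataFrame,
    marker: str,
    time_col: str = "os_months",
    event_col: str = "os_event",
    covariates: list[str] | None = None,
    scan_grid: np.ndarray | None = None,
    min_arm_fraction: float = 0.10,
    force: bool = False,
    ties: str = "breslow",
) -> SurvivalCutoffResult:
    """Prognostic cutoff by maximal between-arm Kaplan-Meier median difference.

    Runs the continuous-marker Cox screen first and refuses to scan when its
    p >= 0.05 unless ``force`` (the refusal raises SurvivalError carrying the
    screen result in its args). See the module docstring for the scan rules.
    """
    cols = list(dict.fromkeys([marker, time_col, event_col, *(covariates or [])]))
    sub = cohort[cols].dropna()
    times = sub[time_col].to_numpy(dtype=float)
    events = sub[event_col].to_numpy(dtype=bool)
    values = sub[marker].to_numpy(dtype=float)
    n = len(sub)

    screen = cox_fit(sub, time_col, event_col, [marker], ties=ties)
    screen_p = float(screen.p_values[0])
    screen_coef = float(screen.coefficients[0])
    if screen_p >= 0.05 and not force:
        raise SurvivalError(
            "continuous-marker Cox screen not significant "
            f"(p={screen_p:.3f} >= 0.05); scan refused", screen)

    grid = (np.unique(values) if scan_grid is None
            else np.unique(np.asarray(scan_grid, dtype=float)))
    min_arm = max(int(np.ceil(min_arm_fraction * n)), 1)

    rows, skipped = [], []
    for cut in grid:
        high = values >= cut
        n_high, n_low = int(high.sum()), int((~high).sum())
        if n_high < min_arm or n_low < min_arm:
            skipped.append(f"{cut:g}: arm below minimum size {min_arm}")
            continue
        med_high = _km_median(times[high], events[high])
        med_low = _km_median(times[~high], events[~high])
        if med_high is None or med_low is None:
            skipped.append(f"{cut:g}: undefined median in one arm")
            continue
        rows.append({"cutoff": float(cut), "n_high": n_high, "n_low": n_low,
                     "median_high": med_high, "median_low": med_low,
                     "median_diff": abs(med_high - med_low)})
    if not rows:
        raise SurvivalError(
            "no admissible cutoff; skipped candidates: " + "; ".join(skipped))

    scan = pd.DataFrame(rows)
    best = scan.sort_values(["median_diff", "cutoff"],
                            ascending=[False, True], kind="stable").iloc[0]
    cut = float(best["cutoff"])
    high = values >= cut
    chi2, df, p = logrank_test(times, events, high)

    adjusted = None
    if covariates:
        adj = sub.copy()
        adj["_high_arm"] = high.astype(float)
        adj_covs = ["_high_arm"] + [c for c in covariates if c != marker]
        adjusted = cox_fit(adj, time_col, event_col, adj_covs, ties=ties)

    return SurvivalCutoffResult(
        marker=marker,
        cutoff=cut,
        n_high=int(best["n_high"]),
        n_low=int(best["n_low"]),
        median_high=float(best["median_high"]),
        median_low=float(best["median_low"]),
        logrank_chi_square=chi2,
        logrank_df=df,
        logrank_p=p,
        screen_p=screen_p,
        screen_coef=screen_coef,
        adjusted_cox=adjusted,
        scan_table=scan,
        skipped=skipped,
    )


class MaxMedianDiffCutoff(BaseEstimator):
    """Scikit-learn-style estimator for the prognostic dichotomization.

    ``fit(X, y)`` takes the marker as a single column and ``y`` as a
    (time, event) two-column array; fitted attributes expose the selected
    ``cutoff_`` and its validation statistics. ``predict`` maps marker values
    to the high-risk arm (marker >= cutoff).
    """

    def __init__(self, min_arm_fraction: float = 0.10, force: bool = False,
                 ties: str = "breslow"):
        self.min_arm_fraction = min_arm_fraction
        self.force = force
        self.ties = ties

    def fit(self, X, y) -> "MaxMedianDiffCutoff":
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        frame = pd.DataFrame({"marker": X, "time": y[:, 0],
                              "event": y[:, 1].astype(bool)})
        res = max_median_diff_cutoff(
            frame, "marker", "time", "event",
            min_arm_fraction=self.min_arm_fraction, force=self.force,
            ties=self.ties)
        self.result_ = res
        self.cutoff_ = res.cutoff
        self.median_high_ = res.median_high
        self.median_low_ = res.median_low
        self.logrank_p_ = res.logrank_p
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return X >= self.cutoff_
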