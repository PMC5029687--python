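"""Survival-analysis primitives.

Cox proportional-hazards fits (a fast in-package Newton solver for the
univariate screens, lifelines for multivariate adjustment), Harrell's
concordance index, Kaplan-Meier curves, the log-rank test and Pearson
correlation with a Fisher-z confidence interval.

Conventions
-----------
* The univariate screening solver handles tied event times with the
  Breslow approximation; the multivariate path delegates to lifelines
  (Efron ties). The two coincide on tie-free data.
* p-values for Cox coefficients are Wald tests from the observed
  information; confidence intervals are 95% Wald intervals.
* A pair of subjects is comparable for the C-index when the strictly
  smaller follow-up time ends in an event; tied risk scores contribute 1/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats


class DegenerateInputError(ValueError):
    """Raised when a survival computation is undefined for the input."""


class ConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization failed to converge."""

    def __init__(self, message: str, last_beta: float | None = None):
        super().__init__(message)
        self.last_beta = last_beta


@dataclass
class SurvivalTestResult:
    """One covariate's Cox result: log-hazard, HR with 95% CI, Wald p, C-index."""

    name: str
    beta: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    c_index: float

    def as_dict(self) -> dict:
        return {
            "name": self.name, "beta": self.beta, "hr": self.hr,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p": self.p, "c_index": self.c_index,
        }


def _validate_surv(time, event):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("time and event must be 1-d arrays of equal length")
    if np.any(t < 0):
        raise ValueError("negative follow-up time")
    if not np.all(np.isin(e, (0.0, 1.0))):
        raise ValueError("event indicators must be 0 or 1")
    return t, e.astype(int)


def cox_univariate(x, time, event, max_iter: int = 60, tol: float = 1e-10):
    """Univariate Cox PH fit with Breslow ties via Newton-Raphson.

    Returns (beta, se, p). This is the workhorse behind the per-gene and
    per-pair screens where many thousands of single-covariate fits are
    needed; it is cross-checked against lifelines in the test suite.
    """
    t, e = _validate_surv(time, event)
    x = np.asarray(x, dtype=float)
    if e.sum() < 2:
        raise DegenerateInputError("need at least two events for a Cox fit")
    if np.ptp(x) == 0:
        raise DegenerateInputError("covariate is constant across samples")
    xc = x - x.mean()
    scale = xc.std()
    xs = xc / scale

    order = np.argsort(-t, kind="stable")
    xs_, t_, e_ = xs[order], t[order], e[order]
    # last index of each tie block in descending-time order: the Breslow
    # risk set for an event at time t is every subject with time >= t.
    tie_end = np.searchsorted(-t_, -t_, side="right") - 1
    ev = e_.astype(bool)

    def score_info(beta: float):
        eta = np.clip(beta * xs_, -500, 500)
        w = np.exp(eta)
        s0 = np.cumsum(w)[tie_end][ev]
        s1 = np.cumsum(w * xs_)[tie_end][ev]
        s2 = np.cumsum(w * xs_ * xs_)[tie_end][ev]
        ll = float(np.sum(beta * xs_[ev] - np.log(s0)))
        u = float(np.sum(xs_[ev] - s1 / s0))
        info = float(np.sum(s2 / s0 - (s1 / s0) ** 2))
        return ll, u, info

    beta = 0.0
    ll, u, info = score_info(beta)
    for _ in range(max_iter):
        if info <= 0:
            raise ConvergenceError("singular information matrix", beta / scale)
        step = u / info
        # step-halving safeguard
        for _ in range(30):
            ll_new, u_new, info_new = score_info(beta + step)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta += step
        ll, u, info = ll_new, u_new, info_new
        # a per-SD log hazard beyond 15 means a monotone likelihood
        # (complete separation); the MLE does not exist
        if abs(beta) > 15:
            raise ConvergenceError(
                "diverging coefficient (likely complete separation)",
                beta / scale)
        if abs(step) < tol:
            break
    else:
        if abs(u) > 1e-4:
            raise ConvergenceError(
                f"Newton-Raphson did not converge (score {u:.3g})", beta / scale
            )
    se_s = 1.0 / math.sqrt(info)
    z = beta / se_s
    p = 2.0 * stats.norm.sf(abs(z))
    return beta / scale, se_s / scale, p


def cox_fit(covariates, time, event, mode: str = "univariate",
            risk_scores=None) -> list[SurvivalTestResult]:
    """Cox PH regression over a covariate table.

    Parameters
    ----------
    covariates : DataFrame (samples x covariates) or 1-d array/Series.
    mode : 'univariate' fits each covariate alone (fast in-package
        Breslow-Newton solver); 'multivariate' fits the joint model with
        lifelines and reports each covariate adjusted for the others.
    risk_scores : optional per-sample risk score used for the C-index;
        defaults to the covariate itself (univariate) or the joint linear
        predictor (multivariate).
    """
    if isinstance(covariates, (pd.Series, np.ndarray, list)):
        covariates = pd.DataFrame({"x": np.asarray(covariates)})
    t, e = _validate_surv(time, event)
    if e.sum() < 2:
        raise DegenerateInputError("need at least two events for a Cox fit")
    z975 = stats.norm.ppf(0.975)
    results: list[SurvivalTestResult] = []
    if mode == "univariate":
        for name in covariates.columns:
            x = covariates[name].to_numpy(dtype=float)
            beta, se, p = cox_univariate(x, t, e)
            score = x if risk_scores is None else np.asarray(risk_scores, float)
            results.append(SurvivalTestResult(
                name=str(name), beta=beta, hr=math.exp(beta),
                ci_low=math.exp(beta - z975 * se),
                ci_high=math.exp(beta + z975 * se),
                p=p, c_index=c_index(score, t, e),
            ))
        return results
    if mode != "multivariate":
        raise ValueError("mode must be 'univariate' or 'multivariate'")
    for name in covariates.columns:
        if covariates[name].nunique() < 2:
            raise DegenerateInputError(f"covariate {name!r} is constant")
    df = covariates.astype(float).copy()
    df["_time"], df["_event"] = t, e
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    lp = cph.predict_partial_hazard(covariates.astype(float)).to_numpy()
    score = lp if risk_scores is None else np.asarray(risk_scores, float)
    ci = c_index(score, t, e)
    for name, row in cph.summary.iterrows():
        results.append(SurvivalTestResult(
            name=str(name), beta=float(row["coef"]),
            hr=float(np.exp(row["coef"])),
            ci_low=float(np.exp(row["coef lower 95%"])),
            ci_high=float(np.exp(row["coef upper 95%"])),
            p=float(row["p"]), c_index=ci,
        ))
    return results


def c_index(risk_scores, time, event) -> float:
    """Harrell's concordance index.

    Comparable pairs are those where the smaller follow-up time belongs to
    an event; a pair is concordant when the earlier-failing subject has the
    higher risk score, and tied scores count 1/2.
    """
    t, e = _validate_surv(time, event)
    r = np.asarray(risk_scores, dtype=float)
    if r.shape != t.shape:
        raise ValueError("risk_scores must match survival records")
    # comparable[i, j]: t_i < t_j and subject i had an event
    lt = t[:, None] < t[None, :]
    comp = lt & (e[:, None] == 1)
    n_comp = comp.sum()
    if n_comp == 0:
        raise DegenerateInputError("no comparable pairs")
    gt_score = r[:, None] > r[None, :]
    eq_score = r[:, None] == r[None, :]
    concordant = (comp & gt_score).sum() + 0.5 * (comp & eq_score).sum()
    return float(concordant / n_comp)


def km_curve(time, event) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a DataFrame with columns ``time`` and ``survival`` describing
    the right-continuous step function, starting at S(0) = 1.
    """
    t, e = _validate_surv(time, event)
    if t.size == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def km_survival_at(curve: pd.DataFrame, at: float) -> float:
    """Evaluate a km_curve step function at a time point."""
    mask = curve["time"].to_numpy() <= at
    if not mask.any():
        return 1.0
    return float(curve["survival"].to_numpy()[mask][-1])


def logrank_p(groups, time, event) -> float:
    """Two-group log-rank test p-value (chi-square, 1 df)."""
    t, e = _validate_surv(time, event)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError("exactly two non-empty groups are required")
    res = multivariate_logrank_test(t, g, e)
    return float(res.p_value)


def pearson_r(x, y) -> dict:
    """Pearson correlation with a 95% Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-d arrays, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    if abs(res.statistic) < 1.0 and x.size > 3:
        ci = res.confidence_interval()  # Fisher z-transform interval
        lo, hi = float(ci.low), float(ci.high)
    else:
        lo = hi = float(res.statistic)
    return {"r": float(res.statistic), "ci_low": lo, "ci_high": hi,
            "p": float(res.pvalue)}
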