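"""Parametric survival laws, maximum-likelihood fitting, and hazard-ratio scaling.

Survival is parameterized with time in months throughout:

* Weibull:      ``S(t) = exp(-lam * t**gamma)`` — ``lam`` is a scale in
  1/month**gamma, ``gamma`` the shape.
* Exponential:  ``S(t) = exp(-rate * t)``; alternatively parameterized by an
  accelerated-failure-time intercept with ``rate = exp(-intercept)``.
* Log-logistic: ``S(t) = 1 / (1 + (lam * t)**gamma)``.

Treatment-specific Weibull parameters are derived from a reference
(chemotherapy) fit by multiplying the scale by a pooled hazard ratio while
keeping the shape — a proportional-hazards assumption that is exact for the
Weibull and exponential families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "SurvParams",
    "FitReport",
    "fit_parametric",
    "rank_fits",
    "apply_hazard_ratio",
    "survival_at",
    "hazard_at",
]

_FAMILIES = ("weibull", "exponential", "loglogistic")


@dataclass(frozen=True)
class SurvParams:
    """Parameters of one parametric survival law.

    For ``exponential`` either ``lam`` (the rate per month) or ``intercept``
    (AFT log-scale; ``rate = exp(-intercept)``) must be given.
    ``cov`` is the covariance of (ln lam, ln gamma) when estimated from data.
    """

    family: str
    lam: float | None = None
    gamma: float | None = None
    intercept: float | None = None
    cov: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown survival family {self.family!r}")
        if self.family == "exponential":
            if self.lam is None and self.intercept is None:
                raise ValueError("exponential law needs a rate or an intercept")
        else:
            if self.lam is None or self.gamma is None:
                raise ValueError(f"{self.family} law needs lam and gamma")
        if self.lam is not None and self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def rate(self) -> float:
        """Event rate per month (exponential family only)."""
        if self.family != "exponential":
            raise AttributeError("rate is defined for the exponential family only")
        return self.lam if self.lam is not None else math.exp(-self.intercept)


@dataclass(frozen=True)
class FitReport:
    params: SurvParams
    loglik: float
    aic: float
    bic: float
    n: int
    events: int

    @property
    def k(self) -> int:
        return 1 if self.params.family == "exponential" else 2


def survival_at(params: SurvParams, t):
    """Survival probability S(t), t in months (scalar or array)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    if params.family == "weibull":
        tp = np.where(t > 0, t, 1.0)  # avoid 0**gamma warnings; S(0)=1 anyway
        s = np.where(t > 0, np.exp(-params.lam * tp**params.gamma), 1.0)
    elif params.family == "exponential":
        s = np.exp(-params.rate * t)
    else:  # loglogistic
        s = 1.0 / (1.0 + (params.lam * t) ** params.gamma)
    return float(s) if s.ndim == 0 else s


def hazard_at(params: SurvParams, t):
    """Instantaneous hazard h(t) per month, t > 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("hazard requires t > 0")
    if params.family == "weibull":
        h = params.lam * params.gamma * t ** (params.gamma - 1.0)
    elif params.family == "exponential":
        h = np.full_like(t, params.rate)
    else:
        lt = (params.lam * t) ** params.gamma
        h = (params.gamma / t) * lt / (1.0 + lt)
    return float(h) if h.ndim == 0 else h


def apply_hazard_ratio(ref: SurvParams, hr: float) -> SurvParams:
    """Scale a reference law by a hazard ratio: lam' = lam*hr, shape kept.

    Valid for Weibull and exponential, where the hazard is proportional to
    the scale so that h'(t)/h(t) = hr for all t > 0.
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    if ref.family == "loglogistic":
        raise ValueError("hazard-ratio scaling is not hazard-proportional for the log-logistic family")
    if ref.family == "exponential":
        return replace(ref, lam=ref.rate * hr, intercept=None, cov=None)
    return replace(ref, lam=ref.lam * hr, cov=None)


def _check_ipd(ipd: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(ipd["time"], dtype=float)
    d = np.asarray(ipd["event"], dtype=int)
    if len(t) == 0:
        raise ValueError("empty IPD")
    if np.any(t <= 0):
        raise ValueError("event/censoring times must be positive")
    if d.sum() == 0:
        raise ValueError("no events in IPD; parametric fit is unidentified")
    return t, d


def _nll_weibull(theta, t, d):
    lam, gam = np.exp(theta)
    ll = np.sum(d * (np.log(lam) + np.log(gam) + (gam - 1) * np.log(t))) - lam * np.sum(t**gam)
    return -ll


def _nll_loglogistic(theta, t, d):
    lam, gam = np.exp(theta)
    lt = lam * t
    log_s = -np.log1p(lt**gam)
    log_f = np.log(lam) + np.log(gam) + (gam - 1) * np.log(lt) + 2 * log_s
    return -np.sum(d * log_f + (1 - d) * log_s)


def _numeric_hessian(fun, x, args, eps=1e-4):
    x = np.asarray(x, dtype=float)
    p = len(x)
    hess = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = eps
            ej = np.zeros(p); ej[j] = eps
            hess[i, j] = hess[j, i] = (
                fun(x + ei + ej, *args) - fun(x + ei - ej, *args)
                - fun(x - ei + ej, *args) + fun(x - ei - ej, *args)
            ) / (4 * eps * eps)
    return hess


def fit_parametric(ipd: pd.DataFrame, family: str) -> FitReport:
    """Right-censored maximum-likelihood fit of one family to IPD.

    ``ipd`` must have columns ``time`` (months) and ``event`` (1 event,
    0 censored). The exponential MLE is closed form; Weibull/log-logistic are
    optimized on (ln lam, ln gamma) from method-of-moments style starts, so
    the result is deterministic for a given dataset.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown survival family {family!r}")
    t, d = _check_ipd(ipd)
    n, events = len(t), int(d.sum())

    if family == "exponential":
        rate = events / t.sum()
        loglik = events * math.log(rate) - rate * t.sum()
        params = SurvParams("exponential", lam=rate,
                            cov=np.array([[1.0 / events]]))
        k = 1
    else:
        nll = _nll_weibull if family == "weibull" else _nll_loglogistic
        # moment-style starts: exponential rate for lam, shape grid for gamma
        rate0 = events / t.sum()
        starts = [np.log([rate0, g]) for g in (0.5, 1.0, 1.5, 2.5)]
        best = None
        for x0 in starts:
            res = optimize.minimize(nll, x0, args=(t, d), method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"{family} fit did not converge: {best}")
        lam, gam = np.exp(best.x)
        hess = _numeric_hessian(nll, best.x, (t, d))
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = None
        params = SurvParams(family, lam=lam, gamma=gam, cov=cov)
        loglik = -best.fun
        k = 2

    return FitReport(params=params, loglik=loglik, aic=2 * k - 2 * loglik,
                     bic=k * math.log(n) - 2 * loglik, n=n, events=events)


def rank_fits(reports: list[FitReport]) -> list[FitReport]:
    """Rank candidate fits on the same data by ascending AIC (ties: fewer parameters)."""
    if len(reports) < 2:
        raise ValueError("ranking needs at least two fit reports")
    ns = {r.n for r in reports}
    if len(ns) > 1:
        raise ValueError(f"fit reports come from different datasets (n = {sorted(ns)})")
    return sorted(reports, key=lambda r: (r.aic, r.k))
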