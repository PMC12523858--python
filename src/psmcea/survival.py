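"""Parametric survival families for extrapolating trial time-to-event curves.

Seven families are supported — exponential, Weibull, gamma, log-normal,
log-logistic, Gompertz and generalized gamma — the set recommended for
survival extrapolation in health-technology assessment.  Time is measured in
months throughout.  Parameterizations follow the conventions used in the
survival-analysis literature (and by R's flexsurv):

* exponential: ``(rate,)`` with S(t) = exp(-rate*t)
* weibull: ``(shape, scale)`` with S(t) = exp(-(t/scale)^shape)
* gamma: ``(shape, scale)``, scale in months
* lognormal: ``(mulog, sdlog)`` — mean and SD of log(time in months);
  S(t) = 1 - Phi((ln t - mulog)/sdlog), median = exp(mulog)
* loglogistic: ``(shape, scale)`` with S(t) = 1/(1 + (t/scale)^shape),
  median = scale (months)
* gompertz: ``(shape, rate)`` with hazard h(t) = rate*exp(shape*t); shape may
  be negative, in which case the distribution is improper (a fraction
  exp(rate/shape) never dies) — such models are flagged, not rejected
* gengamma: ``(mu, sigma, Q)`` — Prentice log-location form; Q=0 reduces to
  the log-normal, Q=1 to the Weibull.

Fitting is by maximum likelihood on right-censored data with a quasi-Newton
optimizer on log-transformed positive parameters and multiple starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "FAMILIES",
    "ParametricSurvival",
    "FitResult",
    "survival_probability",
    "fit_parametric",
    "information_criteria",
]

FAMILIES = (
    "exponential",
    "weibull",
    "gamma",
    "lognormal",
    "loglogistic",
    "gompertz",
    "gengamma",
)

_N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "gamma": 2,
    "lognormal": 2,
    "loglogistic": 2,
    "gompertz": 2,
    "gengamma": 3,
}

# which parameters must be strictly positive (by index)
_POSITIVE = {
    "exponential": (0,),
    "weibull": (0, 1),
    "gamma": (0, 1),
    "lognormal": (1,),
    "loglogistic": (0, 1),
    "gompertz": (1,),
    "gengamma": (1,),
}


def _as_time_array(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


@dataclass(frozen=True)
class ParametricSurvival:
    """A fitted or specified parametric survival curve S(t), t in months."""

    family: str
    params: tuple

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        params = tuple(float(p) for p in self.params)
        if len(params) != _N_PARAMS[self.family]:
            raise ValueError(
                f"{self.family} takes {_N_PARAMS[self.family]} parameters, got {len(params)}"
            )
        for i in _POSITIVE[self.family]:
            if not params[i] > 0:
                raise ValueError(
                    f"{self.family} parameter {i} must be strictly positive, got {params[i]}"
                )
        object.__setattr__(self, "params", params)

    # -- core functions ----------------------------------------------------

    def sf(self, t):
        """Survival function S(t)."""
        t = _as_time_array(t)
        return _sf(self.family, self.params, t)

    def logpdf(self, t):
        t = _as_time_array(t)
        return _logpdf(self.family, self.params, t)

    def logsf(self, t):
        t = _as_time_array(t)
        return _logsf(self.family, self.params, t)

    def pdf(self, t):
        return np.exp(self.logpdf(t))

    def ppf(self, q):
        """Quantile of the event-time distribution (inverse CDF)."""
        q = np.asarray(q, dtype=float)
        return _ppf(self.family, self.params, q)

    def rvs(self, size, rng):
        """Inverse-CDF sampling of event times."""
        return self.ppf(rng.uniform(size=size))

    def median(self):
        return float(self.ppf(0.5))

    @property
    def improper(self) -> bool:
        """True when S(t) does not tend to 0 (Gompertz with negative shape)."""
        return self.family == "gompertz" and self.params[0] < 0


def survival_probability(model: ParametricSurvival, t) -> float | np.ndarray:
    """Evaluate S(t) for ``model`` at time ``t`` (months)."""
    out = model.sf(t)
    return float(out) if np.ndim(t) == 0 else out


# ---------------------------------------------------------------------------
# family implementations


def _sf(family, p, t):
    if family == "exponential":
        return np.exp(-p[0] * t)
    if family == "weibull":
        return np.exp(-((t / p[1]) ** p[0]))
    if family == "gamma":
        return stats.gamma.sf(t, p[0], scale=p[1])
    if family == "lognormal":
        with np.errstate(divide="ignore"):
            z = np.where(t > 0, (np.log(np.maximum(t, 1e-300)) - p[0]) / p[1], -np.inf)
        return stats.norm.sf(z)
    if family == "loglogistic":
        return 1.0 / (1.0 + (t / p[1]) ** p[0])
    if family == "gompertz":
        a, b = p
        if abs(a) < 1e-12:
            return np.exp(-b * t)
        return np.exp(-b / a * np.expm1(a * t))
    if family == "gengamma":
        return _gengamma_sf(t, *p)
    raise AssertionError(family)


def _logsf(family, p, t):
    if family == "exponential":
        return -p[0] * t
    if family == "weibull":
        return -((t / p[1]) ** p[0])
    if family == "gamma":
        return stats.gamma.logsf(t, p[0], scale=p[1])
    if family == "lognormal":
        with np.errstate(divide="ignore"):
            z = np.where(t > 0, (np.log(np.maximum(t, 1e-300)) - p[0]) / p[1], -np.inf)
        return stats.norm.logsf(z)
    if family == "loglogistic":
        return -np.log1p((t / p[1]) ** p[0])
    if family == "gompertz":
        a, b = p
        if abs(a) < 1e-12:
            return -b * t
        return -b / a * np.expm1(a * t)
    if family == "gengamma":
        with np.errstate(divide="ignore"):
            return np.log(np.maximum(_gengamma_sf(t, *p), 1e-300))
    raise AssertionError(family)


def _logpdf(family, p, t):
    tiny = 1e-300
    if family == "exponential":
        return np.log(p[0]) - p[0] * t
    if family == "weibull":
        a, b = p
        lt = np.log(np.maximum(t, tiny))
        return np.log(a / b) + (a - 1) * (lt - np.log(b)) - (t / b) ** a
    if family == "gamma":
        return stats.gamma.logpdf(t, p[0], scale=p[1])
    if family == "lognormal":
        lt = np.log(np.maximum(t, tiny))
        z = (lt - p[0]) / p[1]
        return -0.5 * z * z - lt - np.log(p[1]) - 0.5 * np.log(2 * np.pi)
    if family == "loglogistic":
        a, b = p
        lt = np.log(np.maximum(t, tiny))
        u = a * (lt - np.log(b))
        return np.log(a / b) + (a - 1) * (lt - np.log(b)) - 2 * np.logaddexp(0.0, u)
    if family == "gompertz":
        a, b = p
        if abs(a) < 1e-12:
            return np.log(b) - b * t
        return np.log(b) + a * t - b / a * np.expm1(a * t)
    if family == "gengamma":
        return _gengamma_logpdf(t, *p)
    raise AssertionError(family)


def _ppf(family, p, q):
    if family == "exponential":
        return -np.log1p(-q) / p[0]
    if family == "weibull":
        return p[1] * (-np.log1p(-q)) ** (1.0 / p[0])
    if family == "gamma":
        return stats.gamma.ppf(q, p[0], scale=p[1])
    if family == "lognormal":
        return np.exp(p[0] + p[1] * stats.norm.ppf(q))
    if family == "loglogistic":
        return p[1] * (q / (1.0 - q)) ** (1.0 / p[0])
    if family == "gompertz":
        a, b = p
        if abs(a) < 1e-12:
            return -np.log1p(-q) / b
        arg = 1.0 - a / b * np.log1p(-q)
        # improper tail (a<0): quantiles beyond the cure fraction are infinite
        with np.errstate(invalid="ignore"):
            out = np.log(np.maximum(arg, 0.0)) / a
        return np.where(arg > 0, out, np.inf)
    if family == "gengamma":
        mu, sigma, Q = p
        if abs(Q) < 1e-8:
            return np.exp(mu + sigma * stats.norm.ppf(q))
        gam = Q ** -2.0
        if Q > 0:
            w = np.log(special.gammaincinv(gam, q) / gam) / Q
        else:
            w = np.log(special.gammaincinv(gam, 1.0 - q) / gam) / Q
        return np.exp(mu + sigma * w)
    raise AssertionError(family)


def _gengamma_sf(t, mu, sigma, Q):
    """Prentice generalized gamma survival; Q=0 is the log-normal limit."""
    t = np.maximum(np.asarray(t, dtype=float), 1e-300)
    w = (np.log(t) - mu) / sigma
    if abs(Q) < 1e-8:
        return stats.norm.sf(w)
    gam = Q ** -2.0
    with np.errstate(over="ignore"):  # exp overflow -> u = inf -> S at the limit
        u = gam * np.exp(Q * w)
    if Q > 0:
        return special.gammaincc(gam, u)
    return special.gammainc(gam, u)


def _gengamma_logpdf(t, mu, sigma, Q):
    t = np.maximum(np.asarray(t, dtype=float), 1e-300)
    lt = np.log(t)
    w = (lt - mu) / sigma
    if abs(Q) < 1e-8:
        return -0.5 * w * w - lt - np.log(sigma) - 0.5 * np.log(2 * np.pi)
    gam = Q ** -2.0
    with np.errstate(over="ignore"):  # exp overflow -> logpdf = -inf (density 0)
        return (
            np.log(abs(Q))
            + gam * np.log(gam)
            - special.gammaln(gam)
            + gam * (Q * w - np.exp(Q * w))
            - lt
            - np.log(sigma)
        )


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


@dataclass
class FitResult:
    """Maximum-likelihood fit of one family to right-censored data."""

    model: ParametricSurvival
    loglik: float
    n_params: int
    n_obs: int
    param_se: np.ndarray = field(repr=False)
    converged: bool = True
    message: str = ""

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_obs)


def _check_ipd(data: pd.DataFrame):
    if not {"time_months", "event"}.issubset(data.columns):
        raise ValueError("pseudo-IPD needs columns time_months and event")
    t = np.asarray(data["time_months"], dtype=float)
    e = np.asarray(data["event"], dtype=int)
    if np.any(t <= 0):
        raise ValueError("times must be strictly positive for fitting")
    if e.sum() < 2:
        raise ValueError("need at least 2 events to fit a survival model")
    return t, e


def _transform(family):
    """Map raw params <-> unconstrained optimizer space (log for positives)."""
    pos = set(_POSITIVE[family])
    n = _N_PARAMS[family]

    def to_opt(p):
        return np.array([np.log(v) if i in pos else v for i, v in enumerate(p)])

    def from_opt(x):
        # clamp before exp so wild optimizer excursions stay finite
        return tuple(
            np.exp(min(v, 100.0)) if i in pos else float(v) for i, v in enumerate(x)
        )

    return to_opt, from_opt, n


def _starts(family, t, e):
    """Moment-style starting values plus perturbations (3 starts)."""
    t_ev = t[e == 1]
    m = float(np.mean(t_ev))
    med = float(np.median(t_ev))
    lm, ls = float(np.mean(np.log(t_ev))), float(np.std(np.log(t_ev)) + 1e-3)
    base = {
        "exponential": (e.sum() / t.sum(),),
        "weibull": (1.2, m),
        "gamma": (1.2, m / 1.2),
        "lognormal": (lm, ls),
        "loglogistic": (1.5, med),
        "gompertz": (0.01, 1.0 / m),
        "gengamma": (lm, ls, 0.5),
    }[family]
    starts = [base]
    for f in (0.5, 2.0):
        starts.append(
            tuple(
                p * f if i in _POSITIVE[family] else p + (f - 1.0)
                for i, p in enumerate(base)
            )
        )
    return starts


def fit_parametric(data: pd.DataFrame, family: str) -> FitResult:
    """Fit ``family`` to right-censored records by maximum likelihood.

    ``data`` has columns ``time_months`` (>0) and ``event`` (1 event,
    0 censored).  Standard errors come from the observed information
    (numerical Hessian of the negative log-likelihood).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    t, e = _check_ipd(data)
    to_opt, from_opt, n = _transform(family)

    def nll(x):
        p = from_opt(x)
        try:
            ParametricSurvival(family, p)
        except ValueError:
            return 1e12
        ll = np.where(e == 1, _logpdf(family, p, t), _logsf(family, p, t))
        val = -np.sum(ll)
        return val if np.isfinite(val) else 1e12

    best = None
    for s in _starts(family, t, e):
        res = optimize.minimize(
            nll, to_opt(s), method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    params = from_opt(best.x)
    model = ParametricSurvival(family, params)
    se = _param_se(family, params, t, e)
    return FitResult(
        model=model,
        loglik=-float(best.fun),
        n_params=n,
        n_obs=len(t),
        param_se=se,
        converged=bool(best.success),
        message=str(best.message),
    )


def _param_se(family, params, t, e):
    """SEs from the observed information on the natural parameter scale."""
    p0 = np.asarray(params, dtype=float)
    n = len(p0)

    def nll(p):
        ll = np.where(e == 1, _logpdf(family, tuple(p), t), _logsf(family, tuple(p), t))
        return -np.sum(ll)

    h = np.maximum(np.abs(p0), 1e-3) * 1e-4
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            pp = p0.copy(); pp[i] += h[i]; pp[j] += h[j]
            pm = p0.copy(); pm[i] += h[i]; pm[j] -= h[j]
            mp = p0.copy(); mp[i] -= h[i]; mp[j] += h[j]
            mm = p0.copy(); mm[i] -= h[i]; mm[j] -= h[j]
            H[i, j] = H[j, i] = (nll(pp) - nll(pm) - nll(mp) + nll(mm)) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(n, np.nan)
    return se


def information_criteria(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fits of different families to the *same* data set.

    Sorted ascending by AIC; ties broken by BIC, then family name.
    """
    if not fits:
        raise ValueError("no fits supplied")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) > 1:
        raise ValueError(f"fits computed on differing n_obs: {sorted(n_obs)}")
    rows = [
        {
            "family": f.model.family,
            "aic": f.aic,
            "bic": f.bic,
            "loglik": f.loglik,
            "n_params": f.n_params,
            "params": ";".join(f"{p:.6g}" for p in f.model.params),
            "converged": f.converged,
        }
        for f in fits
    ]
    table = pd.DataFrame(rows).sort_values(
        ["aic", "bic", "family"], kind="mergesort"
    )
    return table.reset_index(drop=True)
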