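"""Bulk-fitting machinery: Hill induction curves and the Bayesian
errors-in-variables log-log slope.

Two statistical objects are fitted from bulk induction measurements:

1. A four-parameter Hill dose-response for the promoter activity at inducer
   concentration c,

       alpha(c) = b * (1 + f (c/k)^m) / (1 + (c/k)^m),

   with basal activity b, fold change f, critical inducer concentration k
   and Hill coefficient m.  The fit is weighted least squares in
   log-activity space with multi-start initialization.

2. A Bayesian straight-line fit of y = a x + b to (log doubling time,
   log critical concentration) pairs with per-point measurement errors
   sigma_i and an intrinsic model-data scatter sigma:

       P(D | a, b, sigma) = prod_i (2 pi (sigma^2 + sigma_i^2))^{-1/2}
                            * exp(-sum_i (y_i - a x_i - b)^2
                                        / (2 (sigma^2 + sigma_i^2)))

   with flat priors on (a, b) and a scale prior d sigma / sigma.  b is
   marginalized analytically, sigma is optimized, and the posterior of the
   slope a at the optimal sigma is Gaussian; its mean and SD are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import lmfit
from scipy.optimize import minimize_scalar

TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# induction curves and the Hill fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InductionCurve:
    """Dose-response measurements: activity (Miller-unit/h or fluorescence
    per OD) versus inducer concentration, with per-point uncertainties."""

    conc: np.ndarray      # µM, strictly increasing, >= 0
    activity: np.ndarray  # > 0 (fitted in log space)
    sigma: np.ndarray     # same units as activity, > 0

    def __post_init__(self) -> None:
        conc = np.asarray(self.conc, dtype=float)
        act = np.asarray(self.activity, dtype=float)
        sig = np.asarray(self.sigma, dtype=float)
        if not (len(conc) == len(act) == len(sig)):
            raise ValueError("conc, activity, sigma must have equal length")
        if np.any(conc < 0) or np.any(np.diff(conc) <= 0):
            raise ValueError("conc must be non-negative and strictly increasing")
        if np.any(act <= 0):
            raise ValueError("activity must be > 0 (log-space fit)")
        if np.any(sig <= 0):
            raise ValueError("sigma must be > 0")
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "activity", act)
        object.__setattr__(self, "sigma", sig)


def hill_activity(c, b: float, f: float, k: float, m: float):
    """The four-parameter Hill dose-response alpha(c)."""
    c = np.asarray(c, dtype=float)
    u = np.where(c > 0, (c / k) ** m, 0.0)
    return b * (1.0 + f * u) / (1.0 + u)


@dataclass(frozen=True)
class HillFit:
    b: float
    f: float
    k: float
    m: float
    b_se: float
    f_se: float
    k_se: float
    m_se: float
    rel_err_k: float      # SE of log k; the relative error of k
    identifiable: bool    # False when the fitted fold change < 1.2
    redchi: float

    UNIDENTIFIABLE_FOLD = 1.2

    def as_dict(self) -> dict:
        return {
            "b": self.b, "f": self.f, "k": self.k, "m": self.m,
            "b_se": self.b_se, "f_se": self.f_se, "k_se": self.k_se,
            "m_se": self.m_se, "rel_err_k": self.rel_err_k,
            "identifiable": self.identifiable, "redchi": self.redchi,
        }


def _hill_residuals(params, conc, log_act, sig_log):
    b = math.exp(params["log_b"].value)
    f = math.exp(params["log_f"].value)
    k = math.exp(params["log_k"].value)
    m = params["m"].value
    model = hill_activity(conc, b, f, k, m)
    return (np.log(model) - log_act) / sig_log


def fit_hill(curve: InductionCurve) -> HillFit:
    """Weighted least-squares Hill fit in log-activity space.

    Requires >= 5 points spanning at least one decade in concentration.
    Multi-start: the critical concentration is initialized at every observed
    positive concentration and the Hill coefficient at 1, 2 and 4; the best
    chi-square solution is kept.  Standard errors are asymptotic (from the
    covariance of the log-parameters, so ``k_se/k`` is the SE of log k).
    """
    conc, act, sig = curve.conc, curve.activity, curve.sigma
    if len(conc) < 5:
        raise ValueError("need >= 5 points for a Hill fit")
    pos = conc[conc > 0]
    if len(pos) < 2 or pos.max() / pos.min() < 10.0:
        raise ValueError("concentrations must span at least one decade")
    log_act = np.log(act)
    sig_log = sig / act

    span = np.ptp(log_act)
    f0 = max(float(np.exp(span)), 1.0 + 1e-6)
    b0 = float(act.min())

    best = None
    for k0 in pos:
        for m0 in (1.0, 2.0, 4.0):
            params = lmfit.Parameters()
            params.add("log_b", value=math.log(b0), min=math.log(b0) - 10, max=math.log(act.max()) + 2)
            params.add("log_f", value=math.log(f0), min=0.0, max=math.log(1e8))
            params.add("log_k", value=math.log(k0), min=math.log(pos.min()) - 5, max=math.log(pos.max()) + 5)
            params.add("m", value=m0, min=0.2, max=10.0)
            try:
                res = lmfit.minimize(
                    _hill_residuals, params, args=(conc, log_act, sig_log), method="leastsq"
                )
            except Exception:
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
    if best is None:
        raise RuntimeError("Hill fit failed to converge from every start")

    p = best.params
    b, f, k = (math.exp(p[n].value) for n in ("log_b", "log_f", "log_k"))
    m = p["m"].value

    def se_of(name, scale=1.0):
        err = p[name].stderr
        return float(err) * scale if err is not None else math.nan

    rel_err_k = se_of("log_k")
    return HillFit(
        b=b, f=f, k=k, m=m,
        b_se=se_of("log_b", b), f_se=se_of("log_f", f),
        k_se=se_of("log_k", k), m_se=se_of("m"),
        rel_err_k=rel_err_k,
        identifiable=f >= HillFit.UNIDENTIFIABLE_FOLD,
        redchi=float(best.redchi),
    )


# ---------------------------------------------------------------------------
# Bayesian log-log slope with intrinsic scatter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlopePoint:
    x: float        # log doubling time
    y: float        # log critical concentration
    sigma_i: float  # measurement SD of y

    def __post_init__(self) -> None:
        if self.sigma_i <= 0:
            raise ValueError("sigma_i must be > 0")


@dataclass(frozen=True)
class SlopeFit:
    a_mean: float     # posterior mean slope (at optimal sigma)
    a_sd: float       # posterior SD of the slope
    sigma_hat: float  # optimized intrinsic scatter
    b_profile: float  # intercept at the posterior-mean slope


def slope_log_likelihood(points: Sequence[SlopePoint], a: float, b: float, sigma: float) -> float:
    """Exact log P(D | a, b, sigma): Gaussian residuals with total variance
    sigma^2 + sigma_i^2 per point, including normalization."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    x = np.array([p.x for p in points])
    y = np.array([p.y for p in points])
    v = sigma ** 2 + np.array([p.sigma_i for p in points]) ** 2
    resid = y - a * x - b
    return float(-0.5 * np.sum(np.log(TWO_PI * v)) - np.sum(resid ** 2 / (2.0 * v)))


def _marginal_a_posterior(x, y, v):
    """After analytic marginalization of the intercept (flat prior), the
    posterior over the slope a is Gaussian N(B/A, 1/A); returns
    (a_mean, a_var, log marginal likelihood with a also integrated out)."""
    w = 1.0 / v
    S0 = w.sum()
    Sx = (w * x).sum()
    Sy = (w * y).sum()
    Sxx = (w * x * x).sum()
    Sxy = (w * x * y).sum()
    Syy = (w * y * y).sum()
    A = Sxx - Sx * Sx / S0
    B = Sxy - Sx * Sy / S0
    C = Syy - Sy * Sy / S0
    if A <= 0:
        raise ValueError("slope undefined: all x values identical")
    log_ml = (
        -0.5 * np.sum(np.log(TWO_PI * v))
        + 0.5 * math.log(TWO_PI / S0)
        + 0.5 * math.log(TWO_PI / A)
        - 0.5 * (C - B * B / A)
    )
    return B / A, 1.0 / A, float(log_ml)


def fit_loglog_slope(
    points: Sequence[SlopePoint],
    *,
    sigma_bounds: tuple[float, float] = (1e-4, 10.0),
) -> SlopeFit:
    """Posterior slope of y versus x with intrinsic scatter.

    The intercept is marginalized analytically under a flat prior; the
    intrinsic scatter sigma is profiled out by maximizing the (a, b)-
    marginalized posterior under a scale prior d sigma/sigma (bounded
    golden-section search on log sigma); the slope posterior at the optimal
    sigma is Gaussian.
    """
    if len(points) < 2:
        raise ValueError("need >= 2 points to fit a slope")
    x = np.array([p.x for p in points])
    y = np.array([p.y for p in points])
    s2 = np.array([p.sigma_i for p in points]) ** 2
    if np.allclose(x, x[0]):
        raise ValueError("slope undefined: all x values identical")

    def neg_log_post(log_sigma: float) -> float:
        v = math.exp(log_sigma) ** 2 + s2
        return -_marginal_a_posterior(x, y, v)[2]

    res = minimize_scalar(
        neg_log_post,
        bounds=(math.log(sigma_bounds[0]), math.log(sigma_bounds[1])),
        method="bounded",
        options=dict(xatol=1e-10),
    )
    sigma_hat = math.exp(res.x)
    v = sigma_hat ** 2 + s2
    a_mean, a_var, _ = _marginal_a_posterior(x, y, v)
    w = 1.0 / v
    b_profile = float(((w * y).sum() - a_mean * (w * x).sum()) / w.sum())
    return SlopeFit(
        a_mean=float(a_mean), a_sd=float(math.sqrt(a_var)),
        sigma_hat=sigma_hat, b_profile=b_profile,
    )
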