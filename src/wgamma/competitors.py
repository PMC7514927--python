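"""Comparison lifetime models: gamma, Weibull, exponentiated exponential
(EE) and exponentiated gamma (EG).

The EE and EG laws raise a classical cdf to a power alpha, adding one
shape parameter.  The EE is parameterized with a *scale* s,
F(x) = (1 - exp(-x/s))^alpha; the EG exponentiates the regularized
lower incomplete gamma, F(x) = [P(k, x/s)]^alpha.

All fits are maximum likelihood over log-parameters (positivity by
construction) with a moment-matched multi-start grid, a Nelder-Mead
search and a quasi-Newton polish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats


@dataclass(frozen=True)
class GammaParams:
    k: float  # shape
    s: float  # scale

    def __post_init__(self):
        _check_positive(self)


@dataclass(frozen=True)
class WeibullParams:
    c: float  # shape
    beta: float  # scale

    def __post_init__(self):
        _check_positive(self)


@dataclass(frozen=True)
class EEParams:
    alpha: float  # power (shape)
    s: float  # scale

    def __post_init__(self):
        _check_positive(self)


@dataclass(frozen=True)
class EGParams:
    alpha: float  # power
    k: float  # gamma shape
    s: float  # scale

    def __post_init__(self):
        _check_positive(self)


def _check_positive(obj) -> None:
    for name, v in vars(obj).items():
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be > 0 and finite, got {v!r}")


# ---------------------------------------------------------------------------
# densities and cdfs


def model_logpdf(x, params):
    """Log-density of any of the four comparison models."""
    x = np.asarray(x, dtype=float)
    if isinstance(params, GammaParams):
        return stats.gamma.logpdf(x, params.k, scale=params.s)
    if isinstance(params, WeibullParams):
        return stats.weibull_min.logpdf(x, params.c, scale=params.beta)
    if isinstance(params, EEParams):
        a, s = params.alpha, params.s
        with np.errstate(divide="ignore"):
            u = -np.expm1(-x / s)
            return np.log(a) - np.log(s) - x / s + (a - 1.0) * np.log(u)
    if isinstance(params, EGParams):
        a, k, s = params.alpha, params.k, params.s
        with np.errstate(divide="ignore"):
            logP = np.log(special.gammainc(k, x / s))
            return np.log(a) + (a - 1.0) * logP + stats.gamma.logpdf(x, k, scale=s)
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


def model_cdf(x, params):
    """Cdf of any of the four comparison models."""
    x = np.asarray(x, dtype=float)
    if isinstance(params, GammaParams):
        return stats.gamma.cdf(x, params.k, scale=params.s)
    if isinstance(params, WeibullParams):
        return stats.weibull_min.cdf(x, params.c, scale=params.beta)
    if isinstance(params, EEParams):
        u = -np.expm1(-np.maximum(x, 0.0) / params.s)
        return u ** params.alpha
    if isinstance(params, EGParams):
        return special.gammainc(params.k, np.maximum(x, 0.0) / params.s) ** params.alpha
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


# ---------------------------------------------------------------------------
# maximum likelihood


def _multistart_mle(nll, starts, n_params):
    """Shared optimizer: log-space Nelder-Mead + BFGS polish per start."""
    best = None
    for x0 in starts:
        t0 = np.log(np.asarray(x0, dtype=float))
        try:
            r = optimize.minimize(
                nll, t0, method="Nelder-Mead",
                options=dict(xatol=1e-10, fatol=1e-10, maxiter=4000, maxfev=4000),
            )
            r2 = optimize.minimize(nll, r.x, method="BFGS", options=dict(maxiter=300))
            cand = r2 if np.isfinite(r2.fun) and r2.fun < r.fun else r
        except Exception:
            continue
        if np.isfinite(cand.fun) and (best is None or cand.fun < best.fun):
            best = cand
    return best


def _make_fit(model, estimates, loglik, n_obs, converged, n_starts):
    from .inference import FitResult  # local import to avoid a cycle

    n_params = len(estimates)
    return FitResult(
        model=model,
        estimates=dict(estimates),
        loglik=float(loglik),
        n_params=n_params,
        aic=2.0 * n_params - 2.0 * float(loglik),
        converged=bool(converged),
        n_obs=int(n_obs),
        n_starts_used=int(n_starts),
    )


def _validate_sample(data):
    x = np.asarray(data, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("all observations must be positive and finite")
    return x


def _perturbed(base, factors=(1.0, 0.5, 2.0)):
    for f in factors:
        yield tuple(b * f for b in base)


def fit_gamma(data):
    """MLE of the two-parameter gamma model."""
    x = _validate_sample(data)
    m, v = x.mean(), x.var()
    base = (max(m * m / v, 1e-3), max(v / m, 1e-12))

    def nll(t):
        k, s = np.exp(t)
        val = stats.gamma.logpdf(x, k, scale=s).sum()
        return -val if np.isfinite(val) else 1e12

    best = _multistart_mle(nll, list(_perturbed(base)), 2)
    k, s = np.exp(best.x)
    return _make_fit("gamma", {"k": k, "s": s}, -best.fun, x.size, best is not None, 3)


def fit_weibull(data):
    """MLE of the two-parameter Weibull model (cdf 1 - exp(-(x/beta)^c))."""
    x = _validate_sample(data)
    base = (1.2, x.mean())

    def nll(t):
        c, b = np.exp(t)
        val = stats.weibull_min.logpdf(x, c, scale=b).sum()
        return -val if np.isfinite(val) else 1e12

    best = _multistart_mle(nll, list(_perturbed(base)), 2)
    c, b = np.exp(best.x)
    return _make_fit("weibull", {"c": c, "beta": b}, -best.fun, x.size, best is not None, 3)


def fit_ee(data):
    """MLE of the exponentiated exponential, cdf (1 - e^(-x/s))^alpha."""
    x = _validate_sample(data)
    base = (1.0, x.mean())

    def nll(t):
        a, s = np.exp(t)
        u = -np.expm1(-x / s)
        val = (np.log(a) - np.log(s) - x / s + (a - 1.0) * np.log(u)).sum()
        return -val if np.isfinite(val) else 1e12

    best = _multistart_mle(nll, list(_perturbed(base)), 2)
    a, s = np.exp(best.x)
    return _make_fit("ee", {"alpha": a, "s": s}, -best.fun, x.size, best is not None, 3)


def fit_eg(data):
    """MLE of the exponentiated gamma, cdf [P(k, x/s)]^alpha."""
    x = _validate_sample(data)
    m, v = x.mean(), x.var()
    k0, s0 = max(m * m / v, 1e-3), max(v / m, 1e-12)
    # the EG likelihood is ridged like the W-g's; spread the starts
    starts = [
        (1.0, k0, s0),
        (0.05, 10.0 * k0, 0.1 * s0),
        (5.0, 0.3 * k0, s0),
        (0.5, k0, 2.0 * s0),
        (10.0, 0.1 * k0, 3.0 * s0),
    ]

    def nll(t):
        a, k, s = np.exp(t)
        if a > 1e8 or k > 1e8 or s > 1e10:
            return 1e12
        with np.errstate(divide="ignore"):
            logP = np.log(special.gammainc(k, x / s))
        val = (np.log(a) + (a - 1.0) * logP + stats.gamma.logpdf(x, k, scale=s)).sum()
        return -val if np.isfinite(val) else 1e12

    best = _multistart_mle(nll, starts, 3)
    a, k, s = np.exp(best.x)
    return _make_fit(
        "eg", {"alpha": a, "k": k, "s": s}, -best.fun, x.size, best is not None, len(starts)
    )
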