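"""Algebraic series expansions of the W-g distribution.

The W-g density can be rearranged into a weighted sum of gamma-type
kernels ``A * x^(k*M + a5 - 1) * exp(-x/s)`` over five summation
indices, by expanding in turn the outer Weibull exponential, the
``1/w`` factor, the power of ``-log(1-G)`` (a generalized binomial
expansion with recursively defined constants ``p``), the incomplete
gamma power series, and finally raising that power series to a real
exponent (the ``q`` recursion).  The expansion yields closed forms for
moments, the mgf and the characteristic function, term by term.

Two caveats, both documented in docs/methods.md:

* the denominator factor ``a1*c + c - a4 - 1`` vanishes exactly when the
  log-power exponent is a non-negative integer; there it always meets a
  zero of the generalized binomial coefficient and the finite 0*inf
  limit must be taken (``singular="limit"``, the default) — dropping the
  tuples (``singular="skip"``) loses mass;
* the rearrangement is formal: for larger abscissae or moment orders the
  truncated sums diverge, so every evaluator returns a convergence
  diagnostic and the recommended public route for moments/mgf/cf is
  adaptive quadrature or Monte Carlo against the closed-form density.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import integrate, special

from .distribution import WgParams, wg_logpdf, wg_quantile, wg_rvs

__all__ = [
    "SeriesCoeffs",
    "SeriesResult",
    "p_coefficients",
    "power_series_power",
    "A_coefficient",
    "pdf_series",
    "cdf_series",
    "moment",
    "mgf",
    "cf",
]

_BLOCK_TOL = 1e-12
_DEFAULT_ORDER = 20


@dataclass
class SeriesResult:
    """Value of a truncated expansion plus its convergence diagnostic."""

    value: float | complex
    converged: bool
    last_block: float  # magnitude of the last total-index block added
    order: int

    def __float__(self) -> float:
        return float(self.value)


@dataclass
class SeriesCoeffs:
    """Truncated expansion tables for a fixed parameter vector.

    p_table[a4, a3] are the log-power constants, c_seq the alternating
    harmonic-type factors, q_table the powered incomplete-gamma series
    coefficients for exponent ``m``, and A the five-index coefficient
    array A[a1, a2, a3, a4, a5].
    """

    order: int
    p_table: np.ndarray
    c_seq: np.ndarray
    q_table: dict = field(default_factory=dict)
    A: np.ndarray | None = None


@lru_cache(maxsize=None)
def _p_value(a4: int, a3: int) -> float:
    if a4 < 0 or a3 < 0:
        raise ValueError("p-recursion indices must be non-negative")
    if a3 == 0:
        return 1.0
    tot = 0.0
    for l in range(1, a3 + 1):
        c_l = (-1.0) ** (l + 1) / (l + 1.0)
        tot += (a3 - l * (a4 + 1)) * c_l * _p_value(a4, a3 - l)
    return tot / a3


def p_coefficients(a4: int, a3_max: int) -> np.ndarray:
    """Constants p_{a4, 0..a3_max} of the (-log(1-x))^a expansion.

    p_{a4,0} = 1 and, for a3 >= 1,
    p_{a4,a3} = (1/a3) * sum_{l=1..a3} [a3 - l(a4+1)] c_l p_{a4,a3-l}
    with c_l = (-1)^(l+1) / (l+1).
    """
    if a4 < 0 or a3_max < 0:
        raise ValueError("indices must be non-negative integers")
    return np.array([_p_value(a4, a3) for a3 in range(a3_max + 1)])


def power_series_power(q_base, m: float, order: int) -> np.ndarray:
    """Coefficients of (sum_j a_j x^j)^m up to x^order.

    q_0 = a_0^m and, for v >= 1,
    q_v = (1/(v a_0)) * sum_{j=1..v} (j*m - v + j) a_j q_{v-j}.
    """
    a = np.zeros(order + 1)
    base = np.asarray(q_base, dtype=float)
    a[: min(len(base), order + 1)] = base[: order + 1]
    if a[0] == 0.0:
        raise ValueError("the base series must have a non-zero constant term")
    q = np.zeros(order + 1)
    q[0] = a[0] ** m
    for v in range(1, order + 1):
        acc = 0.0
        for j in range(1, v + 1):
            acc += (j * m - v + j) * a[j] * q[v - j]
        q[v] = acc / (v * a[0])
    return q


@lru_cache(maxsize=None)
def _gamma_series_base(k: float, order: int) -> tuple:
    """Coefficients a_j = (-1)^j / (j! (k+j)) of gamma(k, z) / z^k."""
    return tuple((-1.0) ** j / (math.factorial(j) * (k + j)) for j in range(order + 1))


@lru_cache(maxsize=None)
def _q_seq(m: float, k: float, order: int) -> tuple:
    return tuple(power_series_power(_gamma_series_base(k, order), m, order))


def _gbinom(z: float, n: int) -> float:
    """Generalized binomial coefficient C(z, n) for integer n >= 0."""
    out = 1.0
    for j in range(n):
        out *= (z - j) / (j + 1.0)
    return out


def _log_power_prefactor(a: float, a3: int, singular: str = "limit") -> float:
    """a4-sum of the (-log(1-x))^a expansion weight at order a3.

    Returns  a * sum_{a4<=a3} (-1)^(a3+a4) C(a3-a, a3) C(a3, a4)
                 p_{a4,a3} / (a - a4),
    with the 0*inf tuples at integer a evaluated by their limit
    (-1)^a4 (a4-1)! (a3-a4)! / a3!  unless singular == "skip".
    """
    if abs(a) < 1e-12:
        return 1.0 if a3 == 0 else 0.0
    tot = 0.0
    for a4 in range(a3 + 1):
        p = _p_value(a4, a3)
        d = a - a4
        if abs(d) < 1e-12:
            if singular == "skip":
                warnings.warn(
                    f"skipping singular expansion tuple a={a}, a3={a3}, a4={a4}",
                    RuntimeWarning,
                    stacklevel=3,
                )
                continue
            lim = (
                (-1.0) ** a4
                * math.factorial(a4 - 1)
                * math.factorial(a3 - a4)
                / math.factorial(a3)
            )
            tot += (-1.0) ** (a3 + a4) * special.binom(a3, a4) * p * lim
        else:
            tot += (-1.0) ** (a3 + a4) * _gbinom(a3 - a, a3) * special.binom(a3, a4) * p / d
    return a * tot


def A_coefficient(a1: int, a2: int, a3: int, a4: int, a5: int, params: WgParams,
                  order: int | None = None, singular: str = "limit") -> float:
    """Single five-index expansion coefficient A_{a1,a2,a3,a4,a5}.

    A = c (-1)^(a1+a3+a4) (a1c+c-1) C(a3-(a1c+c-1), a3) C(a3, a4)
        p_{a4,a3} q_{a5} /
        [Gamma(k)^(a1c+c+a2+a3) a1! s^(k(a1c+c+a2+a3)+a5) beta^(a1c+c)
         (a1c+c-a4-1)]

    with q the powered incomplete-gamma coefficients for exponent
    m = a1c + c + a2 + a3 - 1.  When the denominator factor vanishes the
    continuity limit is substituted (``singular="limit"``); with
    ``singular="skip"`` the tuple evaluates to 0 with a warning.
    """
    if a4 > a3:
        raise ValueError("a4 must not exceed a3")
    if min(a1, a2, a3, a4, a5) < 0:
        raise ValueError("indices must be non-negative")
    c, b, k, s = params.c, params.beta, params.k, params.s
    a = a1 * c + c - 1.0
    M = a1 * c + c + a2 + a3
    if order is None:
        order = max(_DEFAULT_ORDER, a5)
    q = _q_seq(M - 1.0, k, max(order, a5))[a5]
    p = _p_value(a4, a3)
    d = a - a4
    if abs(d) < 1e-12:
        if singular == "skip":
            warnings.warn(
                f"singular denominator at tuple ({a1},{a2},{a3},{a4},{a5}); skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            return 0.0
        if a4 == 0:
            # whole a-prefactor vanishes with a -> 0
            core = 1.0 if a3 == 0 else 0.0
        else:
            lim = (
                (-1.0) ** a4
                * math.factorial(a4 - 1)
                * math.factorial(a3 - a4)
                / math.factorial(a3)
            )
            core = a * (-1.0) ** (a3 + a4) * special.binom(a3, a4) * p * lim
    else:
        core = a * (-1.0) ** (a3 + a4) * _gbinom(a3 - a, a3) * special.binom(a3, a4) * p / d
    sign = (-1.0) ** a1  # (-1)^(a3+a4) already inside `core`
    denom = math.gamma(k) ** M * math.factorial(a1) * s ** (k * M + a5) * b ** (a1 * c + c)
    return c * sign * core * q / denom


def _pdf_blocks(x: float, params: WgParams, order: int, singular: str):
    """Per-total-index blocks of the density expansion at one abscissa."""
    c, b, k, s = params.c, params.beta, params.k, params.s
    lgk = special.gammaln(k)
    blocks = np.zeros(4 * order + 1)
    for a1 in range(order + 1):
        a = a1 * c + c - 1.0
        f1 = c * (-1.0) ** a1 / (math.factorial(a1) * b ** (a1 * c + c))
        for a3 in range(order + 1):
            lp = _log_power_prefactor(a, a3, singular)
            if lp == 0.0:
                continue
            for a2 in range(order + 1):
                M = a1 * c + c + a2 + a3
                q = _q_seq(M - 1.0, k, order)
                base = f1 * lp
                for a5 in range(order + 1):
                    power = k * M + a5 - 1.0
                    t = base * q[a5] * math.exp(
                        power * math.log(x) - x / s - M * lgk - (k * M + a5) * math.log(s)
                    )
                    blocks[a1 + a2 + a3 + a5] += t
    return blocks


def pdf_series(x: float, params: WgParams, order: int = _DEFAULT_ORDER,
               singular: str = "limit") -> SeriesResult:
    """Density via the truncated five-index expansion, with diagnostic."""
    if x <= 0:
        raise ValueError("the expansion is defined for x > 0")
    blocks = _pdf_blocks(float(x), params, order, singular)
    scale = math.exp(min(wg_logpdf(x, params), 50.0)) if np.isfinite(wg_logpdf(x, params)) else 1.0
    return _finish(blocks, order, scale)


def _finish(blocks: np.ndarray, order: int, scale: float) -> SeriesResult:
    total = 0.0
    for N, bN in enumerate(blocks):
        total += bN
        if N > 0 and abs(bN) < _BLOCK_TOL * max(scale, abs(total), 1e-30):
            return SeriesResult(total, True, abs(bN), order)
    tail = np.abs(blocks[-4:])
    converged = bool(np.all(tail <= max(1e-8 * max(scale, abs(total)), 1e-15)))
    return SeriesResult(total, converged, float(abs(blocks[-1])), order)


def cdf_series(x: float, params: WgParams, order: int = _DEFAULT_ORDER,
               singular: str = "limit") -> SeriesResult:
    """Cdf via the expansion of the survival sum: F = 1 - sum(...).

    The log-power exponent here is a = a1*c (no density Jacobian), so
    the denominator factor is (a1*c - a4); the index a2 is absent.
    """
    if x <= 0:
        raise ValueError("the expansion is defined for x > 0")
    c, b, k, s = params.c, params.beta, params.k, params.s
    lgk = special.gammaln(k)
    blocks = np.zeros(3 * order + 1)
    for a1 in range(order + 1):
        a = a1 * c
        f1 = (-1.0) ** a1 / (math.factorial(a1) * b ** (a1 * c))
        for a3 in range(order + 1):
            lp = _log_power_prefactor(a, a3, singular)
            if lp == 0.0:
                continue
            M = a1 * c + a3
            q = _q_seq(float(M), k, order) if M > 0 else None
            for a5 in range(order + 1):
                qv = q[a5] if q is not None else (1.0 if a5 == 0 else 0.0)
                t = f1 * lp * qv * math.exp(
                    (k * M + a5) * math.log(x) - M * lgk - (k * M + a5) * math.log(s)
                )
                blocks[a1 + a3 + a5] += t
    # blocks sum to the survival function; F = 1 - sum
    sf = _finish(blocks, order, 1.0)
    return SeriesResult(1.0 - sf.value, sf.converged, sf.last_block, order)


def moment(r: int, params: WgParams, method: str = "quadrature",
           order: int = _DEFAULT_ORDER, n_mc: int = 100_000, seed=0,
           tol: float = 1e-10):
    """r-th raw moment E[X^r].

    method="series"     : term-by-term closed form
                          sum A * s^r * Gamma(r + k*M + a5) over tuples,
                          returned as a SeriesResult (the rearranged sum
                          diverges outside a narrow parameter range —
                          check ``converged``);
    method="quadrature" : adaptive integration of x^r f(x) (default);
    method="mc"         : average of x^r over inverse-transform draws.
    """
    if r < 1 or not isinstance(r, (int, np.integer)):
        raise ValueError("r must be a positive integer")
    if method == "quadrature":
        return _integrate_against_pdf(lambda x: x ** r, params, tol)
    if method == "mc":
        x = wg_rvs(n_mc, params, seed)
        return float(np.mean(x ** r))
    if method != "series":
        raise ValueError(f"unknown method {method!r}")
    c, b, k, s = params.c, params.beta, params.k, params.s
    lgk = special.gammaln(k)
    blocks = np.zeros(4 * order + 1)
    for a1 in range(order + 1):
        a = a1 * c + c - 1.0
        f1 = c * (-1.0) ** a1 / math.factorial(a1)
        for a3 in range(order + 1):
            lp = _log_power_prefactor(a, a3, "limit")
            if lp == 0.0:
                continue
            for a2 in range(order + 1):
                M = a1 * c + c + a2 + a3
                q = _q_seq(M - 1.0, k, order)
                base = f1 * lp / b ** (a1 * c + c)
                for a5 in range(order + 1):
                    t = base * q[a5] * s ** r * math.exp(
                        special.gammaln(r + k * M + a5) - M * lgk
                    )
                    blocks[a1 + a2 + a3 + a5] += t
    scale = abs(blocks[0]) if blocks[0] != 0 else 1.0
    return _finish(blocks, order, scale)


def _integrate_against_pdf(g, params: WgParams, tol: float,
                           log_weight=None) -> float:
    """Adaptive quadrature of g(x) f(x) over (0, inf), split at quantiles.

    ``log_weight`` replaces ``g`` by exp(log_weight(x)) combined with the
    log-density before exponentiation, for weights like e^(t x) that
    overflow on their own.
    """
    pts = [float(wg_quantile(p, params)) for p in (0.05, 0.25, 0.5, 0.75, 0.95)]
    pts = [p for p in pts if np.isfinite(p) and p > 0]

    def integrand(x):
        lp = wg_logpdf(x, params)
        if lp == -np.inf:
            return 0.0
        if log_weight is not None:
            arg = log_weight(x) + lp
            return math.exp(arg) if arg < 700.0 else math.exp(700.0)
        return g(x) * math.exp(min(lp, 700.0))

    total = 0.0
    edges = [0.0] + sorted(set(pts))
    for lo, hi in zip(edges[:-1], edges[1:]):
        val, _ = integrate.quad(integrand, lo, hi, epsabs=tol, epsrel=tol, limit=200)
        total += val
    val, _ = integrate.quad(integrand, edges[-1], np.inf, epsabs=tol, epsrel=tol, limit=200)
    return total + val


def mgf(t: float, params: WgParams, method: str = "quadrature",
        order: int = _DEFAULT_ORDER, tol: float = 1e-10):
    """Moment generating function E[e^{tX}], defined for t < 1/s.

    The series closed form replaces the gamma-kernel integral by
    Gamma(k*M + a5) (1 - t*s)^-(k*M + a5); quadrature is the default.
    """
    s = params.s
    if t >= 1.0 / s:
        raise ValueError(
            f"mgf requires t < 1/s = {1.0 / s:g} (the integral defining "
            "E[e^(tX)] converges only when 1 - t*s > 0)"
        )
    if t == 0.0:
        return 1.0
    if method == "quadrature":
        return _integrate_against_pdf(None, params, tol, log_weight=lambda x: t * x)
    if method != "series":
        raise ValueError(f"unknown method {method!r}")
    res = _transform_series(params, order, lambda kMa5: (1.0 - t * s) ** (-kMa5))
    res.value = float(np.real(res.value))
    return res


def cf(t: float, params: WgParams, method: str = "quadrature",
       order: int = _DEFAULT_ORDER, tol: float = 1e-10):
    """Characteristic function E[e^{itX}]; |cf| <= 1 always."""
    if t == 0.0:
        return complex(1.0, 0.0)
    s = params.s
    if method == "quadrature":
        re = _integrate_against_pdf(lambda x: math.cos(t * x), params, tol)
        im = _integrate_against_pdf(lambda x: math.sin(t * x), params, tol)
        return complex(re, im)
    if method != "series":
        raise ValueError(f"unknown method {method!r}")
    return _transform_series(params, order, lambda kMa5: (1.0 - 1j * t * s) ** (-kMa5))


def _transform_series(params: WgParams, order: int, kernel):
    """Shared series evaluator for mgf/cf: sum A * Gamma(kM+a5) * kernel."""
    c, b, k, s = params.c, params.beta, params.k, params.s
    lgk = special.gammaln(k)
    blocks = np.zeros(4 * order + 1, dtype=complex)
    for a1 in range(order + 1):
        a = a1 * c + c - 1.0
        f1 = c * (-1.0) ** a1 / (math.factorial(a1) * b ** (a1 * c + c))
        for a3 in range(order + 1):
            lp = _log_power_prefactor(a, a3, "limit")
            if lp == 0.0:
                continue
            for a2 in range(order + 1):
                M = a1 * c + c + a2 + a3
                q = _q_seq(M - 1.0, k, order)
                for a5 in range(order + 1):
                    kMa5 = k * M + a5
                    t = f1 * lp * q[a5] * math.exp(special.gammaln(kMa5) - M * lgk) * kernel(kMa5)
                    blocks[a1 + a2 + a3 + a5] += t
    total = 0.0 + 0.0j
    scale = abs(blocks[0]) if blocks[0] != 0 else 1.0
    for N, bN in enumerate(blocks):
        total += bN
        if N > 0 and abs(bN) < _BLOCK_TOL * max(scale, abs(total)):
            return SeriesResult(total, True, abs(bN), order)
    converged = bool(np.all(np.abs(blocks[-4:]) <= 1e-8 * max(scale, abs(total))))
    return SeriesResult(total, converged, float(abs(blocks[-1])), order)


def series_coefficients(params: WgParams, order: int = 6) -> SeriesCoeffs:
    """Materialize the truncated coefficient tables up to ``order``."""
    p_table = np.array([p_coefficients(a4, order) for a4 in range(order + 1)])
    c_seq = np.array([(-1.0) ** (a3 + 1) / (a3 + 1.0) for a3 in range(1, order + 2)])
    A = np.zeros((order + 1,) * 5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for a1 in range(order + 1):
            for a2 in range(order + 1):
                for a3 in range(order + 1):
                    for a4 in range(a3 + 1):
                        for a5 in range(order + 1):
                            A[a1, a2, a3, a4, a5] = A_coefficient(
                                a1, a2, a3, a4, a5, params, order=order
                            )
    return SeriesCoeffs(order=order, p_table=p_table, c_seq=c_seq, A=A)
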