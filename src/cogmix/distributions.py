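"""Count-distribution kernels for the assessment metrics.

Conway-Maxwell (CM) generalizations of the Poisson, binomial, and
multinomial families add a dispersion exponent ``nu`` on the combinatorial
part of the kernel, accommodating both over-dispersion (``nu < 1``) and
under-dispersion (``nu > 1``); ``nu = 1`` recovers the classical family.
Zero-inflated and N-inflated variants mix in a point mass at the minimum or
maximum of the support to absorb excess boundary observations (task refusal,
ceiling effects).  A lognormal family is included for age-only baseline
models.

Every family exposes a log-PMF (or log-density), a CDF, exact inverse-CDF
sampling, and weighted maximum-likelihood fitting; the weighted fit is what
the mixture model's M-step calls with posterior responsibilities as weights.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

__all__ = [
    "NormalizationError",
    "CMPoissonParams",
    "CMBinomialParams",
    "CMMultinomialParams",
    "LognormalParams",
    "cm_poisson_log_pmf",
    "cm_binomial_log_pmf",
    "cm_multinomial_log_pmf",
    "lognormal_log_pdf",
    "discrete_cdf",
    "pmf_table",
    "support_upper",
    "compositions",
    "sample",
    "fit_weighted",
    "moments",
    "params_to_json",
    "params_from_json",
]

# Numerical guards shared by fitting and EM: probabilities clipped away from
# {0,1}, dispersion kept in a range where normalizers are well conditioned.
PROB_FLOOR = 1e-6
NU_MIN = 1e-4
NU_MAX = 50.0
_SERIES_RTOL = 1e-12
_SERIES_MAX_TERMS = 10_000


class NormalizationError(ValueError):
    """The normalizing series of a CM-Poisson kernel does not converge."""


# ---------------------------------------------------------------------------
# Parameter bundles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CMPoissonParams:
    """Zero-inflated Conway-Maxwell Poisson: rate ``lam``, dispersion ``nu``,
    zero-inflation weight ``pi0``."""

    lam: float
    nu: float
    pi0: float = 0.0

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"lam must be positive, got {self.lam}")
        if self.nu < 0:
            raise ValueError(f"nu must be non-negative, got {self.nu}")
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError(f"pi0 must lie in [0, 1], got {self.pi0}")
        if self.nu == 0 and self.lam >= 1:
            raise NormalizationError(
                "CM-Poisson with nu=0 and lam>=1 has a divergent normalizer"
            )


@dataclass(frozen=True)
class CMBinomialParams:
    """Conway-Maxwell binomial on {0..n} with optional boundary inflation.

    ``inflation`` is one of ``"none"``, ``"zero"`` (point mass at 0) or
    ``"N"`` (point mass at n); ``pi_inf`` is the inflation weight.
    """

    n: int
    p: float
    nu: float
    pi_inf: float = 0.0
    inflation: str = "none"

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n > 0):
            raise ValueError(f"n must be a positive integer, got {self.n}")
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must lie in (0, 1), got {self.p}")
        if self.nu < 0:
            raise ValueError(f"nu must be non-negative, got {self.nu}")
        if not 0.0 <= self.pi_inf <= 1.0:
            raise ValueError(f"pi_inf must lie in [0, 1], got {self.pi_inf}")
        if self.inflation not in ("none", "zero", "N"):
            raise ValueError(f"unknown inflation point {self.inflation!r}")


@dataclass(frozen=True)
class CMMultinomialParams:
    """Conway-Maxwell multinomial over m-part compositions of ``n``."""

    n: int
    q: tuple
    nu: float

    def __post_init__(self) -> None:
        q = tuple(float(v) for v in self.q)
        object.__setattr__(self, "q", q)
        if not (isinstance(self.n, (int, np.integer)) and self.n > 0):
            raise ValueError(f"n must be a positive integer, got {self.n}")
        if len(q) < 2 or any(v <= 0 for v in q):
            raise ValueError("q must have >= 2 strictly positive entries")
        if abs(sum(q) - 1.0) > 1e-8:
            raise ValueError(f"q must sum to 1, got {sum(q)}")
        if self.nu < 0:
            raise ValueError(f"nu must be non-negative, got {self.nu}")


@dataclass(frozen=True)
class LognormalParams:
    """Lognormal with log-scale location ``mu`` and spread ``sigma``."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


Params = CMPoissonParams | CMBinomialParams | CMMultinomialParams | LognormalParams


# ---------------------------------------------------------------------------
# Log-PMFs
# ---------------------------------------------------------------------------


def _cm_poisson_log_terms(lam: float, nu: float, upper: int) -> np.ndarray:
    j = np.arange(upper + 1)
    return j * math.log(lam) - nu * gammaln(j + 1)


def _cm_poisson_log_z(lam: float, nu: float) -> tuple[float, int]:
    """Log normalizer of the CM-Poisson kernel and the truncation point used.

    The series sum_j lam^j / (j!)^nu is summed until the last term falls
    below ``_SERIES_RTOL`` times the partial sum, with a hard cap on the
    number of terms.  The mode of the terms sits near lam**(1/nu), so the
    initial truncation starts past it and doubles if the tail is not yet
    negligible.
    """
    if nu == 0:
        if lam >= 1:
            raise NormalizationError("nu=0 with lam>=1: divergent series")
        # geometric series, closed form
        return -math.log1p(-lam), 0
    log_rtol = math.log(_SERIES_RTOL)
    with np.errstate(over="ignore"):
        mode = min(lam ** (1.0 / nu), float(_SERIES_MAX_TERMS))
    j_hi = min(int(mode + 10 * math.sqrt((mode + 1) / nu) + 20), _SERIES_MAX_TERMS)
    while True:
        log_terms = _cm_poisson_log_terms(lam, nu, j_hi)
        log_sum = float(logsumexp(log_terms))
        if log_terms[-1] < log_sum + log_rtol:
            return log_sum, j_hi
        if j_hi >= _SERIES_MAX_TERMS:
            # the term cap bounds the truncation error; give up only when
            # the tail is still numerically material
            if log_terms[-1] > log_sum + math.log(1e-6):
                raise NormalizationError(
                    f"normalizer did not converge within {_SERIES_MAX_TERMS} terms "
                    f"(lam={lam:g}, nu={nu:g})"
                )
            return log_sum, j_hi
        j_hi = min(j_hi * 2, _SERIES_MAX_TERMS)


def cm_poisson_log_pmf(k, params: CMPoissonParams):
    """Log-PMF of the (optionally zero-inflated) CM-Poisson at ``k``."""
    k = np.asarray(k)
    if np.any(k < 0):
        raise ValueError("k must be non-negative")
    log_z, _ = _cm_poisson_log_z(params.lam, params.nu)
    base = k * math.log(params.lam) - params.nu * gammaln(k + 1) - log_z
    return _inflate_log_pmf(base, k == 0, params.pi0)


def _cm_binomial_base_log_pmf(k: np.ndarray, n: int, p: float, nu: float) -> np.ndarray:
    ks = np.arange(n + 1)
    log_kernel = (
        nu * (gammaln(n + 1) - gammaln(ks + 1) - gammaln(n - ks + 1))
        + ks * math.log(p)
        + (n - ks) * math.log1p(-p)
    )
    log_z = logsumexp(log_kernel)
    return log_kernel[k] - log_z


def cm_binomial_log_pmf(k, params: CMBinomialParams):
    """Log-PMF of the (optionally boundary-inflated) CM-binomial at ``k``."""
    k = np.asarray(k)
    if np.any((k < 0) | (k > params.n)):
        raise ValueError(f"k must lie in 0..{params.n}")
    base = _cm_binomial_base_log_pmf(k, params.n, params.p, params.nu)
    if params.inflation == "none" or params.pi_inf == 0.0:
        return base if base.shape else float(base)
    at = 0 if params.inflation == "zero" else params.n
    return _inflate_log_pmf(base, k == at, params.pi_inf)


def _inflate_log_pmf(base_log: np.ndarray, at_mask: np.ndarray, pi: float):
    """Mix a point mass (weight ``pi`` on ``at_mask``) into a base log-PMF."""
    base_log = np.asarray(base_log, dtype=float)
    if pi == 0.0:
        return base_log if base_log.shape else float(base_log)
    log_keep = math.log1p(-pi) if pi < 1.0 else -np.inf
    out = log_keep + base_log
    out = np.where(at_mask, np.logaddexp(math.log(pi), out), out)
    return out if out.shape else float(out)


def compositions(n: int, m: int) -> np.ndarray:
    """All m-part compositions of n, shape (C(n+m-1, m-1), m)."""
    out = []
    for cuts in itertools.combinations(range(n + m - 1), m - 1):
        prev = -1
        parts = []
        for c in cuts:
            parts.append(c - prev - 1)
            prev = c
        parts.append(n + m - 2 - prev)
        out.append(parts)
    return np.array(out, dtype=int)


def _cm_multinomial_log_table(params: CMMultinomialParams) -> tuple[np.ndarray, np.ndarray]:
    """(compositions, log-PMF) over the full support, exact enumeration."""
    comps = compositions(params.n, len(params.q))
    log_q = np.log(np.asarray(params.q))
    log_coef = gammaln(params.n + 1) - gammaln(comps + 1).sum(axis=1)
    log_kernel = params.nu * log_coef + comps @ log_q
    return comps, log_kernel - logsumexp(log_kernel)


def cm_multinomial_log_pmf(x, params: CMMultinomialParams):
    """Log-PMF of the CM-multinomial at composition(s) ``x``."""
    x = np.asarray(x, dtype=int)
    single = x.ndim == 1
    x2 = x[None, :] if single else x
    if x2.shape[1] != len(params.q):
        raise ValueError("composition length does not match q")
    if np.any(x2 < 0) or np.any(x2.sum(axis=1) != params.n):
        raise ValueError(f"compositions must be non-negative and sum to {params.n}")
    comps, log_pmf = _cm_multinomial_log_table(params)
    # index compositions by mixed radix key
    key = _comp_key(comps, params.n)
    lookup = np.full(key.max() + 1, -np.inf)
    lookup[key] = log_pmf
    vals = lookup[_comp_key(x2, params.n)]
    return float(vals[0]) if single else vals


def _comp_key(comps: np.ndarray, n: int) -> np.ndarray:
    base = n + 1
    key = np.zeros(len(comps), dtype=int)
    for j in range(comps.shape[1] - 1):  # last part is determined
        key = key * base + comps[:, j]
    return key


def lognormal_log_pdf(x, params: LognormalParams):
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("lognormal support is positive reals")
    lx = np.log(x)
    out = (
        -lx
        - math.log(params.sigma)
        - 0.5 * math.log(2 * math.pi)
        - 0.5 * ((lx - params.mu) / params.sigma) ** 2
    )
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# Support tables, CDF, moments, sampling
# ---------------------------------------------------------------------------


def support_upper(params: Params, tail: float = 1e-12) -> int:
    """Upper truncation point capturing all but ``tail`` of the mass
    (exact upper end for finite supports)."""
    if isinstance(params, CMBinomialParams):
        return params.n
    if isinstance(params, CMMultinomialParams):
        return params.n
    if isinstance(params, CMPoissonParams):
        # walk the cumulative series
        log_z, trunc = _cm_poisson_log_z(params.lam, params.nu)
        upper = max(trunc, 10)
        terms = _cm_poisson_log_terms(params.lam, params.nu, upper) - log_z
        probs = np.exp(terms)
        cum = np.cumsum(probs)
        idx = np.searchsorted(cum, 1.0 - tail)
        return int(min(idx + 1, upper))
    raise TypeError(f"no discrete support for {type(params).__name__}")


def pmf_table(params: Params, upper: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(support values, probabilities) for a discrete family.

    For the CM-multinomial the support values are the compositions
    (2-D array); for the others a 1-D integer range starting at 0.  The
    CM-Poisson table is truncated so the omitted tail is below 1e-12.
    """
    if isinstance(params, CMMultinomialParams):
        comps, log_pmf = _cm_multinomial_log_table(params)
        return comps, np.exp(log_pmf)
    if upper is None:
        upper = support_upper(params)
    ks = np.arange(upper + 1)
    if isinstance(params, CMPoissonParams):
        probs = np.exp(cm_poisson_log_pmf(ks, params))
    elif isinstance(params, CMBinomialParams):
        probs = np.exp(cm_binomial_log_pmf(ks, params))
    else:
        raise TypeError(f"no PMF table for {type(params).__name__}")
    return ks, probs


def discrete_cdf(k, params: Params):
    """F(k) = sum_{j<=k} pmf(j); F(-1) = 0.  For the CM-multinomial the
    argument is interpreted as the count of the first category."""
    if isinstance(params, CMMultinomialParams):
        comps, probs = pmf_table(params)
        marg = np.bincount(comps[:, 0], weights=probs, minlength=params.n + 1)
        cum = np.concatenate([[0.0], np.cumsum(marg)])
    else:
        _, probs = pmf_table(params)
        cum = np.concatenate([[0.0], np.cumsum(probs)])
    k = np.asarray(k, dtype=int)
    idx = np.clip(k + 1, 0, len(cum) - 1)
    out = np.where(k < 0, 0.0, cum[idx])
    out = np.where(k + 1 >= len(cum), 1.0, out)
    return float(out) if out.shape == () else out


def moments(params: Params) -> tuple[np.ndarray, np.ndarray]:
    """Exact (mean, SD) from the PMF table.

    For the CM-multinomial returns per-category mean and SD vectors.
    """
    if isinstance(params, LognormalParams):
        m = math.exp(params.mu + params.sigma**2 / 2)
        v = (math.exp(params.sigma**2) - 1) * m**2
        return np.float64(m), np.float64(math.sqrt(v))
    vals, probs = pmf_table(params)
    if vals.ndim == 2:
        mean = probs @ vals
        var = probs @ (vals.astype(float) ** 2) - mean**2
        return mean, np.sqrt(np.maximum(var, 0.0))
    mean = float(probs @ vals)
    var = float(probs @ (vals.astype(float) ** 2) - mean**2)
    return np.float64(mean), np.float64(math.sqrt(max(var, 0.0)))


def sample(params: Params, count: int, seed=None) -> np.ndarray:
    """Exact i.i.d. draws via full-support table sampling (inverse CDF).

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(params, LognormalParams):
        return np.exp(rng.normal(params.mu, params.sigma, size=count))
    vals, probs = pmf_table(params)
    probs = probs / probs.sum()  # absorb truncation tail
    idx = rng.choice(len(probs), size=count, p=probs)
    return vals[idx]


# ---------------------------------------------------------------------------
# Weighted maximum-likelihood fitting
# ---------------------------------------------------------------------------


def _logit(p: float) -> float:
    p = min(max(p, PROB_FLOOR), 1 - PROB_FLOOR)
    return math.log(p / (1 - p))


def _expit(x: float) -> float:
    x = min(max(x, -50.0), 50.0)
    p = 1.0 / (1.0 + math.exp(-x))
    return min(max(p, PROB_FLOOR), 1 - PROB_FLOOR)


def _clip_nu(nu: float) -> float:
    return min(max(nu, NU_MIN), NU_MAX)


def _aggregate(values: np.ndarray, weights: np.ndarray):
    """Collapse (values, weights) onto unique support points; the weighted
    log-likelihood only depends on these sums, which makes the optimizer's
    cost independent of the number of records."""
    if values.ndim == 1:
        uniq, inv = np.unique(values, return_inverse=True)
    else:
        uniq, inv = np.unique(values, axis=0, return_inverse=True)
    w = np.bincount(inv, weights=weights, minlength=len(uniq))
    keep = w > 0
    return uniq[keep], w[keep]


def fit_weighted(
    values,
    weights,
    family: str,
    *,
    n: int | None = None,
    inflation: str = "none",
    fixed: dict | None = None,
    starts: int = 3,
    seed: int = 0,
    init: Params | None = None,
) -> Params:
    """Maximize the weighted log-likelihood ``sum_i w_i log pmf(x_i)``.

    Parameters are optimized on unconstrained scales (log lam, logit p,
    log nu, logit pi) with L-BFGS-B and ``starts`` seeded multi-starts to
    dodge local optima; ``init``, when given, is used as an extra start
    (the mixture M-step warm-starts from the current parameters this way).
    ``fixed`` pins named fields (e.g. ``{"nu": 1.0, "pi": 0.0}``).

    Families: ``"cm_poisson"``, ``"cm_binomial"`` (requires ``n``),
    ``"cm_multinomial"`` (requires ``n``), ``"lognormal"`` (closed form).
    """
    fixed = dict(fixed or {})
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(weights > 0):
        raise ValueError("at least one weight must be positive")

    if family == "lognormal":
        x = np.asarray(values, dtype=float)
        lx = np.log(x)
        wsum = weights.sum()
        mu = fixed.get("mu", float(weights @ lx / wsum))
        var = float(weights @ (lx - mu) ** 2 / wsum)
        sigma = fixed.get("sigma", math.sqrt(max(var, 1e-12)))
        return LognormalParams(mu=mu, sigma=max(sigma, 1e-6))

    values = np.asarray(values)
    vals, w = _aggregate(values, weights)
    rng = np.random.default_rng(seed)

    if family == "cm_poisson":
        return _fit_cm_poisson(vals, w, fixed, starts, rng, init)
    if family == "cm_binomial":
        if n is None:
            raise ValueError("cm_binomial requires n")
        return _fit_cm_binomial(vals, w, int(n), inflation, fixed, starts, rng, init)
    if family == "cm_multinomial":
        if n is None:
            raise ValueError("cm_multinomial requires n")
        return _fit_cm_multinomial(vals, w, int(n), fixed, starts, rng, init)
    raise ValueError(f"unknown family {family!r}")


def _optimize(objective, x0_list):
    best = None
    for x0 in x0_list:
        res = minimize(objective, x0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    return best.x


def _fit_cm_poisson(vals, w, fixed, starts, rng, init):
    mean = max(float(w @ vals / w.sum()), 0.05)
    pi_fixed = fixed.get("pi", fixed.get("pi0"))
    nu_fixed = fixed.get("nu")
    zero_share = float(w[vals == 0].sum() / w.sum())
    if pi_fixed is None and zero_share >= 1.0 - 1e-12:
        # degenerate mass at zero: cap at the boundary
        return CMPoissonParams(lam=max(mean, 0.05), nu=1.0, pi0=1.0 - PROB_FLOOR)

    free = []  # order: log lam, log nu?, logit pi?
    if nu_fixed is None:
        free.append("nu")
    if pi_fixed is None:
        free.append("pi")

    def unpack(theta):
        lam = math.exp(min(theta[0], 8.0))
        i = 1
        nu = nu_fixed
        if nu is None:
            nu = _clip_nu(math.exp(theta[i]))
            i += 1
        pi = pi_fixed
        if pi is None:
            pi = _expit(theta[i])
        return max(lam, 1e-6), nu, min(max(pi, 0.0), 1.0 - PROB_FLOOR)

    def objective(theta):
        lam, nu, pi = unpack(theta)
        try:
            lp = cm_poisson_log_pmf(vals, CMPoissonParams(lam=lam, nu=nu, pi0=pi))
        except (ValueError, OverflowError):
            return 1e12
        return -float(w @ lp)

    nu0 = nu_fixed if nu_fixed is not None else 1.0
    lam0 = mean**nu0 if nu0 else mean
    base = [math.log(max(lam0, 0.05))]
    if nu_fixed is None:
        base.append(0.0)
    if pi_fixed is None:
        base.append(_logit(max(zero_share / 2, 0.01)))
    x0s = [np.array(base)]
    if init is not None and isinstance(init, CMPoissonParams):
        warm = [math.log(init.lam)]
        if nu_fixed is None:
            warm.append(math.log(_clip_nu(init.nu if init.nu > 0 else 1.0)))
        if pi_fixed is None:
            warm.append(_logit(init.pi0))
        x0s.append(np.array(warm))
    for _ in range(max(starts - 1, 0)):
        x0s.append(x0s[0] + rng.normal(0, 0.5, size=len(base)))
    lam, nu, pi = unpack(_optimize(objective, x0s))
    return CMPoissonParams(lam=lam, nu=nu, pi0=pi)


def _fit_cm_binomial(vals, w, n, inflation, fixed, starts, rng, init):
    mean = float(w @ vals / w.sum())
    p0 = min(max(mean / n, PROB_FLOOR), 1 - PROB_FLOOR)
    pi_fixed = fixed.get("pi", fixed.get("pi_inf"))
    nu_fixed = fixed.get("nu")
    if inflation == "none":
        pi_fixed = 0.0
    at = 0 if inflation == "zero" else n
    boundary_share = float(w[vals == at].sum() / w.sum()) if inflation != "none" else 0.0
    if inflation != "none" and pi_fixed is None and boundary_share >= 1.0 - 1e-12:
        return CMBinomialParams(
            n=n, p=p0, nu=1.0, pi_inf=1.0 - PROB_FLOOR, inflation=inflation
        )

    def unpack(theta):
        p = _expit(theta[0])
        i = 1
        nu = nu_fixed
        if nu is None:
            nu = _clip_nu(math.exp(theta[i]))
            i += 1
        pi = pi_fixed
        if pi is None:
            pi = min(_expit(theta[i]), 1 - PROB_FLOOR)
        return p, nu, pi

    def objective(theta):
        p, nu, pi = unpack(theta)
        params = CMBinomialParams(n=n, p=p, nu=nu, pi_inf=pi, inflation=inflation)
        lp = cm_binomial_log_pmf(vals, params)
        return -float(w @ lp)

    base = [_logit(p0)]
    if nu_fixed is None:
        base.append(0.0)
    if pi_fixed is None:
        base.append(_logit(max(boundary_share / 2, 0.01)))
    x0s = [np.array(base)]
    if init is not None and isinstance(init, CMBinomialParams):
        warm = [_logit(init.p)]
        if nu_fixed is None:
            warm.append(math.log(_clip_nu(init.nu if init.nu > 0 else 1.0)))
        if pi_fixed is None:
            warm.append(_logit(init.pi_inf))
        x0s.append(np.array(warm))
    for _ in range(max(starts - 1, 0)):
        x0s.append(x0s[0] + rng.normal(0, 0.5, size=len(base)))
    p, nu, pi = unpack(_optimize(objective, x0s))
    return CMBinomialParams(n=n, p=p, nu=nu, pi_inf=pi, inflation=inflation)


def _fit_cm_multinomial(vals, w, n, fixed, starts, rng, init):
    m = vals.shape[1]
    nu_fixed = fixed.get("nu")
    mean = w @ vals / w.sum()
    q0 = np.clip(mean / n, PROB_FLOOR, None)
    q0 = q0 / q0.sum()

    def unpack(theta):
        # additive log-ratio transform relative to the last category
        lq = np.concatenate([theta[: m - 1], [0.0]])
        q = np.exp(lq - logsumexp(lq))
        q = np.clip(q, PROB_FLOOR, None)
        q = q / q.sum()
        nu = nu_fixed if nu_fixed is not None else _clip_nu(math.exp(theta[m - 1]))
        return q, nu

    def objective(theta):
        q, nu = unpack(theta)
        params = CMMultinomialParams(n=n, q=tuple(q), nu=nu)
        lp = cm_multinomial_log_pmf(vals, params)
        return -float(w @ lp)

    base = list(np.log(q0[:-1] / q0[-1]))
    if nu_fixed is None:
        base.append(0.0)
    x0s = [np.array(base)]
    if init is not None and isinstance(init, CMMultinomialParams):
        qi = np.clip(np.asarray(init.q), PROB_FLOOR, None)
        warm = list(np.log(qi[:-1] / qi[-1]))
        if nu_fixed is None:
            warm.append(math.log(_clip_nu(init.nu if init.nu > 0 else 1.0)))
        x0s.append(np.array(warm))
    for _ in range(max(starts - 1, 0)):
        x0s.append(x0s[0] + rng.normal(0, 0.5, size=len(base)))
    q, nu = unpack(_optimize(objective, x0s))
    return CMMultinomialParams(n=n, q=tuple(q), nu=nu)


# ---------------------------------------------------------------------------
# JSON round-trip
# ---------------------------------------------------------------------------

_FAMILY_NAMES = {
    CMPoissonParams: "cm_poisson",
    CMBinomialParams: "cm_binomial",
    CMMultinomialParams: "cm_multinomial",
    LognormalParams: "lognormal",
}


def params_to_json(params: Params) -> dict:
    """JSON-ready dict with the family name and fields spelled out."""
    d = {"family": _FAMILY_NAMES[type(params)]}
    if isinstance(params, CMPoissonParams):
        d.update(lam=params.lam, nu=params.nu, pi0=params.pi0)
    elif isinstance(params, CMBinomialParams):
        d.update(
            n=int(params.n), p=params.p, nu=params.nu,
            pi_inf=params.pi_inf, inflation=params.inflation,
        )
    elif isinstance(params, CMMultinomialParams):
        d.update(n=int(params.n), q=list(params.q), nu=params.nu)
    else:
        d.update(mu=params.mu, sigma=params.sigma)
    return d


def params_from_json(d: dict) -> Params:
    """Rebuild a parameter bundle; invariants are re-validated on construction."""
    d = dict(d)
    family = d.pop("family")
    if family == "cm_poisson":
        return CMPoissonParams(**d)
    if family == "cm_binomial":
        return CMBinomialParams(**d)
    if family == "cm_multinomial":
        d["q"] = tuple(d["q"])
        return CMMultinomialParams(**d)
    if family == "lognormal":
        return LognormalParams(**d)
    raise ValueError(f"unknown family {family!r}")
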