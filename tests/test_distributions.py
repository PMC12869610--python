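"""Distribution kernels: oracles, invariants, sampling, and weighted fits."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cogmix import distributions as d

# ---------------------------------------------------------------------------
# log-PMF oracles
# ---------------------------------------------------------------------------


def brute_cm_poisson_log_pmf(k, lam, nu, pi0, terms=2000):
    """Independent oracle: direct series summation in log space."""
    lt = [j * math.log(lam) - nu * math.lgamma(j + 1) for j in range(terms)]
    m = max(lt)
    log_z = m + math.log(sum(math.exp(t - m) for t in lt))
    base = k * math.log(lam) - nu * math.lgamma(k + 1) - log_z
    p = (1 - pi0) * math.exp(base) + (pi0 if k == 0 else 0.0)
    return math.log(p)


def test_cm_poisson_reduces_to_poisson():
    p = d.CMPoissonParams(lam=2.0, nu=1.0)
    assert d.cm_poisson_log_pmf(0, p) == pytest.approx(-2.0, abs=1e-12)
    ks = np.arange(30)
    np.testing.assert_allclose(
        d.cm_poisson_log_pmf(ks, p), stats.poisson.logpmf(ks, 2.0), atol=1e-12
    )


def test_cm_poisson_pure_point_mass():
    p = d.CMPoissonParams(lam=3.0, nu=0.5, pi0=1.0)
    assert d.cm_poisson_log_pmf(0, p) == pytest.approx(0.0)


def test_cm_poisson_matches_series_oracle():
    p = d.CMPoissonParams(lam=5.0, nu=1.7, pi0=0.1)
    assert d.cm_poisson_log_pmf(3, p) == pytest.approx(
        brute_cm_poisson_log_pmf(3, 5.0, 1.7, 0.1), abs=1e-12
    )


def test_cm_poisson_divergent_normalizer_rejected():
    with pytest.raises(d.NormalizationError):
        d.CMPoissonParams(lam=1.5, nu=0.0)


def test_cm_binomial_reduces_to_binomial():
    p = d.CMBinomialParams(n=2, p=0.5, nu=1.0)
    assert d.cm_binomial_log_pmf(1, p) == pytest.approx(math.log(0.5), abs=1e-12)
    p = d.CMBinomialParams(n=15, p=0.37, nu=1.0)
    ks = np.arange(16)
    np.testing.assert_allclose(
        d.cm_binomial_log_pmf(ks, p), stats.binom.logpmf(ks, 15, 0.37), atol=1e-12
    )


def test_cm_binomial_nu_zero_is_geometric_kernel():
    p = d.CMBinomialParams(n=3, p=0.5, nu=0.0)
    np.testing.assert_allclose(
        np.exp(d.cm_binomial_log_pmf(np.arange(4), p)), 0.25, atol=1e-12
    )


def test_zero_inflated_binomial_hand_value():
    p = d.CMBinomialParams(n=6, p=0.3, nu=1.0, pi_inf=0.5, inflation="zero")
    assert math.exp(d.cm_binomial_log_pmf(0, p)) == pytest.approx(
        0.5 + 0.5 * 0.7**6, abs=1e-12
    )


def test_cm_binomial_out_of_support_errors():
    p = d.CMBinomialParams(n=6, p=0.3, nu=1.0)
    with pytest.raises(ValueError):
        d.cm_binomial_log_pmf(7, p)


def test_cm_multinomial_reduces_to_multinomial():
    p = d.CMMultinomialParams(n=2, q=(1 / 3, 1 / 3, 1 / 3), nu=1.0)
    assert math.exp(d.cm_multinomial_log_pmf([1, 1, 0], p)) == pytest.approx(2 / 9)
    q = (0.5, 0.3, 0.2)
    p = d.CMMultinomialParams(n=6, q=q, nu=1.0)
    comps = d.compositions(6, 3)
    np.testing.assert_allclose(
        d.cm_multinomial_log_pmf(comps, p),
        stats.multinomial.logpmf(comps, 6, q),
        atol=1e-12,
    )


def test_cm_multinomial_nu_zero_uniform_kernel_weighted_by_q():
    p = d.CMMultinomialParams(n=6, q=(1 / 3, 1 / 3, 1 / 3), nu=0.0)
    comps = d.compositions(6, 3)
    assert len(comps) == 28
    np.testing.assert_allclose(
        np.exp(d.cm_multinomial_log_pmf(comps, p)), 1 / 28, atol=1e-12
    )


def test_cm_multinomial_enumeration_oracle():
    q = (0.8, 0.15, 0.05)
    nu = 1.4
    comps = d.compositions(6, 3)

    def coef(c):
        return math.factorial(6) // (
            math.factorial(c[0]) * math.factorial(c[1]) * math.factorial(c[2])
        )

    kern = [coef(c) ** nu * q[0] ** c[0] * q[1] ** c[1] * q[2] ** c[2] for c in comps]
    expect = math.log(coef([4, 1, 1]) ** nu * q[0] ** 4 * q[1] * q[2] / sum(kern))
    p = d.CMMultinomialParams(n=6, q=q, nu=nu)
    assert d.cm_multinomial_log_pmf([4, 1, 1], p) == pytest.approx(expect, abs=1e-12)


def test_cm_multinomial_wrong_total_errors():
    p = d.CMMultinomialParams(n=6, q=(0.5, 0.3, 0.2), nu=1.0)
    with pytest.raises(ValueError):
        d.cm_multinomial_log_pmf([3, 2, 2], p)


# ---------------------------------------------------------------------------
# normalization / reduction / inflation properties
# ---------------------------------------------------------------------------

# parameter ranges kept inside the convergent envelope of the series cap
pois_params = st.tuples(
    st.floats(0.2, 20.0), st.floats(0.4, 3.0), st.floats(0.0, 0.9)
)
binom_params = st.tuples(
    st.integers(2, 15), st.floats(0.05, 0.95), st.floats(0.0, 4.0),
    st.floats(0.0, 0.9), st.sampled_from(["none", "zero", "N"]),
)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(pois_params)
def test_cm_poisson_pmf_sums_to_one(prm):
    lam, nu, pi0 = prm
    _, probs = d.pmf_table(d.CMPoissonParams(lam=lam, nu=nu, pi0=pi0))
    assert abs(probs.sum() - 1.0) < 1e-10


@settings(max_examples=60, deadline=None, derandomize=True)
@given(binom_params)
def test_cm_binomial_pmf_sums_to_one(prm):
    n, p, nu, pi, infl = prm
    _, probs = d.pmf_table(
        d.CMBinomialParams(n=n, p=p, nu=nu, pi_inf=pi, inflation=infl)
    )
    assert abs(probs.sum() - 1.0) < 1e-10


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.integers(2, 6),
    st.lists(st.floats(0.05, 1.0), min_size=3, max_size=3),
    st.floats(0.0, 3.0),
)
def test_cm_multinomial_pmf_sums_to_one(n, qraw, nu):
    q = tuple(np.asarray(qraw) / np.sum(qraw))
    _, probs = d.pmf_table(d.CMMultinomialParams(n=n, q=q, nu=nu))
    assert abs(probs.sum() - 1.0) < 1e-10


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.floats(0.2, 15.0))
def test_nu_one_poisson_reduction(lam):
    ks = np.arange(0, 60)
    got = d.cm_poisson_log_pmf(ks, d.CMPoissonParams(lam=lam, nu=1.0))
    np.testing.assert_allclose(got, stats.poisson.logpmf(ks, lam), atol=1e-12)


def test_inflation_zero_weight_reproduces_base_family():
    base = d.CMBinomialParams(n=15, p=0.4, nu=0.7)
    infl = d.CMBinomialParams(n=15, p=0.4, nu=0.7, pi_inf=0.0, inflation="N")
    ks = np.arange(16)
    np.testing.assert_array_equal(
        d.cm_binomial_log_pmf(ks, base), d.cm_binomial_log_pmf(ks, infl)
    )
    p0 = d.CMPoissonParams(lam=4.0, nu=1.3, pi0=0.0)
    p1 = d.CMPoissonParams(lam=4.0, nu=1.3)
    np.testing.assert_array_equal(
        d.cm_poisson_log_pmf(np.arange(20), p0), d.cm_poisson_log_pmf(np.arange(20), p1)
    )


def test_inflation_one_is_point_mass():
    p = d.CMBinomialParams(n=15, p=0.4, nu=0.7, pi_inf=1.0, inflation="N")
    probs = np.exp(d.cm_binomial_log_pmf(np.arange(16), p))
    assert probs[15] == pytest.approx(1.0)
    assert probs[:15].sum() == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# CDF and sampling
# ---------------------------------------------------------------------------


def test_discrete_cdf_boundaries_and_poisson_value():
    p = d.CMPoissonParams(lam=2.0, nu=1.0)
    assert d.discrete_cdf(-1, p) == 0.0
    assert d.discrete_cdf(2, p) == pytest.approx(5 * math.exp(-2), abs=1e-12)
    b = d.CMBinomialParams(n=6, p=0.3, nu=0.8, pi_inf=0.2, inflation="zero")
    assert d.discrete_cdf(6, b) == pytest.approx(1.0, abs=1e-10)
    assert d.discrete_cdf(-1, b) == 0.0


def test_sample_empty_and_degenerate():
    p = d.CMPoissonParams(lam=2.0, nu=1.0, pi0=1.0)
    assert len(d.sample(p, 0, seed=0)) == 0
    assert np.all(d.sample(p, 50, seed=0) == 0)


def test_sample_reproducible_and_mean():
    p = d.CMBinomialParams(n=15, p=0.7, nu=1.0)
    x1 = d.sample(p, 100_000, seed=3)
    x2 = d.sample(p, 100_000, seed=3)
    np.testing.assert_array_equal(x1, x2)
    se = math.sqrt(15 * 0.7 * 0.3 / 100_000)
    assert abs(x1.mean() - 10.5) < 3 * se


@pytest.mark.parametrize(
    "params",
    [
        d.CMPoissonParams(lam=6.0, nu=1.4, pi0=0.15),
        d.CMBinomialParams(n=15, p=0.55, nu=0.5, pi_inf=0.1, inflation="N"),
        d.CMBinomialParams(n=6, p=0.3, nu=1.6, pi_inf=0.2, inflation="zero"),
    ],
)
def test_sampling_matches_pmf_chisquare(params):
    """Chi-square goodness of fit of 1e5 draws against the exact PMF."""
    x = d.sample(params, 100_000, seed=9)
    vals, probs = d.pmf_table(params)
    obs = np.bincount(x, minlength=len(vals)).astype(float)[: len(vals)]
    keep = probs * len(x) >= 5
    obs_k, exp_k = obs[keep], probs[keep] * len(x)
    if np.any(~keep):  # pool the sparse tail into one bin
        obs_k = np.append(obs_k, obs[~keep].sum())
        exp_k = np.append(exp_k, probs[~keep].sum() * len(x))
    stat, p = stats.chisquare(obs_k, exp_k * obs_k.sum() / exp_k.sum())
    assert p > 0.001


def test_multinomial_sampling_triples_sum_to_n():
    p = d.CMMultinomialParams(n=6, q=(0.6, 0.3, 0.1), nu=0.8)
    x = d.sample(p, 1000, seed=4)
    assert x.shape == (1000, 3)
    assert np.all(x.sum(axis=1) == 6)


# ---------------------------------------------------------------------------
# weighted fitting
# ---------------------------------------------------------------------------


def test_fit_weighted_binomial_closed_form():
    fit = d.fit_weighted([1, 2], [1.0, 1.0], "cm_binomial", n=2,
                         fixed={"nu": 1.0, "pi": 0.0})
    assert fit.p == pytest.approx(0.75, abs=1e-4)


def test_fit_weighted_all_zeros_hits_inflation_cap():
    fit = d.fit_weighted(
        np.zeros(40, dtype=int), np.ones(40), "cm_binomial", n=6, inflation="zero"
    )
    assert fit.pi_inf >= 1.0 - 1e-5


def test_fit_weighted_rejects_bad_weights():
    with pytest.raises(ValueError):
        d.fit_weighted([1, 2], [0.0, 0.0], "cm_poisson")
    with pytest.raises(ValueError):
        d.fit_weighted([1, 2], [1.0, -1.0], "cm_poisson")


def test_fit_weighted_recovers_cm_poisson():
    true = d.CMPoissonParams(lam=8.0, nu=1.5, pi0=0.1)
    x = d.sample(true, 5000, seed=1)
    fit = d.fit_weighted(x, np.ones(len(x)), "cm_poisson", seed=0)
    assert fit.lam == pytest.approx(true.lam, rel=0.10)
    assert fit.nu == pytest.approx(true.nu, rel=0.10)
    assert fit.pi0 == pytest.approx(true.pi0, abs=0.03)


def test_fit_weighted_beats_coarse_grid():
    """The optimizer's objective is at least the best value on a coarse
    oracle grid of parameter combinations."""
    true = d.CMBinomialParams(n=15, p=0.5, nu=0.6, pi_inf=0.08, inflation="N")
    x = d.sample(true, 800, seed=5)
    w = np.ones(len(x))
    fit = d.fit_weighted(x, w, "cm_binomial", n=15, inflation="N", seed=0)

    def obj(prm):
        return float(w @ d.cm_binomial_log_pmf(x, prm))

    best_grid = max(
        obj(d.CMBinomialParams(n=15, p=p, nu=nu, pi_inf=pi, inflation="N"))
        for p in np.linspace(0.2, 0.8, 7)
        for nu in [0.3, 0.6, 1.0, 1.5]
        for pi in [0.0, 0.05, 0.1, 0.2]
    )
    assert obj(fit) >= best_grid - 1e-6


def test_fit_weighted_objective_not_below_truth():
    true = d.CMBinomialParams(n=6, p=0.35, nu=1.2, pi_inf=0.15, inflation="zero")
    x = d.sample(true, 2000, seed=6)
    w = np.ones(len(x))
    fit = d.fit_weighted(x, w, "cm_binomial", n=6, inflation="zero", seed=0)
    ll_fit = float(w @ d.cm_binomial_log_pmf(x, fit))
    ll_true = float(w @ d.cm_binomial_log_pmf(x, true))
    assert ll_fit >= ll_true - 1e-6


def test_fit_weighted_lognormal_closed_form():
    x = np.array([1.0, 2.0, 4.0])
    w = np.array([1.0, 2.0, 1.0])
    fit = d.fit_weighted(x, w, "lognormal")
    lx = np.log(x)
    mu = w @ lx / w.sum()
    assert fit.mu == pytest.approx(mu, abs=1e-12)
    assert fit.sigma == pytest.approx(math.sqrt(w @ (lx - mu) ** 2 / w.sum()), abs=1e-12)


def test_fit_weighted_multinomial_recovers_q():
    true = d.CMMultinomialParams(n=6, q=(0.7, 0.2, 0.1), nu=1.0)
    x = d.sample(true, 4000, seed=7)
    fit = d.fit_weighted(x, np.ones(len(x)), "cm_multinomial", n=6, seed=0)
    np.testing.assert_allclose(fit.q, true.q, atol=0.05)


# ---------------------------------------------------------------------------
# validation + JSON round-trip
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "ctor",
    [
        lambda: d.CMPoissonParams(lam=-1.0, nu=1.0),
        lambda: d.CMPoissonParams(lam=1.0, nu=-0.1),
        lambda: d.CMPoissonParams(lam=1.0, nu=1.0, pi0=1.5),
        lambda: d.CMBinomialParams(n=0, p=0.5, nu=1.0),
        lambda: d.CMBinomialParams(n=5, p=1.0, nu=1.0),
        lambda: d.CMBinomialParams(n=5, p=0.5, nu=1.0, inflation="max"),
        lambda: d.CMMultinomialParams(n=6, q=(0.5, 0.6), nu=1.0),
        lambda: d.LognormalParams(mu=0.0, sigma=0.0),
    ],
)
def test_invalid_parameters_rejected(ctor):
    with pytest.raises(ValueError):
        ctor()


@pytest.mark.parametrize(
    "params",
    [
        d.CMPoissonParams(lam=7.8, nu=0.69, pi0=0.005),
        d.CMBinomialParams(n=15, p=0.57, nu=0.22, pi_inf=0.1, inflation="N"),
        d.CMMultinomialParams(n=6, q=(0.5, 0.3, 0.2), nu=1.4),
        d.LognormalParams(mu=4.2, sigma=0.13),
    ],
)
def test_json_round_trip(params):
    blob = json.dumps(d.params_to_json(params))
    assert d.params_from_json(json.loads(blob)) == params


def test_json_revalidates_invariants():
    blob = d.params_to_json(d.CMPoissonParams(lam=2.0, nu=1.0))
    blob["lam"] = -3.0
    with pytest.raises(ValueError):
        d.params_from_json(blob)
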