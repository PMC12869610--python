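"""Soft-membership nonparametric between-cluster tests.

Generalizations of the Kruskal-Wallis omnibus test and Dunn's pairwise test
in which hard group indicators are replaced by posterior membership
probabilities: effective group sizes are responsibility column sums and
group mean ranks are responsibility-weighted.  With one-hot memberships
both statistics reduce exactly to their classical tie-corrected forms.

Null distributions come from Monte-Carlo permutation of the covariate
values against the fixed membership rows (this preserves the
membership-uncertainty structure under the null), and pairwise tests are
corrected for multiplicity by the permutation-based step-down max-T method,
sharing the same permutation stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "GroupTestResult",
    "generalized_kw",
    "generalized_dunn",
    "mc_pvalue",
    "maxT_stepdown",
    "soft_rank_tests",
    "results_to_frame",
]

_PERM_BLOCK = 512  # permutations per vectorized block


@dataclass(frozen=True)
class GroupTestResult:
    """Omnibus and pairwise soft-membership rank-test results.

    ``pairs`` lists (a, b) cluster-index pairs matching the rows of
    ``z_pairs`` / ``p_raw`` / ``p_adj``; ``z_matrix`` is the full
    antisymmetric matrix.
    """

    variable: str
    n_records: int
    h: float
    p_mc: float
    group_sizes: np.ndarray
    mean_ranks: np.ndarray
    pairs: tuple
    z_pairs: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    b: int
    seed: int
    group_names: tuple | None = None

    @property
    def z_matrix(self) -> np.ndarray:
        K = len(self.group_sizes)
        Z = np.zeros((K, K))
        for (a, b), z in zip(self.pairs, self.z_pairs):
            Z[a, b] = z
            Z[b, a] = -z
        return Z


def _check(values: np.ndarray, gamma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if values.ndim != 1 or gamma.ndim != 2 or len(values) != len(gamma):
        raise ValueError("values must be 1-D with one membership row each")
    N, K = gamma.shape
    if N < K:
        raise ValueError(f"need at least as many records ({N}) as clusters ({K})")
    n_c = gamma.sum(axis=0)
    if np.any(n_c <= 0):
        raise ValueError(
            f"clusters {np.flatnonzero(n_c <= 0).tolist()} have zero effective size"
        )
    return values, gamma


def _tie_sum(ranks: np.ndarray) -> float:
    """sum_j (t_j^3 - t_j) over groups of tied values."""
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _kw_from_mean_ranks(rbar, n_c, N, tie_sum):
    h = 12.0 / (N * (N + 1)) * np.sum(n_c * (rbar - (N + 1) / 2.0) ** 2, axis=0)
    denom = 1.0 - tie_sum / (N**3 - N)
    if denom <= 0:  # all values identical
        return np.zeros_like(h) if np.ndim(h) else 0.0
    return h / denom


def generalized_kw(values, gamma) -> float:
    """Soft-membership Kruskal-Wallis H with mid-rank tie correction.

    H = [12 / (N(N+1))] * sum_c n_c (Rbar_c - (N+1)/2)^2, divided by
    1 - sum_j (t_j^3 - t_j) / (N^3 - N), with n_c = sum_i gamma_ic and
    Rbar_c the gamma-weighted mean mid-rank.
    """
    values, gamma = _check(values, gamma)
    ranks = rankdata(values)
    n_c = gamma.sum(axis=0)
    rbar = gamma.T @ ranks / n_c
    return float(_kw_from_mean_ranks(rbar, n_c, len(values), _tie_sum(ranks)))


def generalized_dunn(values, gamma) -> np.ndarray:
    """Soft-membership Dunn pairwise Z matrix (antisymmetric).

    Z_ab = (Rbar_a - Rbar_b) / sqrt([N(N+1)/12 - sum_j(t_j^3 - t_j) /
    (12(N-1))] * (1/n_a + 1/n_b)).
    """
    values, gamma = _check(values, gamma)
    N, K = gamma.shape
    ranks = rankdata(values)
    n_c = gamma.sum(axis=0)
    rbar = gamma.T @ ranks / n_c
    var_term = N * (N + 1) / 12.0 - _tie_sum(ranks) / (12.0 * (N - 1))
    inv = 1.0 / n_c
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var_term * (inv[:, None] + inv[None, :]))
        Z = (rbar[:, None] - rbar[None, :]) / se
    Z[~np.isfinite(Z)] = 0.0
    np.fill_diagonal(Z, 0.0)
    return Z


def _permuted_mean_ranks(ranks, gamma, n_c, B, seed):
    """Blocks of permuted gamma-weighted mean ranks (K x block)."""
    rng = np.random.default_rng(seed)
    done = 0
    while done < B:
        b = min(_PERM_BLOCK, B - done)
        idx = np.argsort(rng.random((b, len(ranks))), axis=1)  # b independent perms
        R = ranks[idx].T  # N x b
        yield gamma.T @ R / n_c[:, None]
        done += b


def mc_pvalue(values, gamma, statistic: str = "kw", B: int = 10_000, seed: int = 0) -> float:
    """Monte-Carlo permutation p-value for the omnibus statistic:
    p = (1 + #{H* >= H_obs}) / (B + 1)."""
    if B < 1:
        raise ValueError("B must be at least 1")
    if statistic != "kw":
        raise ValueError(f"unknown statistic {statistic!r}")
    values, gamma = _check(values, gamma)
    ranks = rankdata(values)
    n_c = gamma.sum(axis=0)
    N = len(values)
    ts = _tie_sum(ranks)
    h_obs = float(_kw_from_mean_ranks(gamma.T @ ranks / n_c, n_c, N, ts))
    exceed = 0
    for rbar_blk in _permuted_mean_ranks(ranks, gamma, n_c, B, seed):
        h_star = _kw_from_mean_ranks(rbar_blk, n_c[:, None], N, ts)
        exceed += int(np.sum(h_star >= h_obs - 1e-12))
    return (1 + exceed) / (B + 1)


def maxT_stepdown(z_obs: np.ndarray, z_draws: np.ndarray) -> np.ndarray:
    """Step-down max-T adjusted p-values from recorded permutation draws.

    Pairs are ordered by descending |z_obs|; the j-th adjusted p-value
    counts permutations whose maximum |Z*| over the not-yet-rejected pairs
    (positions j..end of the ordering) reaches |z_obs_j|, and the sequence
    is made monotone non-decreasing down the ordering.
    """
    z_obs = np.asarray(z_obs, dtype=float)
    z_draws = np.asarray(z_draws, dtype=float)
    P, B = z_draws.shape
    if len(z_obs) != P:
        raise ValueError("z_obs and z_draws disagree on the number of pairs")
    order = np.argsort(-np.abs(z_obs), kind="stable")
    abs_draws = np.abs(z_draws[order])  # P x B
    # reverse cumulative max: row j holds max over positions j..P-1
    succ_max = np.maximum.accumulate(abs_draws[::-1], axis=0)[::-1]
    counts = np.sum(succ_max >= np.abs(z_obs[order])[:, None] - 1e-12, axis=1)
    p_sorted = np.maximum.accumulate((1 + counts) / (B + 1))
    out = np.empty(P)
    out[order] = p_sorted
    return out


def soft_rank_tests(
    values,
    gamma,
    *,
    B: int = 10_000,
    seed: int = 0,
    variable: str = "",
    group_names: Sequence[str] | None = None,
) -> GroupTestResult:
    """Full omnibus + pairwise analysis for one covariate.

    Records with missing (NaN) values are dropped together with their
    membership rows (complete-case per variable).  A single permutation
    stream drives the omnibus Monte-Carlo p-value, the per-pair raw
    p-values, and the max-T step-down adjustment.
    """
    values = np.asarray(values, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    keep = ~np.isnan(values)
    values, gamma = _check(values[keep], gamma[keep])
    N, K = gamma.shape
    ranks = rankdata(values)
    n_c = gamma.sum(axis=0)
    ts = _tie_sum(ranks)
    rbar = gamma.T @ ranks / n_c
    h_obs = float(_kw_from_mean_ranks(rbar, n_c, N, ts))
    z_full = generalized_dunn(values, gamma)
    pairs = [(a, b) for a in range(K) for b in range(a + 1, K)]
    z_obs = np.array([z_full[a, b] for a, b in pairs])

    var_term = N * (N + 1) / 12.0 - ts / (12.0 * (N - 1))
    inv = 1.0 / n_c
    se = np.array([np.sqrt(var_term * (inv[a] + inv[b])) for a, b in pairs])

    h_exceed = 0
    z_blocks = []
    for rbar_blk in _permuted_mean_ranks(ranks, gamma, n_c, B, seed):
        h_star = _kw_from_mean_ranks(rbar_blk, n_c[:, None], N, ts)
        h_exceed += int(np.sum(h_star >= h_obs - 1e-12))
        diffs = np.array([rbar_blk[a] - rbar_blk[b] for a, b in pairs])
        z_blocks.append(diffs / se[:, None])
    z_draws = np.concatenate(z_blocks, axis=1)

    p_mc = (1 + h_exceed) / (B + 1)
    p_raw = (1 + np.sum(np.abs(z_draws) >= np.abs(z_obs)[:, None] - 1e-12, axis=1)) / (B + 1)
    p_adj = np.maximum(maxT_stepdown(z_obs, z_draws), p_raw)
    return GroupTestResult(
        variable=variable,
        n_records=N,
        h=h_obs,
        p_mc=p_mc,
        group_sizes=n_c,
        mean_ranks=rbar,
        pairs=tuple(pairs),
        z_pairs=z_obs,
        p_raw=p_raw,
        p_adj=p_adj,
        b=B,
        seed=seed,
        group_names=tuple(group_names) if group_names is not None else None,
    )


def results_to_frame(results: Sequence[GroupTestResult]) -> pd.DataFrame:
    """Tidy table: one row per pairwise comparison, omnibus columns repeated."""
    rows = []
    for r in results:
        names = r.group_names or tuple(str(i) for i in range(len(r.group_sizes)))
        for (a, b), z, praw, padj in zip(r.pairs, r.z_pairs, r.p_raw, r.p_adj):
            rows.append(
                {
                    "variable": r.variable,
                    "n": r.n_records,
                    "H": r.h,
                    "p_mc": r.p_mc,
                    "pair": f"{names[a]} vs {names[b]}",
                    "Z": z,
                    "p_pair_raw": praw,
                    "p_pair_adj": padj,
                    "B": r.b,
                    "seed": r.seed,
                }
            )
    return pd.DataFrame(rows)
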