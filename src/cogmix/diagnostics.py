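"""Model-selection and misspecification diagnostics.

Two tools guide the choice of distribution families and cluster counts:

* k-fold cross-validated log-likelihood — each fold is held out, the
  semi-supervised mixture is refit on the complement, and the constrained
  observed-data log-likelihood of the held-out records is accumulated.
  Overfitting shows up as a drop in held-out likelihood when model
  complexity grows.

* randomized quantile residuals — for a discrete response y with fitted
  CDF F, the residual is the standard-normal quantile of a uniform draw on
  (F(y-1), F(y)).  When the model is correct the residuals are standard
  normal; over-/under-dispersion and unmodeled boundary inflation produce
  visible departures.  Residuals here use the fitted marginal mixture CDF
  of each metric (mixture-weight-averaged over clusters), the standard
  construction for mixtures since it needs no cluster assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import distributions as dist
from .distributions import CMMultinomialParams, LognormalParams
from .mixture import (
    DAC_METRICS,
    DEFAULT_STRUCTURE,
    ClusterStructure,
    MixtureModel,
    build_constraints,
    fit_em,
    log_likelihood,
    records_to_arrays,
)

__all__ = [
    "CVResult",
    "ResidualSet",
    "cv_log_likelihood",
    "randomized_quantile_residuals",
    "marginal_cdf_table",
    "qq_summary",
]


@dataclass(frozen=True)
class CVResult:
    """Held-out log-likelihoods per fold; ``total`` is their sum."""

    fold_log_likelihoods: np.ndarray
    fold_assignment: np.ndarray
    seed: int
    impossible_folds: tuple = ()

    @property
    def total(self) -> float:
        return float(np.sum(self.fold_log_likelihoods))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": np.arange(len(self.fold_log_likelihoods)),
                "heldout_log_likelihood": self.fold_log_likelihoods,
                "n_records": np.bincount(
                    self.fold_assignment, minlength=len(self.fold_log_likelihoods)
                ),
                "seed": self.seed,
            }
        )


def cv_log_likelihood(
    records,
    labels: Sequence[str] | None = None,
    structure: ClusterStructure = DEFAULT_STRUCTURE,
    metrics: Mapping[str, dict] = DAC_METRICS,
    *,
    folds: int = 10,
    seed: int = 0,
    fit_kwargs: dict | None = None,
) -> CVResult:
    """k-fold cross-validated constrained log-likelihood.

    Records are shuffled once with ``seed`` and split into near-equal
    unstratified folds; labeled records keep their constraints in both the
    training fit and the held-out evaluation.  A fold containing a record
    that is impossible under its fitted model contributes ``-inf`` and is
    flagged rather than dropped.
    """
    data = records_to_arrays(records) if not isinstance(records, dict) else records
    n_key = next(iter(metrics))
    N = len(data[n_key])
    if N < folds:
        raise ValueError(f"need at least {folds} records for {folds}-fold CV")
    if labels is None:
        lab = data.get("label")
        labels = list(lab) if lab is not None else ["unlabeled"] * N
    labels = np.asarray(labels, dtype=object)
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("seed", seed)

    rng = np.random.default_rng(seed)
    order = rng.permutation(N)
    assignment = np.empty(N, dtype=int)
    for f, chunk in enumerate(np.array_split(order, folds)):
        assignment[chunk] = f

    fold_ll = np.empty(folds)
    impossible = []
    arrays = {k: np.asarray(v) for k, v in data.items()}
    for f in range(folds):
        held = assignment == f
        train = {k: v[~held] for k, v in arrays.items()}
        test = {k: v[held] for k, v in arrays.items()}
        fr = fit_em(train, list(labels[~held]), structure, metrics, **fit_kwargs)
        C_test = build_constraints(list(labels[held]), structure)
        ll = log_likelihood(fr.model, test, C_test)
        fold_ll[f] = ll
        if not np.isfinite(ll):
            impossible.append(f)
    return CVResult(
        fold_log_likelihoods=fold_ll,
        fold_assignment=assignment,
        seed=seed,
        impossible_folds=tuple(impossible),
    )


# ---------------------------------------------------------------------------
# Randomized quantile residuals
# ---------------------------------------------------------------------------


def marginal_cdf_table(model: MixtureModel, metric: str, upper: int) -> np.ndarray:
    """CDF of the fitted marginal mixture distribution of one metric on
    0..upper (the recognition triple is summarized by its correct count)."""
    pmf = np.zeros(upper + 1)
    for w, comp in zip(model.weights, model.components):
        params = comp[metric]
        if isinstance(params, CMMultinomialParams):
            comps_tab, probs = dist.pmf_table(params)
            marg = np.bincount(comps_tab[:, 0], weights=probs, minlength=upper + 1)
            pmf += w * marg[: upper + 1]
        else:
            ks, probs = dist.pmf_table(params, upper=upper)
            pmf += w * probs[: upper + 1]
    return np.cumsum(pmf)


@dataclass(frozen=True)
class ResidualSet:
    """Per-metric randomized quantile residual vectors (one per record)."""

    residuals: Mapping[str, np.ndarray]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(self.residuals))


def randomized_quantile_residuals(model: MixtureModel, records, seed: int = 0) -> ResidualSet:
    """Randomized quantile residuals under the fitted marginal mixtures.

    For each discrete metric, residual = Phi^-1(u) with u uniform on
    (F(y-1), F(y)); continuous metrics use u = F(y) directly.  An
    observation with (numerically) zero probability raises an error naming
    the record and metric.
    """
    data = records_to_arrays(records) if not isinstance(records, dict) else records
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for metric in model.metrics:
        params0 = model.components[0][metric]
        if isinstance(params0, LognormalParams):
            x = np.asarray(data[metric], dtype=float)
            u = np.zeros(len(x))
            for w, comp in zip(model.weights, model.components):
                p = comp[metric]
                u += w * norm.cdf((np.log(x) - p.mu) / p.sigma)
            out[metric] = norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
            continue
        vals = np.asarray(data[metric])
        y = vals[:, 0] if vals.ndim == 2 else vals  # recognition -> correct count
        upper = int(
            max(
                y.max(),
                max(dist.support_upper(c[metric]) for c in model.components),
            )
        )
        cdf = marginal_cdf_table(model, metric, upper)
        F_y = cdf[y]
        F_ym1 = np.where(y > 0, cdf[np.maximum(y - 1, 0)], 0.0)
        gap = F_y - F_ym1
        bad = gap <= 1e-300
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"record {i} has zero fitted probability for metric {metric!r} "
                f"(value {y[i]})"
            )
        u = F_ym1 + rng.random(len(y)) * gap
        out[metric] = norm.ppf(np.clip(u, 1e-15, 1 - 1e-15))
    return ResidualSet(residuals=out, seed=seed)


def qq_summary(residuals: ResidualSet, n_points: int = 99) -> pd.DataFrame:
    """Numeric quantile-quantile summary: empirical residual quantiles
    against standard-normal quantiles (a plotting hook without styling)."""
    probs = np.linspace(0.01, 0.99, n_points)
    rows = {"theoretical": norm.ppf(probs)}
    for metric, r in residuals.residuals.items():
        rows[metric] = np.quantile(r, probs)
    return pd.DataFrame(rows)
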