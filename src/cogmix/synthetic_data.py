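"""Synthetic assessment datasets with the structure the analysis assumes.

The default generator emulates the study conditions the pipeline targets: a
six-cluster population (one cognitively-unimpaired, three MCI, and two
probable-dementia clusters), count metrics that are over- or under-dispersed
with excess zeros (animal fluency, delayed recall) and excess maximum scores
(backward digit span), a recognition triple on a fixed total of 6, a mix of
unlabeled / diagnosis-labeled / cluster-labeled records, and covariates
shifted by impairment group.

Per-cluster distribution parameters are frozen moment matches: for each
cluster-metric pair the free parameters were chosen (once, by least squares
on the exact mean and SD implied by the PMF) to reproduce the published
cluster moments; boundary-inflation weights were fixed a priori (small, and
larger where impairment makes refusals/floor effects more common) because
two moments cannot identify a third parameter.  The generator discloses its
parameters so recovery tests can compare against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import distributions as dist
from .distributions import (
    CMBinomialParams,
    CMMultinomialParams,
    CMPoissonParams,
)
from .mixture import (
    DEFAULT_STRUCTURE,
    AssessmentRecord,
    ClusterStructure,
    MixtureModel,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "CovariateSpec",
    "DEFAULT_WEIGHTS",
    "DEFAULT_CLUSTER_PARAMS",
    "DEFAULT_COVARIATES",
    "default_true_model",
    "default_generator_config",
    "generate",
    "generate_null_covariate",
]


def _q(*vals):
    v = np.asarray(vals, dtype=float)
    return tuple(v / v.sum())


#: cluster mixture weights (population shares of the six clusters)
DEFAULT_WEIGHTS = {
    "CU": 0.2632, "dMCI": 0.2098, "mxMCI": 0.2110,
    "aMCI": 0.0275, "maDem": 0.1567, "saDem": 0.1318,
}

#: frozen moment-matched per-cluster distribution parameters
DEFAULT_CLUSTER_PARAMS = {
    "CU": dict(
        bdst=CMBinomialParams(n=15, p=0.566167, nu=0.222998, pi_inf=0.10, inflation="N"),
        animals=CMPoissonParams(lam=7.758834, nu=0.694909, pi0=0.005),
        recall=CMBinomialParams(n=6, p=0.608273, nu=0.447693, pi_inf=0.01, inflation="zero"),
        recognition=CMMultinomialParams(n=6, q=_q(0.897456, 0.075051, 0.027492), nu=0.001),
    ),
    "dMCI": dict(
        bdst=CMBinomialParams(n=15, p=0.519371, nu=0.601542, pi_inf=0.02, inflation="N"),
        animals=CMPoissonParams(lam=8.543466, nu=0.799712, pi0=0.01),
        recall=CMBinomialParams(n=6, p=0.614768, nu=1.106343, pi_inf=0.01, inflation="zero"),
        recognition=CMMultinomialParams(n=6, q=_q(0.999992, 0.000007, 0.000001), nu=5.810375),
    ),
    "mxMCI": dict(
        bdst=CMBinomialParams(n=15, p=0.517291, nu=0.324361, pi_inf=0.02, inflation="N"),
        animals=CMPoissonParams(lam=27.219243, nu=1.290348, pi0=0.01),
        recall=CMBinomialParams(n=6, p=0.297191, nu=0.867620, pi_inf=0.10, inflation="zero"),
        recognition=CMMultinomialParams(n=6, q=_q(0.813041, 0.113328, 0.073631), nu=0.894602),
    ),
    "aMCI": dict(
        bdst=CMBinomialParams(n=15, p=0.519612, nu=0.240480, pi_inf=0.03, inflation="N"),
        animals=CMPoissonParams(lam=14.370220, nu=0.899766, pi0=0.01),
        recall=CMBinomialParams(n=6, p=0.380013, nu=0.000100, pi_inf=0.45, inflation="zero"),
        recognition=CMMultinomialParams(n=6, q=_q(0.545630, 0.284507, 0.169863), nu=0.764352),
    ),
    "maDem": dict(
        bdst=CMBinomialParams(n=15, p=0.450363, nu=0.408147, pi_inf=0.01, inflation="N"),
        animals=CMPoissonParams(lam=1.916816, nu=0.294214, pi0=0.04),
        recall=CMBinomialParams(n=6, p=0.301350, nu=0.963538, pi_inf=0.10, inflation="zero"),
        recognition=CMMultinomialParams(n=6, q=_q(0.876666, 0.108987, 0.014347), nu=1.064198),
    ),
    "saDem": dict(
        bdst=CMBinomialParams(n=15, p=0.451797, nu=0.207663, pi_inf=0.01, inflation="N"),
        animals=CMPoissonParams(lam=2.182827, nu=0.372227, pi0=0.06),
        recall=CMBinomialParams(n=6, p=0.140024, nu=0.391807, pi_inf=0.20, inflation="zero"),
        recognition=CMMultinomialParams(n=6, q=_q(0.434979, 0.365998, 0.199023), nu=0.785990),
    ),
}


@dataclass(frozen=True)
class CovariateSpec:
    """Per-group covariate model: location by diagnosis group plus spread.

    ``kind`` is ``"lognormal"`` (location/spread on the natural scale,
    converted internally) or ``"normal"``.  Group locations are ordered so
    that greater impairment shifts in the clinically expected direction.
    """

    kind: str
    group_mean: Mapping[str, float]
    sd: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_mean", dict(self.group_mean))
        if self.kind not in ("lognormal", "normal"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if set(self.group_mean) != {"CU", "MCI", "Dem"}:
            raise ValueError("group_mean must have CU/MCI/Dem keys")
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    def sample(self, group: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        means = np.array([self.group_mean[g] for g in group], dtype=float)
        if self.kind == "normal":
            return rng.normal(means, self.sd)
        # lognormal parameterized by natural-scale mean and SD
        var = self.sd**2
        sigma2 = np.log1p(var / means**2)
        mu = np.log(means) - sigma2 / 2
        return np.exp(rng.normal(mu, np.sqrt(sigma2)))


#: covariate surrogates; shifts ordered CU < MCI < Dem for age and the
#: reverse for the performance measures (magnitudes are free configuration)
DEFAULT_COVARIATES = {
    "age": CovariateSpec("lognormal", {"CU": 67.2, "MCI": 70.2, "Dem": 72.8}, 9.5),
    "education": CovariateSpec("normal", {"CU": 15.7, "MCI": 15.0, "Dem": 14.2}, 2.7),
    "mmse": CovariateSpec("normal", {"CU": 27.4, "MCI": 26.1, "Dem": 23.9}, 2.5),
    "dctclock": CovariateSpec("normal", {"CU": 64.6, "MCI": 53.2, "Dem": 40.1}, 23.5),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the generator needs, disclosed for recovery tests.

    ``label_fractions`` gives the probabilities that a record is unlabeled,
    carries its exact generating cluster as a label, or carries only its
    diagnosis group (a partial label whenever the group holds several
    clusters).
    """

    structure: ClusterStructure = DEFAULT_STRUCTURE
    weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    cluster_params: Mapping[str, Mapping] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLUSTER_PARAMS.items()}
    )
    covariates: Mapping[str, CovariateSpec] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    label_fractions: tuple = (0.8, 0.1, 0.1)  # unlabeled, cluster label, group label

    def __post_init__(self) -> None:
        w = np.array([self.weights[c] for c in self.structure.names])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-3:
            raise ValueError("weights must be non-negative and sum to 1")
        if abs(sum(self.label_fractions) - 1.0) > 1e-9 or min(self.label_fractions) < 0:
            raise ValueError("label fractions must be non-negative and sum to 1")
        for c in self.structure.names:
            if c not in self.cluster_params:
                raise ValueError(f"missing parameters for cluster {c}")

    def weight_vector(self) -> np.ndarray:
        w = np.array([self.weights[c] for c in self.structure.names], dtype=float)
        return w / w.sum()

    def true_model(self) -> MixtureModel:
        """The generating mixture as a model object (for oracle posteriors
        and recovery comparisons)."""
        return MixtureModel(
            weights=self.weight_vector(),
            components=tuple(dict(self.cluster_params[c]) for c in self.structure.names),
            structure=self.structure,
        )


@dataclass(frozen=True)
class SyntheticDataset:
    records: tuple
    true_clusters: tuple
    true_labels: tuple  # diagnosis group of the generating cluster
    config: GeneratorConfig
    seed: int

    def __len__(self) -> int:
        return len(self.records)


def default_true_model() -> GeneratorConfig:
    """The default generator configuration (published cluster weights and
    moment-matched per-cluster distribution parameters)."""
    return GeneratorConfig()


def default_generator_config() -> GeneratorConfig:
    return GeneratorConfig()


def generate(
    config: GeneratorConfig | None = None, N: int = 1000, seed: int = 0
) -> SyntheticDataset:
    """Draw a synthetic dataset: cluster per record from the mixture
    weights, the four metrics independently from that cluster's
    distributions, covariates from group-shifted models, and labels
    following the label regime.  Identical seeds give identical datasets."""
    if config is None:
        config = GeneratorConfig()
    if N <= 0:
        raise ValueError("N must be positive")
    rng = np.random.default_rng(seed)
    names = config.structure.names
    cluster_idx = rng.choice(len(names), size=N, p=config.weight_vector())
    clusters = [names[i] for i in cluster_idx]
    groups = np.array([config.structure.group_of(c) for c in clusters])

    # metric draws, one cluster at a time
    bdst = np.zeros(N, dtype=int)
    animals = np.zeros(N, dtype=int)
    recall = np.zeros(N, dtype=int)
    recog = np.zeros((N, 3), dtype=int)
    for i, name in enumerate(names):
        mask = cluster_idx == i
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        prm = config.cluster_params[name]
        bdst[mask] = dist.sample(prm["bdst"], cnt, rng)
        animals[mask] = dist.sample(prm["animals"], cnt, rng)
        recall[mask] = dist.sample(prm["recall"], cnt, rng)
        recog[mask] = dist.sample(prm["recognition"], cnt, rng)

    covs = {name: spec.sample(groups, rng) for name, spec in config.covariates.items()}

    u = rng.random(N)
    f_unlab, f_cluster, _ = config.label_fractions
    labels = np.where(
        u < f_unlab,
        "unlabeled",
        np.where(u < f_unlab + f_cluster, np.array(clusters), groups),
    )

    records = tuple(
        AssessmentRecord(
            subject_id=f"S{i:05d}",
            bdst=int(bdst[i]),
            animals=int(animals[i]),
            recall=int(recall[i]),
            recognition=tuple(recog[i]),
            label=str(labels[i]),
            covariates={k: float(v[i]) for k, v in covs.items()},
        )
        for i in range(N)
    )
    return SyntheticDataset(
        records=records,
        true_clusters=tuple(clusters),
        true_labels=tuple(groups),
        config=config,
        seed=seed,
    )


def generate_null_covariate(N: int, seed: int = 0, *, constant: bool = False) -> np.ndarray:
    """A covariate drawn independently of any cluster (type-I-error studies).

    Skewed (lognormal) draws by default; ``constant`` returns a flat vector
    (downstream rank statistics then vanish identically).
    """
    if N < 1:
        raise ValueError("N must be at least 1")
    if constant:
        return np.ones(N)
    rng = np.random.default_rng(seed)
    return np.exp(rng.normal(0.0, 0.5, size=N))
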