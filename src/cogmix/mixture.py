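"""Semi-supervised finite mixture model with label constraints.

The model clusters subjects from four assessment metrics — backward digit
span serial score (0-15), unique animals named, delayed recall words (0-6),
and a delayed-recognition triple (correct / prototypical foil / generic
foil, summing to 6).  Metrics are modeled independently within a cluster
using the Conway-Maxwell families from :mod:`cogmix.distributions`.

Clusters are organized into three diagnosis groups (CU, MCI, Dem).  Partial
supervision enters through a binary record-by-cluster constraint matrix: a
diagnosis label restricts a record to that group's clusters during the
E-step (an MCI label with three MCI clusters is a partial label — it pins
the group but not the cluster), an exact cluster label pins one cluster,
and unlabeled records are unconstrained.  Fitting alternates a constrained
E-step with weighted per-cluster maximum-likelihood M-steps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import distributions as dist
from .distributions import (
    CMBinomialParams,
    CMMultinomialParams,
    CMPoissonParams,
    LognormalParams,
    Params,
)

__all__ = [
    "GROUPS",
    "DIAGNOSIS_CLASSES",
    "ClusterStructure",
    "DEFAULT_STRUCTURE",
    "THREE_CLUSTER_STRUCTURE",
    "AssessmentRecord",
    "MixtureModel",
    "FitResult",
    "ImpossibleRecordError",
    "EmptyClusterError",
    "DAC_METRICS",
    "AGE_ONLY_METRICS",
    "build_constraints",
    "record_log_density",
    "records_to_arrays",
    "read_records_csv",
    "write_records_csv",
    "e_step",
    "m_step",
    "log_likelihood",
    "fit_em",
    "predict_posteriors",
    "collapse_posteriors",
    "classify",
    "task_scores",
    "TASKS",
]

GROUPS = ("CU", "MCI", "Dem")
DIAGNOSIS_CLASSES = GROUPS  # collapsed 3-class scale, ordered least impaired first

#: metric name -> (family, fit keyword arguments)
DAC_METRICS: dict[str, dict] = {
    "bdst": {"family": "cm_binomial", "n": 15, "inflation": "N"},
    "animals": {"family": "cm_poisson"},
    "recall": {"family": "cm_binomial", "n": 6, "inflation": "zero"},
    "recognition": {"family": "cm_multinomial", "n": 6},
}

#: baseline comparator using age alone
AGE_ONLY_METRICS: dict[str, dict] = {"age": {"family": "lognormal"}}

_WEIGHT_FLOOR = 1e-6
_EMPTY_CLUSTER_TOL = 1e-8


class ImpossibleRecordError(ValueError):
    """A record has zero likelihood under every cluster its constraints permit."""

    def __init__(self, indices, message=None):
        self.indices = list(indices)
        super().__init__(
            message
            or f"records at positions {self.indices} are impossible under every "
            "permitted cluster"
        )


class EmptyClusterError(RuntimeError):
    """A cluster retained (essentially) zero total responsibility."""


# ---------------------------------------------------------------------------
# Structure and records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterStructure:
    """Ordered cluster names and their partition into diagnosis groups."""

    names: tuple
    groups: Mapping[str, tuple]

    def __post_init__(self) -> None:
        names = tuple(self.names)
        groups = {g: tuple(v) for g, v in self.groups.items()}
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "groups", groups)
        if set(groups) != set(GROUPS):
            raise ValueError(f"groups must be exactly {GROUPS}")
        flat = [c for g in GROUPS for c in groups[g]]
        if sorted(flat) != sorted(names) or len(set(flat)) != len(flat):
            raise ValueError("groups must partition the cluster names")
        if len(set(names)) != len(names):
            raise ValueError("cluster names must be unique")

    @property
    def n_clusters(self) -> int:
        return len(self.names)

    def group_of(self, cluster: str) -> str:
        for g in GROUPS:
            if cluster in self.groups[g]:
                return g
        raise KeyError(cluster)

    def cluster_indices(self, names: Sequence[str]) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.names)}
        return np.array([pos[c] for c in names], dtype=int)

    def group_collapse_matrix(self) -> np.ndarray:
        """K x 3 binary matrix mapping clusters onto (CU, MCI, Dem)."""
        M = np.zeros((self.n_clusters, 3))
        for j, g in enumerate(GROUPS):
            M[self.cluster_indices(self.groups[g]), j] = 1.0
        return M


#: the six-cluster structure of the final assessment model; group tuples
#: are listed in ascending-recall order so canonical reordering puts the
#: severe-amnestic clusters in the slots their names imply
DEFAULT_STRUCTURE = ClusterStructure(
    names=("CU", "dMCI", "mxMCI", "aMCI", "maDem", "saDem"),
    groups={"CU": ("CU",), "MCI": ("aMCI", "mxMCI", "dMCI"), "Dem": ("saDem", "maDem")},
)

#: one cluster per diagnosis group (starting / baseline configuration)
THREE_CLUSTER_STRUCTURE = ClusterStructure(
    names=("CU", "MCI", "Dem"),
    groups={"CU": ("CU",), "MCI": ("MCI",), "Dem": ("Dem",)},
)


@dataclass(frozen=True)
class AssessmentRecord:
    """One subject's four-metric score vector plus optional label/covariates."""

    subject_id: str
    bdst: int
    animals: int
    recall: int
    recognition: tuple
    label: str = "unlabeled"
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rec = tuple(int(v) for v in self.recognition)
        object.__setattr__(self, "recognition", rec)
        object.__setattr__(self, "covariates", dict(self.covariates))
        if not 0 <= self.bdst <= 15:
            raise ValueError(f"bdst must lie in 0..15, got {self.bdst}")
        if self.animals < 0:
            raise ValueError(f"animals must be non-negative, got {self.animals}")
        if not 0 <= self.recall <= 6:
            raise ValueError(f"recall must lie in 0..6, got {self.recall}")
        if len(rec) != 3 or any(v < 0 for v in rec) or sum(rec) != 6:
            raise ValueError(
                f"recognition must be a non-negative triple summing to 6, got {rec}"
            )


def records_to_arrays(records: Sequence[AssessmentRecord]) -> dict:
    """Stack records into column arrays keyed by metric/covariate name."""
    data = {
        "subject_id": np.array([r.subject_id for r in records]),
        "bdst": np.array([r.bdst for r in records], dtype=int),
        "animals": np.array([r.animals for r in records], dtype=int),
        "recall": np.array([r.recall for r in records], dtype=int),
        "recognition": np.array([r.recognition for r in records], dtype=int),
        "label": np.array([r.label for r in records]),
    }
    cov_names = sorted({k for r in records for k in r.covariates})
    for k in cov_names:
        data[k] = np.array([r.covariates.get(k, np.nan) for r in records], dtype=float)
    return data


_CSV_COLUMNS = [
    "subject_id", "bdst_serial", "animals", "recall_correct",
    "recog_correct", "recog_prototypical", "recog_generic", "label",
]


def write_records_csv(records: Sequence[AssessmentRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "bdst_serial": r.bdst,
            "animals": r.animals,
            "recall_correct": r.recall,
            "recog_correct": r.recognition[0],
            "recog_prototypical": r.recognition[1],
            "recog_generic": r.recognition[2],
            "label": "" if r.label == "unlabeled" else r.label,
        }
        row.update(r.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_records_csv(path) -> list[AssessmentRecord]:
    """Read assessment records; malformed rows are reported with line numbers."""
    df = pd.read_csv(path, dtype={"label": "string", "subject_id": "string"})
    missing = [c for c in _CSV_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"input CSV is missing required columns: {missing}")
    cov_cols = [c for c in df.columns if c not in _CSV_COLUMNS]
    records, errors = [], []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            label = row.get("label")
            label = "unlabeled" if pd.isna(label) or label == "" else str(label)
            covs = {c: float(row[c]) for c in cov_cols if not pd.isna(row[c])}
            records.append(
                AssessmentRecord(
                    subject_id=str(row["subject_id"]),
                    bdst=int(row["bdst_serial"]),
                    animals=int(row["animals"]),
                    recall=int(row["recall_correct"]),
                    recognition=(
                        int(row["recog_correct"]),
                        int(row["recog_prototypical"]),
                        int(row["recog_generic"]),
                    ),
                    label=label,
                    covariates=covs,
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValueError("invalid rows in input CSV:\n" + "\n".join(errors))
    return records


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixtureModel:
    """Mixture weights, per-cluster per-metric parameters, cluster structure.

    ``components[c]`` maps metric name to its parameter bundle for cluster
    ``c`` (ordered as ``structure.names``).
    """

    weights: np.ndarray
    components: tuple
    structure: ClusterStructure

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "components", tuple(dict(c) for c in self.components))
        if len(w) != self.structure.n_clusters or len(self.components) != len(w):
            raise ValueError("weights/components/structure sizes disagree")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be a probability vector")

    @property
    def metrics(self) -> tuple:
        return tuple(self.components[0])

    def cluster_means(self, metric: str) -> np.ndarray:
        """Exact per-cluster means of a metric (first category for the
        recognition triple)."""
        out = []
        for comp in self.components:
            m, _ = dist.moments(comp[metric])
            out.append(m[0] if np.ndim(m) else m)
        return np.array(out)

    def canonicalized(self, order_metric: str | None = None) -> "MixtureModel":
        """Reorder clusters within each diagnosis group by ascending mean of
        ``order_metric`` (delayed recall by default), resolving label
        switching among exchangeable within-group clusters."""
        if order_metric is None:
            order_metric = "recall" if "recall" in self.metrics else self.metrics[0]
        means = self.cluster_means(order_metric)
        perm = np.arange(self.structure.n_clusters)
        for g in GROUPS:
            idx = self.structure.cluster_indices(self.structure.groups[g])
            perm[idx] = idx[np.argsort(means[idx], kind="stable")]
        return MixtureModel(
            weights=self.weights[perm],
            components=tuple(self.components[i] for i in perm),
            structure=self.structure,
        )

    def to_json(self) -> dict:
        return {
            "weights": [float(v) for v in self.weights],
            "structure": {
                "names": list(self.structure.names),
                "groups": {g: list(v) for g, v in self.structure.groups.items()},
            },
            "clusters": {
                name: {m: dist.params_to_json(p) for m, p in comp.items()}
                for name, comp in zip(self.structure.names, self.components)
            },
        }

    @classmethod
    def from_json(cls, d: dict) -> "MixtureModel":
        structure = ClusterStructure(
            names=tuple(d["structure"]["names"]),
            groups={g: tuple(v) for g, v in d["structure"]["groups"].items()},
        )
        comps = tuple(
            {m: dist.params_from_json(p) for m, p in d["clusters"][name].items()}
            for name in structure.names
        )
        return cls(weights=np.array(d["weights"]), components=comps, structure=structure)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "MixtureModel":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


@dataclass(frozen=True)
class FitResult:
    model: MixtureModel
    log_likelihood_trace: np.ndarray
    n_iter: int
    converged: bool
    seed: int

    @property
    def log_likelihood(self) -> float:
        return float(self.log_likelihood_trace[-1])


# ---------------------------------------------------------------------------
# Constraints
# ---------------------------------------------------------------------------


def build_constraints(labels: Sequence[str], structure: ClusterStructure) -> np.ndarray:
    """N x K binary constraint matrix from diagnosis (or cluster) labels.

    ``"unlabeled"`` (or empty) rows are all-ones; a diagnosis-group label
    marks the group's clusters; an exact cluster name marks that cluster.
    """
    K = structure.n_clusters
    rows = {"unlabeled": np.ones(K, dtype=int), "": np.ones(K, dtype=int)}
    for g in GROUPS:
        row = np.zeros(K, dtype=int)
        row[structure.cluster_indices(structure.groups[g])] = 1
        rows[g] = row
    for i, c in enumerate(structure.names):
        if c not in rows:  # a cluster name may shadow its group name (e.g. "CU")
            row = np.zeros(K, dtype=int)
            row[i] = 1
            rows[c] = row
    C = np.empty((len(labels), K), dtype=int)
    for i, lab in enumerate(labels):
        lab = "unlabeled" if lab is None else str(lab)
        if lab not in rows:
            raise ValueError(f"unknown label {lab!r} at position {i}")
        C[i] = rows[lab]
    return C


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


def _metric_log_density(values, params: Params) -> np.ndarray:
    if isinstance(params, CMPoissonParams):
        uniq, inv = np.unique(values, return_inverse=True)
        return np.asarray(dist.cm_poisson_log_pmf(uniq, params))[inv]
    if isinstance(params, CMBinomialParams):
        table = np.asarray(dist.cm_binomial_log_pmf(np.arange(params.n + 1), params))
        return table[np.asarray(values, dtype=int)]
    if isinstance(params, CMMultinomialParams):
        return np.asarray(dist.cm_multinomial_log_pmf(values, params))
    if isinstance(params, LognormalParams):
        return np.asarray(dist.lognormal_log_pdf(values, params))
    raise TypeError(type(params).__name__)


def record_log_density(
    record: AssessmentRecord | dict, cluster_params: Mapping[str, Params]
) -> float:
    """Joint log-density of one record under one cluster: the sum of the
    per-metric log-PMFs (metrics are modeled independently)."""
    if isinstance(record, AssessmentRecord):
        values = {
            "bdst": record.bdst,
            "animals": record.animals,
            "recall": record.recall,
            "recognition": record.recognition,
            **record.covariates,
        }
    else:
        values = record
    total = 0.0
    for metric, params in cluster_params.items():
        v = values[metric]
        arr = (
            np.atleast_2d(v)
            if isinstance(params, CMMultinomialParams)
            else np.atleast_1d(v)
        )
        total += float(_metric_log_density(arr, params)[0])
    return total


def log_density_matrix(model: MixtureModel, data: dict) -> np.ndarray:
    """N x K matrix of per-cluster joint log-densities."""
    first = model.metrics[0]
    N = len(data[first])
    out = np.zeros((N, model.structure.n_clusters))
    for c, comp in enumerate(model.components):
        for metric, params in comp.items():
            out[:, c] += _metric_log_density(data[metric], params)
    return out


def e_step(model: MixtureModel, data: dict, C: np.ndarray) -> np.ndarray:
    """Constrained posterior responsibilities: gamma_ic proportional to
    C_ic * w_c * f_c(x_i), rows renormalized."""
    log_dens = log_density_matrix(model, _as_data(data))
    return _e_step_from_log_density(model.weights, log_dens, C)[0]


def _e_step_from_log_density(weights, log_dens, C):
    with np.errstate(divide="ignore"):
        log_num = np.log(np.maximum(weights, 1e-300))[None, :] + log_dens
    log_num = np.where(C > 0, log_num, -np.inf)
    row_norm = logsumexp(log_num, axis=1)
    bad = ~np.isfinite(row_norm)
    if np.any(bad):
        raise ImpossibleRecordError(np.flatnonzero(bad))
    gamma = np.exp(log_num - row_norm[:, None])
    gamma[C == 0] = 0.0
    return gamma, float(row_norm.sum())


def m_step(
    data: dict,
    gamma: np.ndarray,
    structure: ClusterStructure,
    metrics: Mapping[str, dict] = DAC_METRICS,
    *,
    init: MixtureModel | None = None,
    starts: int = 1,
    seed: int = 0,
) -> MixtureModel:
    """Weighted maximum-likelihood update of weights and all cluster-metric
    parameters.  ``init`` supplies warm starts for the optimizers."""
    data = _as_data(data)
    N, K = gamma.shape
    col = gamma.sum(axis=0)
    if np.any(col < _EMPTY_CLUSTER_TOL):
        warnings.warn(
            f"clusters {np.flatnonzero(col < _EMPTY_CLUSTER_TOL).tolist()} have "
            "near-zero responsibility; applying weight floor",
            RuntimeWarning,
        )
    weights = np.maximum(col / N, _WEIGHT_FLOOR)
    weights = weights / weights.sum()
    comps = []
    for c in range(K):
        comp = {}
        w_c = gamma[:, c]
        if w_c.sum() < _EMPTY_CLUSTER_TOL:
            # keep previous parameters for a (temporarily) empty cluster
            if init is not None:
                comps.append(dict(init.components[c]))
                continue
            raise EmptyClusterError(
                f"cluster {structure.names[c]} is empty at the M-step"
            )
        for metric, spec in metrics.items():
            comp[metric] = dist.fit_weighted(
                data[metric],
                w_c,
                spec["family"],
                n=spec.get("n"),
                inflation=spec.get("inflation", "none"),
                fixed=spec.get("fixed"),
                starts=starts,
                seed=seed + 7919 * c,
                init=None if init is None else init.components[c].get(metric),
            )
        comps.append(comp)
    return MixtureModel(weights=weights, components=tuple(comps), structure=structure)


def log_likelihood(model: MixtureModel, data, C: np.ndarray | None = None) -> float:
    """Constrained observed-data log-likelihood
    sum_i log sum_c C_ic w_c f_c(x_i).  Returns ``-inf`` if any record is
    impossible under all of its permitted clusters."""
    data = _as_data(data)
    first = model.metrics[0]
    if C is None:
        C = np.ones((len(data[first]), model.structure.n_clusters), dtype=int)
    log_dens = log_density_matrix(model, data)
    with np.errstate(divide="ignore"):
        log_num = np.log(np.maximum(model.weights, 1e-300))[None, :] + log_dens
    log_num = np.where(C > 0, log_num, -np.inf)
    row = logsumexp(log_num, axis=1)
    if np.any(~np.isfinite(row)):
        return -np.inf
    return float(row.sum())


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def _as_data(records) -> dict:
    if isinstance(records, dict):
        return records
    return records_to_arrays(records)


def fit_em(
    records,
    labels: Sequence[str] | None = None,
    structure: ClusterStructure = DEFAULT_STRUCTURE,
    metrics: Mapping[str, dict] = DAC_METRICS,
    *,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    m_step_starts: int = 1,
    init_concentration: float = 20.0,
    max_restarts: int = 5,
) -> FitResult:
    """Fit the semi-supervised mixture by constrained EM.

    Responsibilities are initialized from the constraint-matrix rows
    (normalized), perturbed by seeded Dirichlet noise so that symmetric
    clusters separate; labeled rows stay inside their permitted clusters.
    Iteration stops when the relative change of the constrained
    observed-data log-likelihood falls below ``tol`` or after ``max_iter``
    iterations.  If an initialization leaves a cluster empty, fitting
    restarts with a fresh seeded perturbation up to ``max_restarts`` times.
    """
    data = _as_data(records)
    if labels is None:
        lab = data.get("label")
        labels = list(lab) if lab is not None else ["unlabeled"] * len(data["bdst"])
    C = build_constraints(list(labels), structure)
    N, K = C.shape
    if N == 0:
        raise ValueError("records must be non-empty")

    last_err: Exception | None = None
    for attempt in range(max_restarts):
        rng = np.random.default_rng(seed + 1_000_003 * attempt)
        noise = rng.dirichlet(np.full(K, init_concentration), size=N)
        gamma0 = C * noise
        gamma0 = gamma0 / gamma0.sum(axis=1, keepdims=True)
        try:
            return _run_em(
                data, C, gamma0, structure, metrics, seed, tol, max_iter, m_step_starts
            )
        except EmptyClusterError as exc:
            last_err = exc
    raise EmptyClusterError(
        f"initialization left a cluster empty in all {max_restarts} attempts"
    ) from last_err


def _run_em(data, C, gamma, structure, metrics, seed, tol, max_iter, m_step_starts):
    trace = []
    model = None
    converged = False
    for it in range(max_iter):
        model = m_step(
            data, gamma, structure, metrics,
            init=model, starts=(3 if it == 0 else m_step_starts), seed=seed,
        )
        log_dens = log_density_matrix(model, data)
        gamma, ll = _e_step_from_log_density(model.weights, log_dens, C)
        trace.append(ll)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(ll - prev) <= tol * (abs(prev) + 1e-12):
                converged = True
                break
    col = gamma.sum(axis=0)
    if np.any(col < _EMPTY_CLUSTER_TOL):
        raise EmptyClusterError(
            f"clusters {np.flatnonzero(col < _EMPTY_CLUSTER_TOL).tolist()} empty at convergence"
        )
    return FitResult(
        model=model,
        log_likelihood_trace=np.array(trace),
        n_iter=len(trace),
        converged=converged,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Prediction, collapse, classification
# ---------------------------------------------------------------------------


def predict_posteriors(model: MixtureModel, records) -> np.ndarray:
    """Posterior responsibilities for new records (no label constraints)."""
    data = _as_data(records)
    N = len(data[model.metrics[0]])
    C = np.ones((N, model.structure.n_clusters), dtype=int)
    return e_step(model, data, C)


def collapse_posteriors(gamma: np.ndarray, structure: ClusterStructure) -> np.ndarray:
    """Sum cluster posteriors within each diagnosis group -> N x 3 rows
    ordered (CU, MCI, Dem)."""
    return np.asarray(gamma) @ structure.group_collapse_matrix()


TASKS = ("impairment", "dementia", "cu_vs_mci", "mci_vs_dem")


def task_scores(p3: np.ndarray, task: str) -> np.ndarray:
    """Probability score of the positive (more impaired) side of a task.

    The two conditional tasks renormalize over the task's two classes.
    """
    p3 = np.atleast_2d(p3)
    cu, mci, dem = p3[:, 0], p3[:, 1], p3[:, 2]
    if task == "impairment":
        return mci + dem
    if task == "dementia":
        return dem
    if task == "cu_vs_mci":
        with np.errstate(invalid="ignore"):
            return mci / (cu + mci)
    if task == "mci_vs_dem":
        with np.errstate(invalid="ignore"):
            return dem / (mci + dem)
    raise ValueError(f"unknown task {task!r}")


def classify(p3: np.ndarray, task: str = "3class"):
    """Decision rule on collapsed 3-class probability rows.

    The 3-class decision is the argmax over (CU, MCI, Dem), preferring the
    less-impaired class on exact ties.  Binary tasks threshold the summed
    (conditional tasks: renormalized) positive-side probability at 0.5,
    again resolving an exact tie toward the less-impaired side.
    """
    p3 = np.atleast_2d(p3)
    if task == "3class":
        # np.argmax returns the first maximum; column order is least impaired first
        return np.array(DIAGNOSIS_CLASSES)[np.argmax(p3, axis=1)]
    return task_scores(p3, task) > 0.5
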