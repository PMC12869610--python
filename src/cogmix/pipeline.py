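"""Run orchestration: generate -> fit -> diagnose -> validate -> evaluate.

Every stage reads a single :class:`RunConfig` (loadable from a YAML file),
takes all randomness from named seeds recorded in a run manifest (config
hash, seeds, library versions), and writes plain CSV/JSON outputs, so a
rerun with an identical manifest reproduces identical numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from . import classification_eval as ce
from . import diagnostics as dg
from . import group_tests as gt
from . import mixture as mx
from . import synthetic_data as sd

__all__ = [
    "RunConfig",
    "load_config",
    "write_manifest",
    "run_generate",
    "run_fit",
    "run_diagnose",
    "run_validate",
    "run_evaluate",
    "run_report",
]

log = logging.getLogger("cogmix")

_STRUCTURES = {
    "default": mx.DEFAULT_STRUCTURE,
    "three_cluster": mx.THREE_CLUSTER_STRUCTURE,
}


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one analysis run.

    All seeds are explicit; the Monte-Carlo draw counts default to the
    10,000 used for both the permutation tests and the bootstrap.
    """

    output_dir: str = "out"
    input: str | None = None
    holdout: str | None = None
    structure: str = "default"
    seeds: Mapping[str, int] = field(
        default_factory=lambda: {"em": 1, "cv": 2, "mc": 3, "bootstrap": 4, "generator": 5}
    )
    tol: float = 1e-8
    max_iter: int = 500
    cv_folds: int = 10
    b_tests: int = 10_000
    b_bootstrap: int = 10_000
    generate_n: int = 1000
    covariate_columns: tuple = ("age", "education", "mmse", "dctclock")
    age_only: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "seeds", dict(self.seeds))
        object.__setattr__(self, "covariate_columns", tuple(self.covariate_columns))
        missing = {"em", "cv", "mc", "bootstrap", "generator"} - set(self.seeds)
        if missing:
            raise ValueError(f"seeds missing for stages: {sorted(missing)}")
        if self.structure not in _STRUCTURES:
            raise ValueError(
                f"structure must be one of {sorted(_STRUCTURES)}, got {self.structure!r}"
            )
        if self.b_tests < 1 or self.b_bootstrap < 100:
            raise ValueError("draw counts too small")

    @property
    def cluster_structure(self) -> mx.ClusterStructure:
        return _STRUCTURES[self.structure]

    @property
    def metrics(self) -> dict:
        return mx.AGE_ONLY_METRICS if self.age_only else mx.DAC_METRICS

    def out(self, name: str) -> Path:
        p = Path(self.output_dir)
        p.mkdir(parents=True, exist_ok=True)
        return p / name


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must hold a mapping")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ValueError(f"invalid config: {exc}") from exc


def _config_hash(config: RunConfig) -> str:
    canon = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def write_manifest(config: RunConfig, extra: dict | None = None) -> Path:
    import scipy
    import sklearn
    import statsmodels

    manifest = {
        "config_sha256": _config_hash(config),
        "config": asdict(config),
        "seeds": dict(config.seeds),
        "versions": {
            "cogmix": _pkg_version,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    path = config.out("manifest.json")
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def run_generate(config: RunConfig) -> Path:
    """Write a synthetic dataset (records CSV + disclosed generating
    parameters JSON) under the output directory."""
    log.info("generate: N=%d seed=%d", config.generate_n, config.seeds["generator"])
    ds = sd.generate(N=config.generate_n, seed=config.seeds["generator"])
    path = config.out("records.csv")
    mx.write_records_csv(ds.records, path)
    truth = {
        "weights": {c: ds.config.weights[c] for c in ds.config.structure.names},
        "clusters": ds.config.true_model().to_json()["clusters"],
        "true_clusters": list(ds.true_clusters),
        "seed": ds.seed,
    }
    config.out("generating_params.json").write_text(json.dumps(truth, indent=1))
    write_manifest(config)
    return path


def _load_records(path, structure: mx.ClusterStructure | None = None) -> list:
    if path is None:
        raise ValueError("config.input is required for this stage")
    records = mx.read_records_csv(path)
    if structure is not None:
        records = [_coerce_label(r, structure) for r in records]
    return records


def _coerce_label(record: mx.AssessmentRecord, structure: mx.ClusterStructure):
    """Map a cluster-level label onto its diagnosis group when the target
    structure does not contain that cluster (e.g. refitting six-cluster
    labeled data with the three-cluster baseline)."""
    import dataclasses

    lab = record.label
    known = set(structure.names) | set(mx.GROUPS) | {"unlabeled", ""}
    if lab in known:
        return record
    for src in (mx.DEFAULT_STRUCTURE,):
        if lab in src.names:
            return dataclasses.replace(record, label=src.group_of(lab))
    return record  # leave it; build_constraints will report it precisely


def run_fit(config: RunConfig) -> mx.FitResult:
    """Fit the semi-supervised mixture and write the model JSON, the
    log-likelihood trace, and the run manifest."""
    records = _load_records(config.input, config.cluster_structure)
    log.info("fit: %d records, structure=%s", len(records), config.structure)
    fr = mx.fit_em(
        records,
        structure=config.cluster_structure,
        metrics=config.metrics,
        seed=config.seeds["em"],
        tol=config.tol,
        max_iter=config.max_iter,
    )
    model = fr.model.canonicalized()
    model.save(config.out("model.json"))
    pd.DataFrame(
        {"iteration": np.arange(fr.n_iter), "log_likelihood": fr.log_likelihood_trace}
    ).to_csv(config.out("loglik_trace.csv"), index=False)
    write_manifest(
        config,
        extra={"fit": {"iterations": fr.n_iter, "converged": fr.converged,
                       "log_likelihood": fr.log_likelihood}},
    )
    for i, ll in enumerate(fr.log_likelihood_trace):
        log.debug("EM iteration %d: log-likelihood %.6f", i, ll)
    log.info("fit: converged=%s after %d iterations", fr.converged, fr.n_iter)
    return fr


def run_diagnose(config: RunConfig, model: mx.MixtureModel | None = None) -> dg.CVResult:
    """Cross-validated log-likelihood and randomized quantile residuals."""
    records = _load_records(config.input, config.cluster_structure)
    cv = dg.cv_log_likelihood(
        records,
        structure=config.cluster_structure,
        metrics=config.metrics,
        folds=config.cv_folds,
        seed=config.seeds["cv"],
        fit_kwargs={"seed": config.seeds["em"], "tol": config.tol,
                    "max_iter": config.max_iter},
    )
    cv.to_frame().to_csv(config.out("cv_log_likelihood.csv"), index=False)
    if model is None:
        model_path = config.out("model.json")
        if model_path.exists():
            model = mx.MixtureModel.load(model_path)
        else:
            model = run_fit(config).model
    res = dg.randomized_quantile_residuals(model, records, seed=config.seeds["cv"])
    res.to_frame().to_csv(config.out("quantile_residuals.csv"), index=False)
    dg.qq_summary(res).to_csv(config.out("residual_qq.csv"), index=False)
    log.info("diagnose: CV total %.2f over %d folds", cv.total, config.cv_folds)
    return cv


def run_validate(config: RunConfig, model: mx.MixtureModel) -> dict:
    """Soft-membership rank tests for every covariate, at 6-cluster and
    collapsed 3-cluster granularity; tidy CSV outputs."""
    records = _load_records(config.input)
    data = mx.records_to_arrays(records)
    gamma = mx.predict_posteriors(model, data)
    struct = model.structure
    gamma3 = mx.collapse_posteriors(gamma, struct)
    results = {"clusters": [], "groups": []}
    for var in config.covariate_columns:
        if var not in data or np.all(np.isnan(data[var])):
            warnings.warn(f"covariate {var!r} missing entirely; skipped", RuntimeWarning)
            continue
        for key, g, names in (
            ("clusters", gamma, struct.names),
            ("groups", gamma3, mx.GROUPS),
        ):
            results[key].append(
                gt.soft_rank_tests(
                    data[var], g,
                    B=config.b_tests, seed=config.seeds["mc"],
                    variable=var, group_names=names,
                )
            )
    gt.results_to_frame(results["clusters"]).to_csv(
        config.out("validate_6cluster.csv"), index=False
    )
    gt.results_to_frame(results["groups"]).to_csv(
        config.out("validate_3cluster.csv"), index=False
    )
    log.info("validate: %d covariates tested", len(results["groups"]))
    return results


def run_evaluate(config: RunConfig, model: mx.MixtureModel) -> ce.ClassificationReport:
    """Predictive validity on a labeled holdout: collapse posteriors,
    3-class confusion, binary-task metrics, AUROCs with BCa intervals."""
    records = _load_records(config.holdout or config.input)
    data = mx.records_to_arrays(records)
    labels = [r.label for r in records]
    if any(l not in mx.GROUPS for l in labels):
        raise ValueError("evaluation requires a CU/MCI/Dem label on every record")
    gamma = mx.predict_posteriors(model, data)
    p3 = mx.collapse_posteriors(gamma, model.structure)
    report = ce.evaluate_posteriors(
        labels, p3, B=config.b_bootstrap, seed=config.seeds["bootstrap"]
    )
    config.out("evaluation.json").write_text(json.dumps(report.to_json(), indent=1))
    config.out("evaluation.txt").write_text(report.to_table() + "\n")
    log.info("evaluate: accuracy %.3f on %d records", report.accuracy[0], len(records))
    return report


def run_report(config: RunConfig) -> Path:
    """Collect stage outputs under the output directory into one summary."""
    parts = []
    for name in (
        "manifest.json", "loglik_trace.csv", "cv_log_likelihood.csv",
        "validate_3cluster.csv", "validate_6cluster.csv", "evaluation.txt",
    ):
        p = config.out(name)
        if p.exists():
            parts.append(f"== {name} ==\n{p.read_text()}")
    path = config.out("report.txt")
    path.write_text("\n\n".join(parts) if parts else "no stage outputs found\n")
    return path
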