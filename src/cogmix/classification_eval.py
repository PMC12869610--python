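"""Predictive-validity evaluation of the 3-class staging output.

Cluster posteriors collapsed to (CU, MCI, Dem) are compared against
gold-standard diagnoses: overall accuracy and a 3x3 confusion matrix, four
clinically motivated binary tasks (impairment and dementia detection, and
the two conditional contrasts CU-vs-MCI and MCI-vs-Dem) with exact
Clopper-Pearson binomial intervals on sensitivity / specificity / PPV /
NPV, and AUROC with bias-corrected-and-accelerated (BCa) bootstrap
intervals.

A small held-out confusion-matrix fixture (75 diagnosis/prediction pairs)
ships with the package so the evaluation arithmetic can be exercised
without any subject-level data.
"""

from __future__ import annotations

import importlib.resources
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import bootstrap as _scipy_bootstrap
from statsmodels.stats.proportion import proportion_confint

from .mixture import DIAGNOSIS_CLASSES, TASKS, task_scores

__all__ = [
    "confusion_matrix",
    "accuracy_with_ci",
    "binary_task_metrics",
    "auroc",
    "auroc_with_ci",
    "bca_bootstrap_ci",
    "BinaryTaskMetrics",
    "ClassificationReport",
    "evaluate_posteriors",
    "report_from_confusion",
    "holdout_fixture",
]

_CLASS_INDEX = {c: i for i, c in enumerate(DIAGNOSIS_CLASSES)}

#: task -> (diagnosis classes included, positive diagnosis classes,
#:          predicted classes counted as a positive call)
_TASK_DEFS: dict[str, tuple] = {
    "impairment": (("CU", "MCI", "Dem"), ("MCI", "Dem"), ("MCI", "Dem")),
    "dementia": (("CU", "MCI", "Dem"), ("Dem",), ("Dem",)),
    "cu_vs_mci": (("CU", "MCI"), ("MCI",), ("MCI", "Dem")),
    "mci_vs_dem": (("MCI", "Dem"), ("Dem",), ("Dem",)),
}


def confusion_matrix(true_labels: Sequence[str], pred_labels: Sequence[str]) -> np.ndarray:
    """3x3 counts: rows = gold-standard diagnosis, columns = predicted
    cluster group, both ordered (CU, MCI, Dem)."""
    M = np.zeros((3, 3), dtype=int)
    for t, p in zip(true_labels, pred_labels, strict=True):
        if t not in _CLASS_INDEX or p not in _CLASS_INDEX:
            raise ValueError(f"labels must be in {DIAGNOSIS_CLASSES}, got ({t!r}, {p!r})")
        M[_CLASS_INDEX[t], _CLASS_INDEX[p]] += 1
    return M


def _clopper_pearson(k: int, n: int, level: float) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
    return float(lo), float(hi)


def accuracy_with_ci(confusion: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Overall accuracy (trace / N) with an exact Clopper-Pearson interval."""
    confusion = np.asarray(confusion)
    n = int(confusion.sum())
    if n < 1:
        raise ValueError("confusion matrix is empty")
    k = int(np.trace(confusion))
    lo, hi = _clopper_pearson(k, n, level)
    return k / n, lo, hi


@dataclass(frozen=True)
class _Proportion:
    """A proportion with its exact binomial interval; undefined when the
    denominator is empty (flagged, not coerced to 0 or 1)."""

    numerator: int
    denominator: int
    point: float
    lower: float
    upper: float
    defined: bool

    def to_json(self) -> dict:
        return {
            "numerator": self.numerator,
            "denominator": self.denominator,
            "point": None if not self.defined else self.point,
            "lower": None if not self.defined else self.lower,
            "upper": None if not self.defined else self.upper,
            "defined": self.defined,
        }


def _proportion(k: int, n: int, level: float) -> _Proportion:
    if n == 0:
        return _Proportion(0, 0, math.nan, math.nan, math.nan, False)
    lo, hi = _clopper_pearson(k, n, level)
    return _Proportion(int(k), int(n), k / n, lo, hi, True)


@dataclass(frozen=True)
class BinaryTaskMetrics:
    task: str
    sensitivity: _Proportion
    specificity: _Proportion
    ppv: _Proportion
    npv: _Proportion

    def to_json(self) -> dict:
        return {
            "task": self.task,
            **{
                name: getattr(self, name).to_json()
                for name in ("sensitivity", "specificity", "ppv", "npv")
            },
        }


def binary_task_metrics(
    confusion: np.ndarray | None = None,
    task: str = "impairment",
    *,
    truth: np.ndarray | None = None,
    decisions: np.ndarray | None = None,
    level: float = 0.95,
) -> BinaryTaskMetrics:
    """Sensitivity / specificity / PPV / NPV with Clopper-Pearson intervals.

    Either pass a 3x3 argmax ``confusion`` matrix — the task then restricts
    to its diagnosis rows and pools its positive predicted columns — or
    pass explicit boolean ``truth`` / ``decisions`` vectors (already
    restricted to the task's subset).
    """
    if task not in _TASK_DEFS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    if (confusion is None) == (truth is None or decisions is None):
        raise ValueError("pass exactly one of confusion or (truth, decisions)")
    if confusion is not None:
        rows, pos_rows, pos_cols = _TASK_DEFS[task]
        M = np.asarray(confusion)
        r_idx = [_CLASS_INDEX[c] for c in rows]
        pr = [_CLASS_INDEX[c] for c in pos_rows]
        pc = [_CLASS_INDEX[c] for c in pos_cols]
        tp = int(M[np.ix_(pr, pc)].sum())
        fn = int(M[pr].sum() - tp)
        neg_rows = [i for i in r_idx if i not in pr]
        fp = int(M[np.ix_(neg_rows, pc)].sum())
        tn = int(M[neg_rows].sum() - fp)
    else:
        truth = np.asarray(truth, dtype=bool)
        decisions = np.asarray(decisions, dtype=bool)
        tp = int(np.sum(truth & decisions))
        fn = int(np.sum(truth & ~decisions))
        fp = int(np.sum(~truth & decisions))
        tn = int(np.sum(~truth & ~decisions))
    return BinaryTaskMetrics(
        task=task,
        sensitivity=_proportion(tp, tp + fn, level),
        specificity=_proportion(tn, tn + fp, level),
        ppv=_proportion(tp, tp + fp, level),
        npv=_proportion(tn, tn + fn, level),
    )


def auroc(scores, labels) -> float:
    """Area under the ROC curve as the Mann-Whitney probability: the chance
    a random positive outscores a random negative, with half credit for
    ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def bca_bootstrap_ci(
    data,
    statistic: Callable,
    B: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Nonparametric BCa bootstrap interval for ``statistic(sample)``.

    The bias correction comes from the share of bootstrap replicates below
    the observed statistic and the acceleration from jackknife skewness; a
    statistic that is constant over resamples collapses to a point interval
    with a warning.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    data = np.asarray(data)
    obs = float(statistic(data))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on degenerate BCa inputs
        try:
            res = _scipy_bootstrap(
                (data,),
                lambda x, axis=-1: np.asarray(statistic(np.asarray(x)))
                if np.ndim(x) == 1
                else np.apply_along_axis(statistic, axis, x),
                n_resamples=B,
                confidence_level=level,
                method="BCa",
                vectorized=True,
                rng=np.random.default_rng(seed),
            )
        except Exception:
            res = None
    if res is None or not np.isfinite(res.confidence_interval.low) or not np.isfinite(
        res.confidence_interval.high
    ):
        warnings.warn(
            "degenerate bootstrap distribution; collapsing to a point interval",
            RuntimeWarning,
        )
        return obs, obs
    return float(res.confidence_interval.low), float(res.confidence_interval.high)


def auroc_with_ci(
    scores, labels, B: int = 10_000, seed: int = 0, level: float = 0.95
) -> tuple[float, float, float]:
    """AUROC with a BCa bootstrap interval, resampling positives and
    negatives separately (stratified, so every resample has both classes)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    point = auroc(scores, labels)
    pos, neg = scores[labels], scores[~labels]

    def stat(p, n):
        s = np.concatenate([p, n])
        lab = np.concatenate([np.ones(len(p), bool), np.zeros(len(n), bool)])
        return auroc(s, lab)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = _scipy_bootstrap(
                (pos, neg),
                stat,
                n_resamples=B,
                confidence_level=level,
                method="BCa",
                vectorized=False,
                paired=False,
                rng=np.random.default_rng(seed),
            )
            lo = float(res.confidence_interval.low)
            hi = float(res.confidence_interval.high)
        except Exception:
            lo = hi = math.nan
    if not (np.isfinite(lo) and np.isfinite(hi)):
        warnings.warn(
            "degenerate AUROC bootstrap; collapsing to a point interval",
            RuntimeWarning,
        )
        lo = hi = point
    return point, lo, hi


@dataclass(frozen=True)
class ClassificationReport:
    """3-class confusion matrix plus per-task metrics and AUROCs."""

    confusion: np.ndarray
    accuracy: tuple
    tasks: Mapping[str, BinaryTaskMetrics]
    aurocs: Mapping[str, tuple] = field(default_factory=dict)  # task -> (pt, lo, hi)
    b: int = 0
    seed: int = 0

    def to_json(self) -> dict:
        return {
            "confusion": np.asarray(self.confusion).tolist(),
            "classes": list(DIAGNOSIS_CLASSES),
            "accuracy": {
                "point": self.accuracy[0],
                "lower": self.accuracy[1],
                "upper": self.accuracy[2],
            },
            "tasks": {t: m.to_json() for t, m in self.tasks.items()},
            "aurocs": {
                t: {"point": v[0], "lower": v[1], "upper": v[2]}
                for t, v in self.aurocs.items()
            },
            "B": self.b,
            "seed": self.seed,
        }

    def to_table(self) -> str:
        lines = ["confusion (rows=diagnosis, cols=predicted; CU/MCI/Dem):"]
        for c, row in zip(DIAGNOSIS_CLASSES, np.asarray(self.confusion)):
            lines.append(f"  {c:>4} {row.tolist()}")
        a = self.accuracy
        lines.append(f"accuracy {a[0]:.3f} [{a[1]:.3f}, {a[2]:.3f}]")
        for t, m in self.tasks.items():
            parts = []
            for name in ("sensitivity", "specificity", "ppv", "npv"):
                pr = getattr(m, name)
                parts.append(
                    f"{name} --" if not pr.defined
                    else f"{name} {pr.point:.3f} [{pr.lower:.3f}, {pr.upper:.3f}]"
                )
            if t in self.aurocs:
                pt, lo, hi = self.aurocs[t]
                parts.append(
                    "auroc --" if not np.isfinite(pt)
                    else f"auroc {pt:.3f} [{lo:.3f}, {hi:.3f}]"
                )
            lines.append(f"{t}: " + "  ".join(parts))
        return "\n".join(lines)


def report_from_confusion(confusion: np.ndarray, level: float = 0.95) -> ClassificationReport:
    """Evaluation driven by a 3-class argmax confusion matrix alone
    (no probability scores, hence no AUROCs)."""
    return ClassificationReport(
        confusion=np.asarray(confusion),
        accuracy=accuracy_with_ci(confusion, level),
        tasks={t: binary_task_metrics(confusion, t, level=level) for t in TASKS},
    )


def evaluate_posteriors(
    true_labels: Sequence[str],
    p3: np.ndarray,
    *,
    B: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
) -> ClassificationReport:
    """Full predictive-validity report from collapsed posterior rows.

    The 3-class confusion matrix uses the argmax rule; each binary task
    thresholds its summed (conditional tasks: renormalized) probability at
    0.5, restricted to the task's diagnosis subset; AUROCs score each task
    by the same probabilities with stratified BCa intervals.  Tasks whose
    subset misses a class get an undefined (flagged) AUROC.
    """
    from .mixture import classify  # local import to avoid a cycle at import time

    true_labels = list(true_labels)
    p3 = np.atleast_2d(np.asarray(p3, dtype=float))
    pred3 = classify(p3)
    M = confusion_matrix(true_labels, pred3)
    tasks: dict[str, BinaryTaskMetrics] = {}
    aurocs: dict[str, tuple] = {}
    t_arr = np.asarray(true_labels)
    for t in TASKS:
        rows, pos_rows, _ = _TASK_DEFS[t]
        mask = np.isin(t_arr, rows)
        truth = np.isin(t_arr[mask], pos_rows)
        scores = task_scores(p3[mask], t)
        decisions = scores > 0.5
        tasks[t] = binary_task_metrics(task=t, truth=truth, decisions=decisions, level=level)
        if truth.all() or not truth.any():
            aurocs[t] = (math.nan, math.nan, math.nan)
        else:
            aurocs[t] = auroc_with_ci(scores, truth, B=B, seed=seed, level=level)
    return ClassificationReport(
        confusion=M,
        accuracy=accuracy_with_ci(M, level),
        tasks=tasks,
        aurocs=aurocs,
        b=B,
        seed=seed,
    )


def holdout_fixture() -> tuple[list, list]:
    """The packaged held-out diagnosis/prediction pairs (N=75) as two label
    lists (true diagnosis, predicted group)."""
    ref = importlib.resources.files("cogmix").joinpath("data/holdout_confusion_pairs.csv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return df["diagnosis"].tolist(), df["predicted"].tolist()
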