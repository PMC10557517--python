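"""External evaluation of clusterings and the method benchmark harness.

Cluster indices carry no meaning relative to grade labels, so accuracy is
computed after finding the one-to-one cluster-to-grade correspondence that
maximizes agreement (Hungarian assignment on the contingency table) — the
standard external clustering accuracy.  The benchmark runs each method over
the same seed list on the same cohort (paired comparison) and reports per-run
rows plus per-method medians.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .clustering import ClusteringResult, KMeansConfig, fwa_kmeans, kmeans, kmeanspp_init
from .fwa import FWAConfig
from .synthetic_cohort import LabeledCohort

__all__ = [
    "EvaluationError",
    "EvaluationReport",
    "match_accuracy",
    "benchmark",
    "register_method",
    "run_method",
    "METHOD_NAMES",
]


class EvaluationError(ValueError):
    """Invalid input for an evaluation operation."""


def match_accuracy(predicted, true_labels) -> float:
    """Hungarian-matched clustering accuracy in [0, 1].

    Builds the cluster x grade contingency table, finds the one-to-one
    matching maximizing total agreement (rectangular tables are handled by the
    assignment solver directly), and returns matched agreement / n.  Invariant
    under any bijective relabeling of clusters or grades.
    """
    pred = np.asarray(predicted).ravel()
    true = np.asarray(true_labels).ravel()
    if pred.size != true.size:
        raise EvaluationError(f"length mismatch: {pred.size} predicted vs {true.size} true")
    if pred.size == 0:
        raise EvaluationError("at least one sample is required")
    _, pi = np.unique(pred, return_inverse=True)
    _, ti = np.unique(true, return_inverse=True)
    table = np.zeros((pi.max() + 1, ti.max() + 1), dtype=int)
    np.add.at(table, (pi, ti), 1)
    rows, cols = linear_sum_assignment(table, maximize=True)
    return float(table[rows, cols].sum()) / pred.size


def _kmeans_random(data, K, seed, fwa_config, kmeans_config) -> ClusteringResult:
    rng = np.random.default_rng(seed)
    idx = rng.choice(data.shape[0], size=K, replace=False)
    return kmeans(data, replace(kmeans_config, seed=seed), data[idx])


def _kmeans_pp(data, K, seed, fwa_config, kmeans_config) -> ClusteringResult:
    rng = np.random.default_rng(seed)
    init = kmeanspp_init(data, K, rng)
    return kmeans(data, replace(kmeans_config, seed=seed), init)


def _fwa_kmeans(data, K, seed, fwa_config, kmeans_config) -> ClusteringResult:
    return fwa_kmeans(
        data, K,
        fwa_config=replace(fwa_config, seed=seed),
        kmeans_config=replace(kmeans_config, seed=seed),
    )


_METHODS: Dict[str, Callable] = {
    "kmeans_random": _kmeans_random,
    "kmeans_pp": _kmeans_pp,
    "fwa_kmeans": _fwa_kmeans,
}

METHOD_NAMES = tuple(_METHODS)


def register_method(name: str, fn: Callable) -> None:
    """Register an external clustering method for the benchmark harness.

    ``fn(data, K, seed, fwa_config, kmeans_config) -> ClusteringResult``.
    """
    _METHODS[name] = fn


def run_method(
    name: str,
    data: np.ndarray,
    K: int,
    seed: int,
    fwa_config: Optional[FWAConfig] = None,
    kmeans_config: Optional[KMeansConfig] = None,
) -> ClusteringResult:
    """Run one registered clustering method with an explicit seed."""
    if name not in _METHODS:
        raise EvaluationError(f"unknown method {name!r}; known: {sorted(_METHODS)}")
    if fwa_config is None:
        fwa_config = FWAConfig()
    if kmeans_config is None:
        kmeans_config = KMeansConfig(K=K)
    return _METHODS[name](np.asarray(data, dtype=float), K, seed, fwa_config, kmeans_config)


@dataclass
class EvaluationReport:
    """Per-run benchmark rows plus per-method medians.

    Every row satisfies ``error_rate = 1 - accuracy`` exactly.
    """

    rows: List[dict] = field(default_factory=list)
    summary: Dict[str, dict] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["method", "seed", "accuracy", "error_rate", "loss", "iterations"],
        )

    def to_dict(self) -> dict:
        return {"rows": self.rows, "summary": self.summary}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, lineterminator="\n")


def benchmark(
    cohort: LabeledCohort,
    K: int = 4,
    methods: Sequence[str] = METHOD_NAMES,
    n_seeds: int = 20,
    fwa_config: Optional[FWAConfig] = None,
    kmeans_config: Optional[KMeansConfig] = None,
) -> EvaluationReport:
    """Paired-seed comparison of clustering methods on one labeled cohort.

    Each method runs with seeds ``0 .. n_seeds-1`` on the identical cohort;
    rows record accuracy (Hungarian-matched against the true grades), error
    rate, final SSE loss, and iterations; the summary holds per-method median
    accuracy, error rate, and loss.
    """
    if not cohort.has_labels:
        raise EvaluationError("benchmark requires a labeled cohort")
    if n_seeds < 1:
        raise EvaluationError("n_seeds must be >= 1")
    for m in methods:
        if m not in _METHODS:
            raise EvaluationError(f"unknown method {m!r}; known: {sorted(_METHODS)}")
    if fwa_config is None:
        fwa_config = FWAConfig()
    if kmeans_config is None:
        kmeans_config = KMeansConfig(K=K)
    data = cohort.scores_matrix()
    true = cohort.grade_values()

    report = EvaluationReport()
    for method in methods:
        accs, losses = [], []
        for seed in range(n_seeds):
            result = run_method(method, data, K, seed, fwa_config, kmeans_config)
            acc = match_accuracy(result.labels, true)
            accs.append(acc)
            losses.append(result.loss)
            report.rows.append({
                "method": method,
                "seed": seed,
                "accuracy": acc,
                "error_rate": 1.0 - acc,
                "loss": result.loss,
                "iterations": result.iterations_run,
            })
        report.summary[method] = {
            "median_accuracy": float(np.median(accs)),
            "median_error_rate": 1.0 - float(np.median(accs)),
            "median_loss": float(np.median(losses)),
            "n_seeds": n_seeds,
        }
    return report
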