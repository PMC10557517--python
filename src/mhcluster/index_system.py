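"""Mental-health evaluation index layer.

Students are scored on a set of indicators, each on a 0–10 scale with a
three-band reading (``normal`` >= 8, ``average`` in [3, 8), ``obstacle`` < 3).
One indicator quantifies *temporal perception* — a person's untimed judgment
of duration — from duration-estimation trials.  The final outcome is one of
four mental-health grades (normal, mild / moderate / severe anxiety), assigned
by clustering the indicator profiles and ordering the clusters by mean score.

The indicator list is configuration data, not hard-coded: see
:func:`default_indicators` for the shipped default of ten indicators (nine
conventional plus temporal perception).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import yaml

__all__ = [
    "IndexSystemError",
    "IndicatorCategory",
    "IndicatorDefinition",
    "IndicatorLevel",
    "MHGrade",
    "default_indicators",
    "indicators_to_yaml",
    "indicators_from_yaml",
    "indicator_level",
    "quantify_temporal_perception",
    "map_clusters_to_grades",
]


class IndexSystemError(ValueError):
    """Invalid input for an index-system operation."""


class IndicatorCategory(str, enum.Enum):
    CONVENTIONAL = "conventional"
    TEMPORAL_PERCEPTION = "temporal_perception"


@dataclass(frozen=True)
class IndicatorDefinition:
    """One indicator of the evaluation system (name + category)."""

    name: str
    category: IndicatorCategory = IndicatorCategory.CONVENTIONAL


class IndicatorLevel(str, enum.Enum):
    """Three-band reading of a single 0–10 indicator score."""

    NORMAL = "normal"
    AVERAGE = "average"
    OBSTACLE = "obstacle"


class MHGrade(str, enum.Enum):
    """The four final mental-health grades, ordered by severity."""

    NORMAL = "normal"
    MILD_ANXIETY = "mild_anxiety"
    MODERATE_ANXIETY = "moderate_anxiety"
    SEVERE_ANXIETY = "severe_anxiety"


#: Grades in severity order, used when mapping score-ordered clusters.
GRADES_BY_SEVERITY = (
    MHGrade.NORMAL,
    MHGrade.MILD_ANXIETY,
    MHGrade.MODERATE_ANXIETY,
    MHGrade.SEVERE_ANXIETY,
)


def default_indicators() -> List[IndicatorDefinition]:
    """The shipped default index: nine conventional indicators plus one
    temporal-perception indicator, all scored 0–10."""
    conventional = [
        "emotional_stability",
        "sleep_quality",
        "academic_stress",
        "social_adaptation",
        "self_esteem",
        "family_support",
        "physical_condition",
        "interpersonal_trust",
        "future_outlook",
    ]
    defs = [IndicatorDefinition(n, IndicatorCategory.CONVENTIONAL) for n in conventional]
    defs.append(
        IndicatorDefinition("temporal_perception", IndicatorCategory.TEMPORAL_PERCEPTION)
    )
    return defs


def indicators_to_yaml(indicators: Sequence[IndicatorDefinition]) -> str:
    return yaml.safe_dump(
        [{"name": d.name, "category": d.category.value} for d in indicators],
        sort_keys=True,
    )


def indicators_from_yaml(text: str) -> List[IndicatorDefinition]:
    raw = yaml.safe_load(text)
    defs = [
        IndicatorDefinition(item["name"], IndicatorCategory(item["category"]))
        for item in raw
    ]
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise IndexSystemError("indicator names must be unique")
    return defs


def indicator_level(score: float) -> IndicatorLevel:
    """Three-band reading of one 0–10 score: >= 8 normal, < 3 obstacle,
    otherwise average (so [3, 8) is average and reals leave no gap)."""
    s = float(score)
    if not (0.0 <= s <= 10.0):
        raise IndexSystemError(f"score {s} outside the [0, 10] scale")
    if s >= 8.0:
        return IndicatorLevel.NORMAL
    if s < 3.0:
        return IndicatorLevel.OBSTACLE
    return IndicatorLevel.AVERAGE


def quantify_temporal_perception(
    estimated_durations,
    true_durations,
    max_relative_error: float = 1.0,
) -> float:
    """Turn duration-estimation trials into a 0–10 indicator score.

    Per trial the relative error ``|estimated - true| / true`` is computed;
    the trials are aggregated by the median (robust to single wild trials);
    the score is a linear ramp ``10 * max(0, 1 - E / max_relative_error)``, so
    perfect estimation scores 10 and a median error at or beyond
    ``max_relative_error`` scores 0.
    """
    est = np.asarray(estimated_durations, dtype=float).ravel()
    true = np.asarray(true_durations, dtype=float).ravel()
    if est.size != true.size:
        raise IndexSystemError(
            f"trial count mismatch: {est.size} estimates vs {true.size} true durations"
        )
    if est.size < 1:
        raise IndexSystemError("at least one trial is required")
    if np.any(true <= 0):
        raise IndexSystemError("true durations must be strictly positive")
    if max_relative_error <= 0:
        raise IndexSystemError("max_relative_error must be positive")
    errors = np.abs(est - true) / true
    aggregate = float(np.median(errors))
    return 10.0 * max(0.0, 1.0 - aggregate / max_relative_error)


def map_clusters_to_grades(result, data) -> Dict[int, MHGrade]:
    """Assign the four grades to the four clusters of a clustering result.

    Clusters are ordered by descending mean indicator score over their members
    (higher scores = healthier on the 0–10 convention) and receive normal,
    mild, moderate, severe anxiety in that order; ties break by cluster index.
    """
    K = int(result.centroids.shape[0])
    if K != 4:
        raise IndexSystemError(
            f"grade mapping requires exactly 4 clusters, got K={K}; "
            "supply a custom cluster-to-grade mapping for other K"
        )
    X = np.asarray(data, dtype=float)
    labels = np.asarray(result.labels, dtype=int)
    means = np.empty(K)
    for k in range(K):
        members = X[labels == k]
        # an empty cluster ranks by its centroid so the mapping stays total
        means[k] = members.mean() if members.size else float(np.mean(result.centroids[k]))
    order = sorted(range(K), key=lambda k: (-means[k], k))
    return {cluster: GRADES_BY_SEVERITY[rank] for rank, cluster in enumerate(order)}
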