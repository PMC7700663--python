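"""Rule-based mild/severe tremor scoring.

Each rule thresholds a subset of the kinematic features and awards one
point per feature at or above its threshold:

* ET rule — histogram feature, vertical swing, average travel distance;
  total >= 2 points means severe.
* CD rule — RMSD plus the same three; total >= 3 points means severe.

Threshold values are cohort-dependent (there is no universal set of
numbers), so :func:`calibrate_thresholds` derives them from a small
labeled training set by a reproducible midpoint rule, and results always
carry the thresholds that produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .features import FeatureVector

__all__ = [
    "ET_FEATURES",
    "CD_FEATURES",
    "SeverityThresholds",
    "SeverityResult",
    "score_et",
    "score_cd",
    "score",
    "calibrate_thresholds",
]

ET_FEATURES = ("histogram_feature", "angular", "avg_travel_distance")
CD_FEATURES = ("rmsd", "histogram_feature", "angular", "avg_travel_distance")
ET_SEVERE_POINTS = 2
CD_SEVERE_POINTS = 3


@dataclass(frozen=True)
class SeverityThresholds:
    """Per-feature cutoffs for the ET and CD scoring rules.

    ``angular_uses`` selects whether the angular feature is entered as the
    raw swing count or the per-step fraction.
    """

    et: dict = field(default_factory=dict)
    cd: dict = field(default_factory=dict)
    angular_uses: str = "count"  # "count" | "fraction"

    def __post_init__(self) -> None:
        for rule, names in (("et", ET_FEATURES), ("cd", CD_FEATURES)):
            table = getattr(self, rule)
            for name, v in table.items():
                if name not in names:
                    raise ValueError(f"unknown {rule} feature {name!r}")
                if not np.isfinite(v) or v <= 0:
                    raise ValueError(f"threshold for {name} must be finite and > 0")
        if self.angular_uses not in ("count", "fraction"):
            raise ValueError("angular_uses must be 'count' or 'fraction'")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "et": {k: float(v) for k, v in self.et.items()},
                    "cd": {k: float(v) for k, v in self.cd.items()},
                    "angular_uses": self.angular_uses,
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "SeverityThresholds":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(
            et=data.get("et", {}),
            cd=data.get("cd", {}),
            angular_uses=data.get("angular_uses", "count"),
        )


@dataclass(frozen=True)
class SeverityResult:
    """Outcome of one scoring: per-feature points, total, verdict."""

    points: dict
    total: int
    verdict: str  # "mild" | "severe"
    rule: str  # "et" | "cd"
    thresholds: SeverityThresholds | None = None

    def __post_init__(self) -> None:
        if self.total != sum(self.points.values()):
            raise ValueError("total must equal the sum of points")


def _feature_value(fv: FeatureVector, name: str, angular_uses: str) -> float:
    if name == "angular":
        return (
            fv.vertical_swing_count
            if angular_uses == "count"
            else fv.vertical_swing_fraction
        )
    return fv.get(name)


def _score(fv: FeatureVector, th: SeverityThresholds, rule: str) -> SeverityResult:
    names = ET_FEATURES if rule == "et" else CD_FEATURES
    cutoff = ET_SEVERE_POINTS if rule == "et" else CD_SEVERE_POINTS
    table = getattr(th, rule)
    missing = [n for n in names if n not in table]
    if missing:
        raise ValueError(f"{rule} thresholds missing features: {missing}")
    points = {}
    for name in names:
        value = _feature_value(fv, name, th.angular_uses)
        # A value exactly at the threshold scores the point.
        points[name] = int(value >= table[name])
    total = sum(points.values())
    return SeverityResult(
        points=points,
        total=total,
        verdict="severe" if total >= cutoff else "mild",
        rule=rule,
        thresholds=th,
    )


def score_et(fv: FeatureVector, th: SeverityThresholds) -> SeverityResult:
    """ET rule: 1 point each for histogram, angular and travel-distance
    features at/above threshold; 2 or more points means severe."""
    return _score(fv, th, "et")


def score_cd(fv: FeatureVector, th: SeverityThresholds) -> SeverityResult:
    """CD rule: 1 point each for RMSD, histogram, angular and
    travel-distance features at/above threshold; 3 or more means severe."""
    return _score(fv, th, "cd")


def score(fv: FeatureVector, th: SeverityThresholds, rule: str) -> SeverityResult:
    if rule not in ("et", "cd"):
        raise ValueError("rule must be 'et' or 'cd'")
    return score_et(fv, th) if rule == "et" else score_cd(fv, th)


def calibrate_thresholds(
    feature_vectors: list[FeatureVector],
    severity_labels: list[str],
    rule: str,
    angular_uses: str = "count",
) -> SeverityThresholds:
    """Derive per-feature cutoffs from a labeled training set.

    For each feature the threshold is the midpoint between the mild-group
    maximum and the severe-group minimum; when the groups overlap (the
    midpoint would not separate them) the pooled median is used instead.
    Deterministic; needs at least one mild and one severe example.
    """
    if rule not in ("et", "cd"):
        raise ValueError("rule must be 'et' or 'cd'")
    labels = np.asarray(severity_labels)
    mild = labels == "mild"
    severe = labels == "severe"
    if not mild.any() or not severe.any():
        raise ValueError("calibration needs both mild and severe examples")
    names = ET_FEATURES if rule == "et" else CD_FEATURES
    table = {}
    for name in names:
        vals = np.array(
            [_feature_value(fv, name, angular_uses) for fv in feature_vectors],
            dtype=np.float64,
        )
        mild_max = vals[mild].max()
        severe_min = vals[severe].min()
        if mild_max < severe_min:
            t = 0.5 * (mild_max + severe_min)
        else:
            t = float(np.median(vals))
        # Thresholds must be positive to be meaningful point cutoffs.
        table[name] = max(t, np.finfo(float).tiny)
    kwargs = {rule: table, "angular_uses": angular_uses}
    return SeverityThresholds(**kwargs)
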