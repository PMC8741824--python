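"""Scoring detections against ground truth and aggregating trial results.

Recall is the fraction of truly present weeds that were detected
(TP / total weeds); precision is the fraction of detections that were
correct (TP / (TP + FP)). Matching between detections and ground-truth
weed centres is greedy nearest-centroid within a pixel tolerance, each
ground-truth weed usable at most once, so extra detections on the same
weed count as false positives.

The package ships the precision/recall table and the site summaries of a
seven-transect fallow field trial (five daylight, two artificially lit
night transects, four algorithms) as reference data;
:func:`load_field_performance` / :func:`load_field_sites` return them and
:func:`aggregate` reproduces the trial's summary statistics from any such
table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pipeline import Detection

__all__ = [
    "GroundTruth",
    "GroundTruthSet",
    "EvalResult",
    "AggregateSummary",
    "match_detections",
    "precision_recall",
    "weed_density",
    "aggregate",
    "load_field_performance",
    "load_field_sites",
    "load_ground_truth",
]


@dataclass(frozen=True)
class GroundTruth:
    """One annotated weed: an id, its centre, optionally frame and species."""

    id: int
    centroid: tuple[float, float]
    frame: int | None = None
    species: str | None = None


@dataclass(frozen=True)
class GroundTruthSet:
    annotations: tuple[GroundTruth, ...]

    def __post_init__(self) -> None:
        ids = [a.id for a in self.annotations]
        if len(set(ids)) != len(ids):
            raise ValueError("ground-truth ids must be unique")

    @property
    def total_weeds(self) -> int:
        return len(self.annotations)


@dataclass(frozen=True)
class EvalResult:
    """Precision/recall outcome for one transect × algorithm.

    ``precision`` is None (undefined, reported as "n/a") when there were no
    detections at all; ``recall`` is None when no weeds were present.
    """

    true_positives: int
    false_positives: int
    total_weeds: int
    precision: float | None
    recall: float | None

    def as_row(self) -> dict:
        fmt = lambda v: "n/a" if v is None else f"{100 * v:.1f}"
        return {
            "tp": self.true_positives,
            "fp": self.false_positives,
            "total_weeds": self.total_weeds,
            "precision_pct": fmt(self.precision),
            "recall_pct": fmt(self.recall),
        }


def match_detections(
    detections: Sequence[Detection],
    truth: GroundTruthSet,
    tolerance: float = 50.0,
) -> tuple[int, int]:
    """Greedy nearest-centroid matching; returns (TP, FP).

    All detection/truth pairs within ``tolerance`` pixels are sorted by
    distance (ties broken by ids) and assigned one-to-one, so the result is
    invariant to the input order of either list. A detection with no truth
    within tolerance, or arriving after its weed is taken, is a false
    positive; multiple detections on one weed yield one TP plus FPs.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    pairs = []
    for i, det in enumerate(sorted(detections, key=lambda d: (d.centroid[1], d.centroid[0]))):
        for ann in truth.annotations:
            d = math.dist(det.centroid, ann.centroid)
            if d <= tolerance:
                pairs.append((d, i, ann.id))
    pairs.sort()
    used_det: set[int] = set()
    used_truth: set[int] = set()
    tp = 0
    for _, i, tid in pairs:
        if i in used_det or tid in used_truth:
            continue
        used_det.add(i)
        used_truth.add(tid)
        tp += 1
    return tp, len(detections) - tp


def precision_recall(tp: int, fp: int, total_weeds: int) -> EvalResult:
    """Build an :class:`EvalResult` from raw counts.

    precision = TP / (TP + FP), recall = TP / total weeds present.
    """
    if min(tp, fp, total_weeds) < 0:
        raise ValueError("counts must be non-negative")
    if tp > total_weeds:
        raise ValueError("true positives cannot exceed the weeds present")
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / total_weeds if total_weeds > 0 else None
    return EvalResult(tp, fp, total_weeds, precision, recall)


def weed_density(total_weeds: int, transect_length: float, fov_width: float) -> float:
    """Weeds per square metre over a transect of length × FOV-width area."""
    area = transect_length * fov_width
    if area <= 0:
        raise ValueError("transect area must be positive")
    return total_weeds / area


@dataclass(frozen=True)
class AggregateSummary:
    """Trial-level summary statistics of a precision/recall table (in %)."""

    mean_precision: float
    sem_precision: float
    mean_recall: float
    sem_recall: float
    median_precision_by_algorithm: dict[str, float]
    median_recall_by_algorithm: dict[str, float]
    mean_precision_by_field: dict[str, float]
    sem_precision_by_field: dict[str, float]
    mean_recall_by_field: dict[str, float]
    sem_recall_by_field: dict[str, float]


def _sem(values: pd.Series) -> float:
    values = values.dropna()
    if len(values) < 2:
        return float("nan")
    return float(values.std(ddof=1) / math.sqrt(len(values)))


def aggregate(table: pd.DataFrame) -> AggregateSummary:
    """Summarise a (field, algorithm) precision/recall table.

    Expects columns ``field``, ``algorithm``, ``precision_pct``,
    ``recall_pct`` with percentages in [0, 100]; missing cells (transects
    where an algorithm produced no usable output) are NaN and are excluded
    from every statistic. Means are over all present cells, medians are per
    algorithm across fields, and per-field means are across algorithms;
    standard errors (sd/√n, ddof = 1) accompany every mean.
    """
    required = {"field", "algorithm", "precision_pct", "recall_pct"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if table.empty:
        raise ValueError("cannot aggregate an empty table")
    prec, rec = table["precision_pct"], table["recall_pct"]
    by_alg = table.groupby("algorithm")
    by_field = table.groupby("field")
    return AggregateSummary(
        mean_precision=float(prec.mean()),
        sem_precision=_sem(prec),
        mean_recall=float(rec.mean()),
        sem_recall=_sem(rec),
        median_precision_by_algorithm=by_alg["precision_pct"].median().to_dict(),
        median_recall_by_algorithm=by_alg["recall_pct"].median().to_dict(),
        mean_precision_by_field=by_field["precision_pct"].mean().to_dict(),
        sem_precision_by_field=by_field["precision_pct"].apply(_sem).to_dict(),
        mean_recall_by_field=by_field["recall_pct"].mean().to_dict(),
        sem_recall_by_field=by_field["recall_pct"].apply(_sem).to_dict(),
    )


def _data_path(name: str):
    return resources.files("weedscan.data").joinpath(name)


def load_field_performance() -> pd.DataFrame:
    """Bundled per-transect precision/recall results of the field trial."""
    with resources.as_file(_data_path("field_performance.csv")) as path:
        return pd.read_csv(path)


def load_field_sites() -> pd.DataFrame:
    """Bundled site summaries (background, weed density, transect geometry)."""
    with resources.as_file(_data_path("field_sites.csv")) as path:
        return pd.read_csv(path)


def load_ground_truth(path: str | Path) -> GroundTruthSet:
    """Read ground truth from CSV (id,frame,cx,cy[,species]) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if isinstance(records, dict):
            records = records.get("annotations", [])
    else:
        df = pd.read_csv(path)
        missing = {"id", "cx", "cy"} - set(df.columns)
        if missing:
            raise ValueError(
                f"ground-truth file {path} is missing column(s) {sorted(missing)}"
            )
        records = df.to_dict("records")
    annotations = tuple(
        GroundTruth(
            id=int(r["id"]),
            centroid=(float(r["cx"]), float(r["cy"])),
            frame=None if pd.isna(r.get("frame", None)) else int(r["frame"]),
            species=r.get("species") if isinstance(r.get("species"), str) else None,
        )
        for r in records
    )
    return GroundTruthSet(annotations)
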