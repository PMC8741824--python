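"""Tests for detection scoring, density arithmetic and trial aggregation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from weedscan import (
    Detection,
    GroundTruth,
    GroundTruthSet,
    aggregate,
    load_field_performance,
    load_field_sites,
    match_detections,
    precision_recall,
    weed_density,
)


def det(cx, cy):
    return Detection(bbox=(int(cx), int(cy), 2, 2), centroid=(cx, cy), area=4)


def truth_at(*centres):
    return GroundTruthSet(tuple(
        GroundTruth(id=i, centroid=c) for i, c in enumerate(centres)
    ))


def optimal_matching(detections, truth, tolerance):
    """Brute-force maximum one-to-one matching (oracle for small layouts).

    Enumerates every injective assignment from the smaller side to the
    larger, so it is exact for the toy sizes used here.
    """
    anns = truth.annotations
    if len(detections) >= len(anns):
        small = [a.centroid for a in anns]
        large = [d.centroid for d in detections]
    else:
        small = [d.centroid for d in detections]
        large = [a.centroid for a in anns]
    best = 0
    for perm in itertools.permutations(range(len(large)), len(small)):
        tp = sum(
            1 for s, li in zip(small, perm)
            if math.dist(s, large[li]) <= tolerance
        )
        best = max(best, tp)
    return best


class TestMatching:
    def test_no_detections(self):
        assert match_detections([], truth_at((10, 10))) == (0, 0)

    def test_exact_hit(self):
        assert match_detections([det(10, 10)], truth_at((10, 10))) == (1, 0)

    def test_multiple_detections_on_one_weed(self):
        dets = [det(10, 10), det(12, 10), det(10, 13)]
        truth = truth_at((10, 10))
        assert match_detections(dets, truth) == (1, 2)
        assert optimal_matching(dets, truth, 50.0) == 1

    def test_far_detection_is_false_positive(self):
        assert match_detections([det(300, 300)], truth_at((10, 10))) == (0, 1)

    def test_order_invariance(self, rng):
        dets = [det(float(x), float(y))
                for x, y in rng.integers(0, 200, size=(8, 2))]
        truth = truth_at(*(tuple(map(float, c))
                           for c in rng.integers(0, 200, size=(5, 2))))
        reference = match_detections(dets, truth, tolerance=30.0)
        for _ in range(5):
            shuffled = list(dets)
            rng.shuffle(shuffled)
            assert match_detections(shuffled, truth, tolerance=30.0) == reference

    def test_greedy_agrees_with_optimal_on_small_layouts(self, rng):
        for _ in range(10):
            dets = [det(float(x), float(y))
                    for x, y in rng.integers(0, 100, size=(4, 2))]
            truth = truth_at(*(tuple(map(float, c))
                               for c in rng.integers(0, 100, size=(3, 2))))
            tp, fp = match_detections(dets, truth, tolerance=40.0)
            assert tp <= optimal_matching(dets, truth, 40.0)
            assert tp + fp == len(dets)


class TestPrecisionRecall:
    @pytest.mark.parametrize(
        "tp,fp,total,precision,recall",
        [(5, 0, 10, 1.0, 0.5), (0, 7, 10, 0.0, 0.0), (3, 1, 4, 0.75, 0.75)],
    )
    def test_algebra(self, tp, fp, total, precision, recall):
        result = precision_recall(tp, fp, total)
        assert result.precision == pytest.approx(precision)
        assert result.recall == pytest.approx(recall)

    def test_undefined_precision_without_detections(self):
        result = precision_recall(0, 0, 10)
        assert result.precision is None
        assert result.recall == 0.0
        assert result.as_row()["precision_pct"] == "n/a"

    def test_undefined_recall_without_weeds(self):
        assert precision_recall(0, 3, 0).recall is None

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            precision_recall(-1, 0, 5)
        with pytest.raises(ValueError):
            precision_recall(6, 0, 5)  # TP cannot exceed weeds present


class TestWeedDensity:
    @pytest.mark.parametrize("count,expected", [(155, 3.1), (465, 9.3), (0, 0.0)])
    def test_per_square_metre(self, count, expected):
        assert weed_density(count, 50.0, 1.0) == pytest.approx(expected)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            weed_density(10, 0.0, 1.0)


class TestAggregate:
    def test_field_trial_summaries(self):
        """The bundled seven-transect trial table reproduces its published
        summary statistics."""
        summary = aggregate(load_field_performance())
        assert round(summary.mean_precision, 1) == 78.8
        assert round(summary.mean_recall, 1) == 52.2
        assert round(summary.median_recall_by_algorithm["exg"], 1) == 68.1
        assert round(summary.median_precision_by_algorithm["hsv"], 1) == 96.6
        assert round(summary.mean_precision_by_field["HEN1"], 1) == 26.6
        assert round(summary.mean_precision_by_field["WAG1"], 2) == 95.65
        assert round(summary.sem_precision_by_field["HEN1"], 1) == 4.3
        assert round(summary.sem_precision_by_field["WAG1"], 1) == 1.5

    def test_missing_cells_excluded(self):
        table = load_field_performance()
        night2_nexg = table[(table.field == "NIGHT2") & (table.algorithm == "nexg")]
        assert night2_nexg.precision_pct.isna().all()
        # 27 of 28 cells are present
        assert table.precision_pct.notna().sum() == 27
        assert table.recall_pct.notna().sum() == 27

    def test_single_cell_table(self):
        table = pd.DataFrame(
            [{"field": "F1", "algorithm": "exg",
              "precision_pct": 80.0, "recall_pct": 40.0}]
        )
        summary = aggregate(table)
        assert summary.mean_precision == 80.0
        assert summary.median_recall_by_algorithm["exg"] == 40.0
        assert math.isnan(summary.sem_precision)

    def test_empty_or_malformed_table_rejected(self):
        with pytest.raises(ValueError):
            aggregate(pd.DataFrame(columns=["field", "algorithm",
                                            "precision_pct", "recall_pct"]))
        with pytest.raises(ValueError):
            aggregate(pd.DataFrame([{"foo": 1}]))


def test_site_table_density_consistency():
    """Back-derived weed counts reproduce each site's published density."""
    sites = load_field_sites()
    for row in sites.itertuples():
        count = round(row.weed_density_per_m2 * row.transect_length_m * row.fov_width_m)
        assert weed_density(count, row.transect_length_m, row.fov_width_m) == (
            pytest.approx(row.weed_density_per_m2, abs=0.01)
        )


def test_unique_truth_ids_enforced():
    with pytest.raises(ValueError):
        GroundTruthSet((GroundTruth(0, (1, 1)), GroundTruth(0, (2, 2))))
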