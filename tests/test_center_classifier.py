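import math

import numpy as np
import pandas as pd
import pytest

from riskpath.center_classifier import (
    CALL_FUZZY_INTERSECTION,
    CALL_FUZZY_ISOLATION,
    PathwayEvaluation,
    classify,
    evaluate_pathway,
    fit,
    geometric_center,
    minimal_radius,
    rank_pathways,
    risk_overlap,
)


class TestGeometry:
    def test_center_is_mean(self):
        assert np.allclose(geometric_center([(0, 0), (2, 2)]), (1, 1))

    def test_single_point_center(self):
        assert np.allclose(geometric_center([(3.5, -1.0)]), (3.5, -1.0))

    def test_center_matches_loop(self, rng):
        pts = rng.standard_normal((100, 2))
        c = geometric_center(pts)
        assert c[0] == pytest.approx(sum(p[0] for p in pts) / 100)
        assert c[1] == pytest.approx(sum(p[1] for p in pts) / 100)

    def test_radius_is_order_statistic(self):
        pts = [(d, 0.0) for d in range(1, 11)]
        assert minimal_radius(pts, (0.0, 0.0), coverage=0.8) == 8.0

    def test_full_coverage_is_max_distance(self):
        pts = [(d, 0.0) for d in range(1, 11)]
        assert minimal_radius(pts, (0.0, 0.0), coverage=1.0) == 10.0

    def test_radius_minimality_scan(self, rng):
        pts = rng.standard_normal((37, 2)) * 2.5
        center = (0.3, -0.1)
        r = minimal_radius(pts, center, coverage=0.8)
        dist = np.linalg.norm(pts - np.array(center), axis=1)
        need = math.ceil(0.8 * len(pts))
        assert (dist <= r).sum() >= need
        # no strictly smaller candidate radius achieves the coverage
        for cand in sorted(dist):
            if cand < r:
                assert (dist <= cand).sum() < need


class TestFitClassify:
    def test_separated_clouds_give_disjoint_circles(self, rng):
        good = rng.standard_normal((30, 2))
        poor = rng.standard_normal((15, 2)) + 20.0  # 10+ SD separation
        model = fit(good, poor)
        gap = np.linalg.norm(
            np.array(model.center_good) - np.array(model.center_poor)
        )
        assert gap > model.radius_good + model.radius_poor

    def test_identical_clouds_give_similar_circles(self, rng):
        pts = rng.standard_normal((20, 2))
        model = fit(pts, pts)
        assert model.center_good == model.center_poor
        assert model.radius_good == model.radius_poor

    def test_self_coverage_is_exact(self, rng):
        for _ in range(5):
            good = rng.standard_normal((23, 2)) * rng.uniform(0.5, 3)
            poor = rng.standard_normal((11, 2)) + rng.uniform(-2, 2)
            model = fit(good, poor)
            dg = np.linalg.norm(good - np.array(model.center_good), axis=1)
            dp = np.linalg.norm(poor - np.array(model.center_poor), axis=1)
            assert (dg <= model.radius_good).sum() >= math.ceil(0.8 * 23)
            assert (dp <= model.radius_poor).sum() >= math.ceil(0.8 * 11)

    def test_degenerate_identical_points_radius_zero(self):
        model = fit([(1, 1)] * 5, [(4, 4)] * 5)
        assert model.radius_good == model.radius_poor == 0.0

    def test_call_definitions(self):
        model = fit([(0, 0), (0, 1), (1, 0), (1, 1)], [(10, 10), (10, 11), (11, 10), (11, 11)])
        calls = classify(model, [(0.5, 0.5), (10.5, 10.5), (5, 5)])
        assert list(calls) == ["good", "poor", CALL_FUZZY_ISOLATION]

    def test_point_in_both_circles_is_intersection_fuzzy(self):
        model = fit([(0, 0), (2, 0), (0, 2), (2, 2)], [(1, 0), (3, 0), (1, 2), (3, 2)])
        calls = classify(model, [(1.5, 1.0)])
        assert calls.iloc[0] == CALL_FUZZY_INTERSECTION

    def test_rigid_rotation_invariance(self, rng):
        good = rng.standard_normal((20, 2))
        poor = rng.standard_normal((12, 2)) + 3.0
        pts = rng.standard_normal((25, 2)) * 2
        model = fit(good, poor)
        theta = 0.83
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        model_rot = fit(good @ rot.T, poor @ rot.T)
        a = classify(model, pts)
        b = classify(model_rot, pts @ rot.T)
        assert list(a) == list(b)


class TestEvaluation:
    def test_perfect_separation(self):
        calls = pd.Series(["good", "good", "poor"], index=["a", "b", "c"])
        truth = {"a": "good", "b": "good", "c": "poor"}
        ev = evaluate_pathway(calls, truth)
        assert (ev.precise1, ev.precise2, ev.fuzzy_count) == (1.0, 1.0, 0)
        assert ev.mean_precision == 1.0

    def test_all_fuzzy_degenerate(self, caplog):
        calls = pd.Series(
            [CALL_FUZZY_INTERSECTION, CALL_FUZZY_ISOLATION], index=["a", "b"]
        )
        with caplog.at_level("WARNING"):
            ev = evaluate_pathway(calls, {"a": "good", "b": "poor"})
        assert ev.precise1 == ev.precise2 == 0.0
        assert ev.fuzzy_count == 2

    def test_matches_confusion_tally(self, rng):
        labels = ["good", "poor", CALL_FUZZY_INTERSECTION, CALL_FUZZY_ISOLATION]
        calls = pd.Series(
            rng.choice(labels, size=60), index=[f"s{i}" for i in range(60)]
        )
        truth = dict(
            zip(calls.index, rng.choice(["good", "poor"], size=60))
        )
        ev = evaluate_pathway(calls, truth)
        cg = [s for s in calls.index if calls[s] == "good"]
        cp = [s for s in calls.index if calls[s] == "poor"]
        assert ev.precise1 == pytest.approx(
            sum(truth[s] == "good" for s in cg) / len(cg)
        )
        assert ev.precise2 == pytest.approx(
            sum(truth[s] == "poor" for s in cp) / len(cp)
        )
        assert ev.fuzzy_count == 60 - len(cg) - len(cp)

    def test_label_swap_swaps_precisions(self, rng):
        labels = ["good", "poor"]
        calls = pd.Series(
            rng.choice(labels, size=40), index=[f"s{i}" for i in range(40)]
        )
        truth = dict(zip(calls.index, rng.choice(labels, size=40)))
        ev = evaluate_pathway(calls, truth)
        swap = {"good": "poor", "poor": "good"}
        ev_sw = evaluate_pathway(calls.map(swap), {s: swap[g] for s, g in truth.items()})
        assert ev_sw.precise1 == pytest.approx(ev.precise2)
        assert ev_sw.precise2 == pytest.approx(ev.precise1)


class TestRanking:
    def _ev(self, pid, p1, p2, fuzzy=0):
        return PathwayEvaluation(pid, p1, p2, fuzzy)

    def test_sort_filter_truncate(self):
        evals = [
            self._ev("A", 0.8, 0.8),
            self._ev("B", 0.6, 0.6),
            self._ev("C", 0.7, 0.7),
        ]
        assert [e.pathway_id for e in rank_pathways(evals, top_k=2)] == ["A", "C"]

    def test_all_below_threshold(self, caplog):
        with caplog.at_level("WARNING"):
            assert rank_pathways([self._ev("A", 0.5, 0.5)]) == []

    def test_tie_breaks(self):
        evals = [
            self._ev("B", 0.9, 0.7, fuzzy=2),
            self._ev("A", 0.8, 0.8, fuzzy=5),
            self._ev("C", 0.8, 0.8, fuzzy=1),
        ]
        # same mean 0.8: A/C beat B on min precision; C beats A on fuzz
        assert [e.pathway_id for e in rank_pathways(evals)] == ["C", "A", "B"]

    def test_matches_independent_sort(self, rng):
        evals = [
            self._ev(f"P{i:03d}", rng.uniform(0.5, 1), rng.uniform(0.5, 1), int(rng.integers(0, 20)))
            for i in range(278)
        ]
        ranked = rank_pathways(evals, threshold=0.65, top_k=278)
        oracle = sorted(
            (e for e in evals if (e.precise1 + e.precise2) / 2 > 0.65),
            key=lambda e: (-e.mean_precision, -min(e.precise1, e.precise2), e.fuzzy_count, e.pathway_id),
        )
        assert [e.pathway_id for e in ranked] == [e.pathway_id for e in oracle]


class TestRiskOverlap:
    def test_identical_sets(self):
        assert risk_overlap({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert risk_overlap({"a"}, {"b"}) == 0.0

    def test_empty_intersection_warns(self, caplog):
        with caplog.at_level("WARNING"):
            assert risk_overlap(set(), {"a"}) == 0.0

    def test_set_arithmetic(self, rng):
        inter = set(rng.choice(100, 20, replace=False))
        at_risk = set(rng.choice(100, 30, replace=False))
        assert risk_overlap(inter, at_risk) == len(inter & at_risk) / 20


def test_separation_monotonicity(rng):
    """Mean precision rises toward 1 as the clouds separate."""
    from riskpath.center_classifier import evaluate_pathway as ev

    precisions = []
    for sep in (0.3, 1.5, 20.0):
        good = rng.standard_normal((30, 2))
        poor = rng.standard_normal((15, 2)) + sep
        model = fit(good, poor)
        pts = np.vstack([good, poor])
        ids = [f"s{i}" for i in range(45)]
        truth = {s: ("good" if i < 30 else "poor") for i, s in enumerate(ids)}
        calls = classify(model, pts, sample_ids=ids)
        precisions.append(ev(calls, truth).mean_precision)
    assert precisions[0] <= precisions[1] <= precisions[2]
    assert precisions[0] < precisions[2]
    assert precisions[2] == 1.0
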