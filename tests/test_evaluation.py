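"""Image metrics, point matching, detection rates, and aggregation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from papillae import (DetectionOutcome, Heatmap, PointSet, aggregate_runs,
                      detection_rates, dice_metric, evaluate_fold,
                      HeatmapConfig, mae_metric, match_points,
                      points_to_heatmap, ssim_metric)
from papillae.errors import ValidationError


def brute_force_tp(gt: np.ndarray, pred: np.ndarray, radius: float) -> int:
    """Exhaustive search over one-to-one assignments; returns max TP count."""
    n, m = len(gt), len(pred)
    if n == 0 or m == 0:
        return 0
    d = np.sqrt(((gt[:, None] - pred[None]) ** 2).sum(-1))
    feasible = d <= radius
    best = 0
    for k in range(min(n, m), 0, -1):
        for gsub in itertools.combinations(range(n), k):
            for psub in itertools.permutations(range(m), k):
                if all(feasible[g, p] for g, p in zip(gsub, psub)):
                    return k
    return best


class TestImageMetrics:
    def test_mae_identity_and_closed_form(self, rng):
        x = Heatmap(rng.random((16, 16)))
        assert mae_metric(x, x) == 0.0
        zero = Heatmap(np.zeros((16, 16)))
        tenth = Heatmap(np.full((16, 16), 0.1))
        assert mae_metric(tenth, zero) == pytest.approx(0.1, abs=1e-7)

    def test_mae_symmetry(self, rng):
        a, b = Heatmap(rng.random((16, 16))), Heatmap(rng.random((16, 16)))
        assert mae_metric(a, b) == mae_metric(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mae_metric(Heatmap(np.zeros((4, 4))), Heatmap(np.zeros((5, 5))))

    def test_ssim_identity(self, rng):
        x = Heatmap(rng.random((32, 32)))
        assert ssim_metric(x, x) == pytest.approx(1.0, abs=1e-9)

    def test_ssim_constant_maps_zero_variance_closed_form(self):
        a = Heatmap(np.full((32, 32), 0.3))
        b = Heatmap(np.full((32, 32), 0.8))
        # the closed form is evaluated on the stored (float32) intensities
        c1, c2 = float(a.values[0, 0]), float(b.values[0, 0])
        C1 = 0.01 ** 2
        expected = (2 * c1 * c2 + C1) / (c1 ** 2 + c2 ** 2 + C1)
        assert ssim_metric(a, b) == pytest.approx(expected, abs=1e-9)

    def test_ssim_anticorrelated_high_variance_is_negative(self):
        g = np.random.default_rng(5)
        x = (g.random((16, 16)) > 0.5).astype(float)
        assert ssim_metric(Heatmap(x), Heatmap(1.0 - x)) < 0

    def test_dice_perfect_disjoint_and_partial(self):
        a = np.zeros((8, 8)); a[:2, :2] = 1.0
        b = np.zeros((8, 8)); b[:2, 2:4] = 1.0
        assert dice_metric(Heatmap(a), Heatmap(a)) == 1.0
        assert dice_metric(Heatmap(a), Heatmap(b)) == 0.0
        # |A|=4, |B|=4, overlap 2 -> 0.5
        c = np.zeros((8, 8)); c[:2, 1:3] = 1.0
        assert dice_metric(Heatmap(a), Heatmap(c)) == 0.5

    def test_dice_both_empty_is_one(self):
        z = Heatmap(np.zeros((8, 8)))
        assert dice_metric(z, z) == 1.0


class TestMatchPoints:
    def test_single_pair_in_range(self):
        out = match_points(PointSet.from_list([(5, 5)]),
                           PointSet.from_list([(6, 5)]), radius=3)
        assert (out.tp, out.up, out.un) == (1, 0, 0)
        assert out.matched_pairs[0][2] == pytest.approx(1.0)

    def test_empty_prediction(self):
        out = match_points(PointSet.from_list([(5, 5)]),
                           PointSet.from_list([]), radius=3)
        assert (out.tp, out.up, out.un) == (0, 0, 1)

    def test_shared_prediction_matches_only_one_gt(self):
        out = match_points(PointSet.from_list([(0, 0), (4, 0)]),
                           PointSet.from_list([(2, 0)]), radius=3)
        assert (out.tp, out.up, out.un) == (1, 0, 1)

    def test_order_independence(self, rng):
        gt = rng.random((6, 2)) * 20
        pred = rng.random((5, 2)) * 20
        a = match_points(PointSet(gt), PointSet(pred), 4.0)
        b = match_points(PointSet(gt[::-1]), PointSet(pred[::-1]), 4.0)
        assert (a.tp, a.up, a.un) == (b.tp, b.up, b.un)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_tp_count_equals_exhaustive_enumeration(self, seed):
        g = np.random.default_rng(seed)
        gt = g.random((int(g.integers(0, 8)), 2)) * 30
        pred = g.random((int(g.integers(0, 8)), 2)) * 30
        out = match_points(PointSet(gt), PointSet(pred), radius=5.0)
        assert out.tp == brute_force_tp(gt, pred, 5.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_conservation_identities(self, seed):
        g = np.random.default_rng(seed)
        gt = g.random((int(g.integers(0, 30)), 2)) * 50
        pred = g.random((int(g.integers(0, 30)), 2)) * 50
        out = match_points(PointSet(gt), PointSet(pred), radius=4.0)
        assert out.tp + out.un == len(gt)
        assert out.tp + out.up == len(pred)
        assert all(p[2] <= 4.0 for p in out.matched_pairs)


class TestDetectionRates:
    def test_printed_formula_example(self):
        r = detection_rates(DetectionOutcome(tp=8, up=2, un=2, matched_pairs=[]))
        assert r.tp_rate_pct == pytest.approx(80.0)
        assert r.accurate_count_pct == pytest.approx(80.0)
        assert r.complete_accuracy_pct == pytest.approx(100 * 8 / 12)

    def test_perfect_detection_all_hundred(self):
        r = detection_rates(DetectionOutcome(tp=9, up=0, un=0, matched_pairs=[]))
        assert r.tp_rate_pct == r.accurate_count_pct == r.complete_accuracy_pct == 100.0

    def test_zero_tp(self):
        r = detection_rates(DetectionOutcome(tp=0, up=5, un=10, matched_pairs=[]))
        assert r.tp_rate_pct == 0.0 and r.accurate_count_pct == 0.0
        assert r.complete_accuracy_pct == 0.0

    def test_undefined_rates_are_marked_not_zero(self):
        r = detection_rates(DetectionOutcome(tp=0, up=0, un=0, matched_pairs=[]))
        assert r.tp_rate_pct is None and r.accurate_count_pct is None

    def test_tp_plus_un_rates_sum_to_hundred(self, rng):
        for _ in range(20):
            tp, up, un = (int(x) for x in rng.integers(0, 40, 3))
            if tp + un == 0:
                continue
            r = detection_rates(DetectionOutcome(tp=tp, up=up, un=un, matched_pairs=[]))
            assert r.tp_rate_pct + r.un_rate_pct == pytest.approx(100.0, abs=1e-9)


class _OracleModel:
    """Fake model that returns the ground-truth heatmap for each image."""

    def __init__(self, maps):
        self.maps = maps
        self.i = -1

    def predict(self, image):
        self.i += 1
        return self.maps[self.i]


class TestFoldEvaluation:
    @pytest.fixture()
    def fold_data(self, rng, hm_config):
        val, maps = [], []
        for i in range(4):
            pts = PointSet(rng.integers(10, 50, (6, 2)).astype(float))
            # re-sample until separated enough for exact peak recovery
            while pts.min_separation() <= 2 * hm_config.peak_min_distance + 1:
                pts = PointSet(rng.integers(10, 50, (6, 2)).astype(float))
            maps.append(points_to_heatmap(pts, (64, 64), hm_config))
            val.append((f"s{i}", rng.random((64, 64, 3)), pts))
        return val, maps

    def test_oracle_model_is_perfect(self, fold_data, hm_config):
        val, maps = fold_data
        rep = evaluate_fold(_OracleModel(maps), val, hm_config, radius=5.0)
        assert (rep.per_image["mae"] == 0).all()
        assert np.allclose(rep.per_image["ssim"], 1.0)
        assert (rep.per_image["dice"] == 1.0).all()
        assert (rep.per_image["up"] == 0).all() and (rep.per_image["un"] == 0).all()
        assert rep.rates.tp_rate_pct == 100.0

    def test_all_zero_model_misses_everything(self, fold_data, hm_config):
        val, _ = fold_data
        zero = _OracleModel([Heatmap(np.zeros((64, 64))) for _ in val])
        rep = evaluate_fold(zero, val, hm_config, radius=5.0)
        assert (rep.per_image["tp"] == 0).all()
        assert (rep.per_image["un"] == rep.per_image["gt_count"]).all()

    def test_predicted_count_is_tp_plus_up(self, fold_data, hm_config):
        val, maps = fold_data
        rep = evaluate_fold(_OracleModel(maps), val, hm_config, radius=5.0)
        assert (rep.per_image["pred_count"]
                == rep.per_image["tp"] + rep.per_image["up"]).all()


class TestAggregation:
    def _report(self, tp, up, un, hm_config):
        import pandas as pd
        from papillae.evaluation import FoldReport
        df = pd.DataFrame([{
            "sample_id": "x", "mae": 0.1, "ssim": 0.9, "dice": 0.8,
            "gt_count": tp + un, "pred_count": tp + up,
            "tp": tp, "up": up, "un": un,
        }])
        return FoldReport(per_image=df, radius=5.0)

    def test_single_fold_mean_is_value_sd_zero(self, hm_config):
        agg = aggregate_runs([self._report(8, 2, 2, hm_config)])
        row = agg["summary"].set_index("metric").loc["tp_rate_pct"]
        assert row["mean"] == pytest.approx(80.0) and row["sd"] == 0.0

    def test_two_fold_mean_and_sd(self, hm_config):
        agg = aggregate_runs([self._report(8, 0, 2, hm_config),
                              self._report(6, 0, 4, hm_config)])
        row = agg["summary"].set_index("metric").loc["tp_rate_pct"]
        assert row["mean"] == pytest.approx(70.0)
        assert row["sd"] == pytest.approx(np.std([80.0, 60.0], ddof=1))

    def test_count_export_has_one_row_per_image(self, hm_config):
        agg = aggregate_runs([self._report(8, 2, 2, hm_config),
                              self._report(6, 0, 4, hm_config)])
        assert len(agg["counts"]) == 2
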