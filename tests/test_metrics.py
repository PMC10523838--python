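"""Evaluation protocol: Dice/IOU, matching, precision/recall/yield, areas, sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somaswin.metrics import (
    FP_BACKGROUND,
    FP_DOUBLET,
    FP_WRONG_BOUNDARY,
    area_agreement,
    dice,
    iou,
    match_instances,
    precision,
    recall,
    soma_area,
    threshold_sweep,
    yield_rate,
)


def _mask(shape, coords):
    m = np.zeros(shape, dtype=bool)
    for r, c in coords:
        m[r, c] = True
    return m


def _blob(shape, r0, c0, h, w):
    m = np.zeros(shape, dtype=bool)
    m[r0:r0 + h, c0:c0 + w] = True
    return m


class TestDiceIou:
    def test_identical_masks(self):
        m = _blob((8, 8), 2, 2, 3, 3)
        assert dice(m, m) == 1.0
        assert iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a, b = _blob((8, 8), 0, 0, 2, 2), _blob((8, 8), 5, 5, 2, 2)
        assert dice(a, b) == 0.0
        assert iou(a, b) == 0.0

    def test_half_overlap_counts(self):
        a = _mask((4, 4), [(0, 0), (0, 1), (1, 0), (1, 1)])
        b = _mask((4, 4), [(1, 0), (1, 1), (2, 0), (2, 1)])
        assert dice(a, b) == pytest.approx(0.5)
        assert iou(a, b) == pytest.approx(2 / 6)

    def test_both_empty_is_an_error(self):
        e = np.zeros((4, 4), dtype=bool)
        with pytest.raises(ValueError):
            dice(e, e)
        with pytest.raises(ValueError):
            iou(e, e)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.ones((3, 3), bool), np.ones((4, 4), bool))

    @given(st.integers(0, 2 ** 18 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_dice_iou_identity_and_symmetry(self, bits):
        rng = np.random.default_rng(bits)
        a = rng.random((6, 6)) < 0.4
        b = rng.random((6, 6)) < 0.4
        if not (a.any() or b.any()):
            a[0, 0] = True
        d, j = dice(a, b), iou(a, b)
        assert 0.0 <= d <= 1.0 and 0.0 <= j <= 1.0
        assert d == pytest.approx(2 * j / (1 + j))
        assert d == dice(b, a) and j == iou(b, a)


# ---------------------------------------------------------------------------
# independent matching oracle: pure-python pixel counting + naive rule replay


def pixel_loop_overlap(x, y):
    inter = nx = ny = 0
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            xi, yi = bool(x[i, j]), bool(y[i, j])
            inter += xi and yi
            nx += xi
            ny += yi
    d = 2 * inter / (nx + ny) if nx + ny else 0.0
    u = nx + ny - inter
    return d, (inter / u if u else 0.0)


def oracle_match(gt_masks, pred_masks, iou_threshold=0.5, doublet_iou=0.2):
    """Naive replay of the matching rule with pixel-loop overlaps."""
    nd = [[pixel_loop_overlap(g, p) for p in pred_masks] for g in gt_masks]
    best = [max((d for d, _ in row), default=0.0) for row in nd]
    order = sorted(range(len(gt_masks)), key=lambda g: (-best[g], g))
    taken = {}
    verdict_gt = {}
    for g in order:
        cand, cd = None, 0.0
        for p in range(len(pred_masks)):
            if p in taken:
                continue
            d, _ = nd[g][p]
            if d > cd:
                cand, cd = p, d
        if cand is not None and nd[g][cand][1] > iou_threshold:
            taken[cand] = g
            verdict_gt[g] = "TP"
        else:
            verdict_gt[g] = "FN"
    verdict_pred = {}
    for p in range(len(pred_masks)):
        if p in taken:
            verdict_pred[p] = "TP"
            continue
        ious = [nd[g][p][1] for g in range(len(gt_masks))]
        best_iou = max(ious, default=0.0)
        if 0.0 < best_iou <= iou_threshold:
            verdict_pred[p] = FP_WRONG_BOUNDARY
        elif sum(v > doublet_iou for v in ious) >= 2:
            verdict_pred[p] = FP_DOUBLET
        else:
            verdict_pred[p] = FP_BACKGROUND
    return verdict_gt, verdict_pred


def random_mask_set(rng, shape=(16, 16), max_n=4):
    n = int(rng.integers(0, max_n + 1))
    masks = []
    for _ in range(n):
        r = int(rng.integers(0, shape[0] - 4))
        c = int(rng.integers(0, shape[1] - 4))
        h = int(rng.integers(2, 5))
        w = int(rng.integers(2, 5))
        masks.append(_blob(shape, r, c, h, w))
    return masks


class TestMatchInstances:
    def test_no_predictions_all_missed(self):
        gts = [_blob((8, 8), 0, 0, 3, 3), _blob((8, 8), 4, 4, 3, 3)]
        res = match_instances(gts, [])
        assert (res.tp, res.fp, res.fn) == (0, 0, 2)

    def test_perfect_predictions(self):
        gts = [_blob((8, 8), 0, 0, 3, 3), _blob((8, 8), 4, 4, 3, 3)]
        res = match_instances(gts, [m.copy() for m in gts])
        assert (res.tp, res.fp, res.fn) == (2, 0, 0)
        assert all(r.dice == 1.0 for r in res.gt_records)

    def test_contention_two_predictions_one_gt(self):
        # 10x1 gt; preds overlap 8 and 7 px -> IOUs 8/12=0.67 and 7/13~0.54
        gt = _blob((20, 4), 0, 0, 10, 1)
        p1 = _blob((20, 4), 0, 0, 8, 1) | _blob((20, 4), 10, 0, 2, 1)
        p2 = _blob((20, 4), 3, 0, 10, 1)
        res = match_instances([gt], [p1, p2])
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)

    def test_fp_subtypes(self):
        shape = (24, 24)
        gts = [_blob(shape, 0, 0, 6, 6), _blob(shape, 0, 8, 6, 6)]
        exact = gts[0].copy()                     # TP
        nudged = _blob(shape, 3, 0, 6, 6)         # overlaps gt0 with IOU ~0.33
        straddle = _blob(shape, 0, 3, 6, 8)       # hits both gts
        far = _blob(shape, 16, 16, 4, 4)          # background
        res = match_instances(gts, [exact, nudged, straddle, far])
        verdicts = {r.index: r.verdict for r in res.pred_records}
        assert verdicts[0] == "TP"
        assert verdicts[1] == FP_WRONG_BOUNDARY
        assert verdicts[3] == FP_BACKGROUND
        assert res.fp_by_type[FP_WRONG_BOUNDARY] >= 1

    def test_doublet_subtype(self):
        # an unmatched prediction spanning two somas (best IOU > 0.5, its best
        # ground truth already claimed by an exact detection) is a doublet
        shape = (12, 30)
        gts = [_blob(shape, 2, 2, 8, 8), _blob(shape, 2, 10, 8, 8)]
        exact = gts[0].copy()
        spanning = _blob(shape, 2, 2, 8, 14)  # IOU 0.57 with gt0, 0.375 with gt1
        res = match_instances(gts, [exact, spanning], iou_threshold=0.5)
        verdicts = {r.index: r.verdict for r in res.pred_records}
        assert verdicts[0] == "TP"
        assert verdicts[1] == FP_DOUBLET
        assert res.fn == 1

    def test_agrees_with_pixel_loop_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            gts = random_mask_set(rng)
            preds = random_mask_set(rng)
            res = match_instances(gts, preds)
            ogt, opred = oracle_match(gts, preds)
            assert {r.index: r.verdict for r in res.gt_records} == ogt
            assert {r.index: r.verdict for r in res.pred_records} == opred

    def test_one_to_one_assignment(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            gts = random_mask_set(rng)
            preds = random_mask_set(rng)
            res = match_instances(gts, preds)
            matched_preds = [r.matched_pred for r in res.gt_records
                             if r.matched_pred is not None]
            assert len(matched_preds) == len(set(matched_preds))
            assert res.tp <= min(len(gts), len(preds))
            assert res.tp + res.fn == len(gts)
            assert res.tp + res.fp == len(preds)


class TestRates:
    def test_precision_recall_exact_ratios(self):
        assert precision(3, 1) == 0.75
        assert recall(3, 1) == 0.75
        assert precision(5, 0) == 1.0

    def test_zero_denominators_raise(self):
        with pytest.raises(ZeroDivisionError):
            precision(0, 0)
        with pytest.raises(ZeroDivisionError):
            recall(0, 0)
        with pytest.raises(ZeroDivisionError):
            yield_rate(0, 0)

    def test_yield_rate_bounds(self):
        assert yield_rate(0, 10) == 0.0
        assert yield_rate(10, 10) == 1.0
        with pytest.raises(ValueError):
            yield_rate(11, 10)

    def test_rates_invert_to_integer_counts(self):
        tp, fp, fn = 37, 11, 5
        assert precision(tp, fp) * (tp + fp) == pytest.approx(tp)
        assert recall(tp, fn) * (tp + fn) == pytest.approx(tp)


class TestSomaArea:
    def test_unit_pixel_size(self):
        assert soma_area(np.ones((10, 10), bool), 1.0) == 100.0

    def test_half_micron_pixels(self):
        assert soma_area(np.ones((10, 10), bool), 0.5) == 25.0

    def test_empty_mask_zero(self):
        assert soma_area(np.zeros((5, 5), bool), 1.0) == 0.0

    def test_invalid_pixel_size(self):
        with pytest.raises(ValueError):
            soma_area(np.ones((2, 2), bool), 0.0)


class TestAreaAgreement:
    def test_identical_pairs(self):
        pairs = [(10.0, 10.0), (20.0, 20.0), (30.0, 30.0)]
        out = area_agreement(pairs)
        assert out["mean_diff"] == 0.0
        assert out["slope"] == pytest.approx(1.0)
        assert out["r_squared"] == pytest.approx(1.0)

    def test_constant_offset(self):
        manual = np.array([10.0, 20.0, 30.0, 40.0])
        out = area_agreement(list(zip(manual + 10, manual)))
        assert out["mean_diff"] == pytest.approx(10.0)
        assert out["slope"] == pytest.approx(1.0)
        assert out["intercept"] == pytest.approx(10.0)

    def test_multiplicative_bias(self):
        manual = np.array([10.0, 20.0, 30.0, 40.0])
        out = area_agreement(list(zip(1.1 * manual, manual)))
        assert out["slope"] == pytest.approx(1.1)
        assert out["r_squared"] == pytest.approx(1.0)

    def test_constant_manual_reported_as_nan(self):
        out = area_agreement([(9.0, 5.0), (11.0, 5.0), (10.0, 5.0)])
        assert np.isnan(out["r_squared"]) and np.isnan(out["slope"])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            area_agreement([(1.0, 1.0), (2.0, 2.0)])


class TestThresholdSweep:
    def _setup(self):
        shape = (32, 32)
        gts = {0: [_blob(shape, 0, 0, 6, 6), _blob(shape, 10, 10, 6, 6)],
               1: [_blob(shape, 20, 20, 6, 6)]}
        preds = {0: [(_blob(shape, 0, 0, 6, 6), 0.9),
                     (_blob(shape, 10, 10, 6, 6), 0.3),
                     (_blob(shape, 24, 0, 4, 4), 0.1)],
                 1: [(_blob(shape, 20, 20, 6, 6), 0.5)]}
        return preds, gts

    def test_threshold_zero_keeps_everything(self):
        preds, gts = self._setup()
        summary = threshold_sweep(preds, gts, [0.0])
        assert summary.rows[0].total_detected == 4

    def test_totals_non_increasing_and_percentages_partition(self):
        preds, gts = self._setup()
        summary = threshold_sweep(preds, gts, [0.0, 0.2, 0.4, 0.95])
        totals = [r.total_detected for r in summary.rows]
        assert totals == sorted(totals, reverse=True)
        for row in summary.rows:
            if row.total_detected:
                s = row.pct_correct + row.pct_wrong_boundary + row.pct_background_doublet
                assert s == pytest.approx(100.0)

    def test_headline_rates_at_lowest_threshold(self):
        preds, gts = self._setup()
        summary = threshold_sweep(preds, gts, [0.0])
        assert summary.precision == pytest.approx(3 / 4)
        assert summary.recall == pytest.approx(1.0)
        assert summary.yield_rate == pytest.approx(1.0)

    def test_unsorted_thresholds_rejected(self):
        preds, gts = self._setup()
        with pytest.raises(ValueError):
            threshold_sweep(preds, gts, [0.4, 0.1])
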