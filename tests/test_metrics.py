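"""Metric formulas against independent oracles and edge-case conventions."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sgnet.metrics import (ConfusionCounts, MetricsReport, binarize,
                           confusion, evaluate, hd95, mask_boundary,
                           scalar_metrics, write_report)

counts_strategy = st.tuples(*[st.integers(0, 10_000)] * 4).filter(
    lambda c: sum(c) > 0)


def rational_oracle(tp, fp, tn, fn):
    """Exact rational-arithmetic evaluation of the five overlap metrics."""
    def ratio(num, den):
        return float(Fraction(num, den)) if den else 1.0
    return (ratio(tp, fp + tp + fn),
            ratio(2 * tp, fp + 2 * tp + fn),
            ratio(tp + tn, tp + fp + tn + fn),
            ratio(tp, tp + fn),
            ratio(tn, tn + fp))


class TestConfusion:
    def test_all_ones_agree(self):
        m = np.ones((2, 2), dtype=np.uint8)
        c = confusion(m, m)
        assert (c.tp, c.fp, c.tn, c.fn) == (4, 0, 0, 0)

    def test_complement_has_no_agreement(self):
        t = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        c = confusion(1 - t, t)
        assert c.tp == 0 and c.tn == 0 and c.fp == 2 and c.fn == 2

    def test_matches_exhaustive_pixel_loop(self, rng):
        p = (rng.random((4, 4)) > 0.5).astype(np.uint8)
        t = (rng.random((4, 4)) > 0.5).astype(np.uint8)
        c = confusion(p, t)
        tp = fp = tn = fn = 0
        for i in range(4):
            for j in range(4):
                if p[i, j] and t[i, j]:
                    tp += 1
                elif p[i, j] and not t[i, j]:
                    fp += 1
                elif not p[i, j] and t[i, j]:
                    fn += 1
                else:
                    tn += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)

    def test_shape_mismatch_and_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="0,1"):
            confusion(np.full((2, 2), 2), np.zeros((2, 2)))


class TestScalarMetrics:
    def test_printed_formula_examples(self):
        miou, *_ = scalar_metrics(ConfusionCounts(tp=3, fp=1, tn=0, fn=2))
        assert miou == pytest.approx(0.5)
        _, dsc, *_ = scalar_metrics(ConfusionCounts(tp=2, fp=1, tn=0, fn=1))
        assert dsc == pytest.approx(4 / 6)

    def test_both_empty_convention(self):
        miou, dsc, acc, se, sp = scalar_metrics(
            ConfusionCounts(tp=0, fp=0, tn=10, fn=0))
        assert (miou, dsc, acc, se, sp) == (1.0, 1.0, 1.0, 1.0, 1.0)

    @given(counts_strategy)
    @settings(max_examples=1000, deadline=None)
    def test_matches_rational_oracle(self, counts):
        tp, fp, tn, fn = counts
        got = scalar_metrics(ConfusionCounts(tp, fp, tn, fn))
        want = rational_oracle(tp, fp, tn, fn)
        assert np.allclose(got, want, rtol=1e-12)

    @given(counts_strategy)
    @settings(max_examples=300, deadline=None)
    def test_dsc_dominates_miou(self, counts):
        tp, fp, tn, fn = counts
        miou, dsc, *_ = scalar_metrics(ConfusionCounts(tp, fp, tn, fn))
        assert dsc >= miou - 1e-12

    def test_two_class_mean_variant(self):
        c = ConfusionCounts(tp=6, fp=2, tn=10, fn=2)
        fg = 6 / 10
        bg = 10 / 14
        miou, *_ = scalar_metrics(c, mean_over_classes=True)
        assert miou == pytest.approx((fg + bg) / 2)


def brute_force_hd95(p: np.ndarray, t: np.ndarray) -> float:
    """All-pairs boundary-distance oracle (pooled-percentile definition)."""
    bp = np.argwhere(mask_boundary(p))
    bt = np.argwhere(mask_boundary(t))
    d = np.sqrt(((bp[:, None, :] - bt[None, :, :]) ** 2).sum(-1))
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(np.percentile(pooled, 95))


class TestHD95:
    def test_identical_masks_zero(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[3:7, 3:7] = 1
        assert hd95(m, m) == 0.0

    def test_single_pixels_five_apart(self):
        a = np.zeros((9, 12), dtype=np.uint8)
        b = np.zeros((9, 12), dtype=np.uint8)
        a[4, 2] = 1
        b[4, 7] = 1
        assert hd95(a, b) == pytest.approx(5.0)

    def test_empty_mask_returns_image_diagonal(self):
        t = np.zeros((6, 8), dtype=np.uint8)
        p = t.copy()
        p[2, 2] = 1
        assert hd95(p, t) == pytest.approx(np.hypot(6, 8))
        assert hd95(t, t) == 0.0  # both empty

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        from scipy import ndimage
        p = ndimage.binary_dilation(rng.random((24, 24)) > 0.92,
                                    iterations=2).astype(np.uint8)
        t = ndimage.binary_dilation(rng.random((24, 24)) > 0.92,
                                    iterations=2).astype(np.uint8)
        if not (p.any() and t.any()):
            pytest.skip("degenerate draw")
        assert hd95(p, t) == pytest.approx(brute_force_hd95(p, t), abs=1e-9)

    def test_symmetry(self, rng):
        p = (rng.random((16, 16)) > 0.6).astype(np.uint8)
        t = (rng.random((16, 16)) > 0.6).astype(np.uint8)
        assert hd95(p, t) == hd95(t, p)

    def test_max_directed_variant_bounds_pooled(self, rng):
        p = (rng.random((16, 16)) > 0.7).astype(np.uint8)
        t = (rng.random((16, 16)) > 0.7).astype(np.uint8)
        assert hd95(p, t, variant="max_directed") >= 0


class TestEvaluationPipeline:
    def test_binarize_threshold(self):
        probs = np.array([[0.2, 0.5001], [0.9, 0.4999]])
        assert np.array_equal(binarize(probs),
                              np.array([[0, 1], [1, 0]], dtype=np.uint8))

    def test_global_vs_per_image_aggregation(self):
        a_pred = np.ones((4, 4), dtype=np.uint8)
        a_true = np.ones((4, 4), dtype=np.uint8)
        b_pred = np.zeros((4, 4), dtype=np.uint8)
        b_true = np.ones((4, 4), dtype=np.uint8)
        g = evaluate([(a_pred, a_true), (b_pred, b_true)], aggregate="global")
        p = evaluate([(a_pred, a_true), (b_pred, b_true)],
                     aggregate="per_image")
        assert g.dsc == pytest.approx(2 * 16 / (2 * 16 + 16))
        assert p.dsc == pytest.approx(0.5)   # (1.0 + 0.0) / 2

    def test_report_writers(self, tmp_path):
        rep = MetricsReport(0.8, 0.88, 0.95, 0.9, 0.97, 3.2,
                            ConfusionCounts(10, 2, 50, 3))
        for name in ("r.json", "r.csv"):
            write_report(rep, tmp_path / name)
            assert (tmp_path / name).stat().st_size > 0
        import json
        data = json.loads((tmp_path / "r.json").read_text())
        assert data["dsc"] == pytest.approx(88.0)
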