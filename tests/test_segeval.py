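"""Segmentation scoring: IoU pixel-count oracles, detection-rate monotonicity,
binarization, minimum enclosing circles, overlays."""

import numpy as np
import pytest
from skimage.draw import disk

import surgmon as sm
from surgmon.phantom import MaskSet


def random_mask(rng, shape=(20, 30), p=0.3):
    return (rng.random(shape) < p).astype(np.uint8)


class TestIoU:
    def test_toy_grid_pixel_counts(self):
        # two 2x2 squares overlapping in a 2x2 region of a 4x2-ish union
        a = np.zeros((4, 8), np.uint8)
        b = np.zeros((4, 8), np.uint8)
        a[1:3, 1:5] = 1          # 2x4 block, 8 px
        b[1:3, 3:5] = 1          # 2x2 block inside a's right end
        assert sm.iou(a, b) == pytest.approx(4 / 8)
        c = np.zeros((4, 8), np.uint8)
        c[1:3, 3:7] = 1          # 2x4 block shifted by two columns
        # 2x2 overlap inside a union of two 4x2 blocks: 4 / 12
        assert sm.iou(a, c) == pytest.approx(4 / 12)

    def test_identity_disjoint_empty(self):
        m = np.zeros((5, 5), np.uint8)
        m[1:3, 1:3] = 1
        assert sm.iou(m, m) == 1.0
        assert sm.iou(m, np.roll(m, 3, axis=0)) == 0.0
        z = np.zeros((5, 5), np.uint8)
        assert sm.iou(z, z) == 1.0   # both-empty convention
        with pytest.raises(ValueError):
            sm.iou(m, np.zeros((4, 4), np.uint8))

    def test_symmetry_on_random_pairs(self, rng):
        for _ in range(100):
            a, b = random_mask(rng), random_mask(rng)
            assert sm.iou(a, b) == sm.iou(b, a)

    def test_matches_pixel_count_oracle(self, rng):
        for _ in range(50):
            a, b = random_mask(rng), random_mask(rng)
            inter = int(((a == 1) & (b == 1)).sum())
            union = int(((a == 1) | (b == 1)).sum())
            expect = inter / union if union else 1.0
            assert sm.iou(a, b) == pytest.approx(expect)


class TestAccIoU:
    def test_count_oracle_and_bounds(self):
        ious = (0.05, 0.15, 0.95)
        assert sm.acc_iou_ge(ious, 0.1) == pytest.approx(2 / 3)
        assert sm.acc_iou_ge(ious, 0.0) == 1.0
        with pytest.raises(ValueError):
            sm.acc_iou_ge([], 0.5)

    def test_monotone_nonincreasing_in_n(self, rng):
        ious = rng.random(50)
        vals = [sm.acc_iou_ge(ious, n) for n in np.linspace(0, 1, 21)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestBinarize:
    def test_boundary_convention(self):
        assert sm.binarize(np.full((3, 3), 0.4)).sum() == 0
        assert sm.binarize(np.full((3, 3), 0.5)).sum() == 9   # >= at the threshold
        with pytest.raises(ValueError):
            sm.binarize(np.zeros((2, 2)), threshold=0.0)
        with pytest.raises(ValueError):
            sm.binarize(np.full((2, 2), 1.5))

    def test_elementwise_oracle(self, rng):
        c = rng.random((15, 15))
        assert np.array_equal(sm.binarize(c, 0.5), (c >= 0.5).astype(np.uint8))


class TestCircles:
    def test_single_pixel(self):
        m = np.zeros((10, 10), np.uint8)
        m[4, 7] = 1
        (ann,) = sm.circumscribed_circles(m)
        assert ann.center == (7.0, 4.0)
        assert ann.radius == pytest.approx(0.5)

    def test_disk_radius_recovered(self):
        m = np.zeros((40, 40), np.uint8)
        rr, cc = disk((20, 20), 10)
        m[rr, cc] = 1
        (ann,) = sm.circumscribed_circles(m)
        assert ann.center[0] == pytest.approx(20, abs=1)
        assert ann.center[1] == pytest.approx(20, abs=1)
        assert ann.radius == pytest.approx(10, abs=1)

    def test_component_count_and_empty(self):
        m = np.zeros((20, 20), np.uint8)
        m[2:5, 2:5] = 1
        m[12:15, 12:16] = 1
        assert len(sm.circumscribed_circles(m)) == 2
        assert sm.circumscribed_circles(np.zeros((5, 5), np.uint8)) == []
        # diagonal pixels stay one 8-connected component
        d = np.eye(6, dtype=np.uint8)
        assert len(sm.circumscribed_circles(d)) == 1

    def test_every_pixel_enclosed_on_random_blobs(self, rng):
        for _ in range(100):
            m = np.zeros((25, 25), np.uint8)
            n_seeds = int(rng.integers(1, 4))
            for _ in range(n_seeds):
                y, x = rng.integers(3, 22, 2)
                rr, cc = disk((int(y), int(x)), int(rng.integers(1, 5)), shape=m.shape)
                m[rr, cc] = 1
            anns = sm.circumscribed_circles(m)
            from skimage.measure import label as cc_label
            labels = cc_label(m, connectivity=2)
            assert len(anns) == labels.max()
            for ann in anns:
                cx, cy = ann.center
                dists = []
                for lab in range(1, labels.max() + 1):
                    ys, xs = np.nonzero(labels == lab)
                    dists.append(np.hypot(xs - cx, ys - cy).max())
                assert min(dists) <= ann.radius + 1e-6


class TestOverlay:
    def test_pure_blue_and_red_tints(self, rng):
        frame = rng.integers(0, 256, (10, 12, 3)).astype(np.uint8)
        blue = sm.gradation_overlay(frame, np.zeros((10, 12)), alpha=1.0)
        assert (blue[..., 2] == 255).all() and (blue[..., 0] == 0).all()
        red = sm.gradation_overlay(frame, np.ones((10, 12)), alpha=1.0)
        assert (red[..., 0] == 255).all() and (red[..., 2] == 0).all()
        out = sm.gradation_overlay(frame, rng.random((10, 12)))
        assert out.shape == frame.shape and out.dtype == np.uint8
        with pytest.raises(ValueError):
            sm.gradation_overlay(frame, np.zeros((5, 5)))


class TestEvaluateDataset:
    def _maps_from_masks(self, masks: MaskSet) -> np.ndarray:
        return masks.stacked().astype(np.float64)

    def make_truth(self, rng):
        h, w = 24, 32
        cornea = np.zeros((h, w), np.uint8)
        rr, cc = disk((12, 16), 8, shape=(h, w))
        cornea[rr, cc] = 1
        tips = np.zeros((h, w), np.uint8)
        tips[5:7, 5:7] = 1
        return MaskSet(cornea, tips, np.zeros((h, w), np.uint8))

    def test_perfect_predictions_score_100(self, rng):
        truths = [self.make_truth(rng) for _ in range(4)]
        preds = [self._maps_from_masks(t) for t in truths]
        summary = sm.evaluate_dataset(preds, truths)
        assert np.allclose(summary.acc_table.to_numpy(), 100.0)
        # frames whose incision truth is empty are tracked separately
        assert summary.both_empty_counts["incision"] == 4
        assert np.isnan(summary.acc_table_nonempty.loc["incision"].to_numpy()).all()

    def test_empty_predictions_fail_nonempty_truths(self, rng):
        truths = [self.make_truth(rng) for _ in range(3)]
        preds = [np.zeros((24, 32, 3)) for _ in truths]
        summary = sm.evaluate_dataset(preds, truths)
        assert np.allclose(summary.acc_table.loc["cornea"].to_numpy(), 0.0)

    def test_hand_built_table(self, rng):
        """Five frames with known per-frame IoUs produce the hand-counted table."""
        h, w = 10, 10
        truths, preds = [], []
        overlaps = [10, 8, 6, 4, 0]   # predicted rows out of a 10-row truth strip
        for k in overlaps:
            t = np.zeros((h, w), np.uint8)
            t[:, 0] = 1                       # 10-px column
            p = np.zeros((h, w), np.uint8)
            p[:k, 0] = 1
            truths.append(MaskSet(t, np.zeros_like(t), np.zeros_like(t)))
            m = np.zeros((h, w, 3))
            m[..., 0] = p
            preds.append(m)
        summary = sm.evaluate_dataset(preds, truths, n_grid=(0.5, 0.8))
        # IoUs are 1.0, 0.8, 0.6, 0.4, 0.0 -> ACC(0.5)=60%, ACC(0.8)=40%
        assert summary.acc_table.loc["cornea", 0.5] == pytest.approx(60.0)
        assert summary.acc_table.loc["cornea", 0.8] == pytest.approx(40.0)
        with pytest.raises(ValueError):
            sm.evaluate_dataset(preds[:2], truths)
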