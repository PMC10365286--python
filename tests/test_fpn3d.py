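import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulmo3d.backbone import BackboneConfig
from pulmo3d.fpn3d import (Cube, DetectorConfig, FPN3D, anchors_for_level,
                           assign_anchors, decode_boxes, detection_loss,
                           encode_boxes, iou_cube, iou_cubes, nms3d,
                           sliding_window_detect, window_starts)
from pulmo3d.io_formats import Candidate, CTVolume, IntensitySpace


class TestIoU:
    def test_identical_cubes(self):
        c = Cube(center=(1, 2, 3), side=6)
        assert iou_cube(c, c) == pytest.approx(1.0)

    def test_disjoint_cubes(self):
        a = Cube(center=(0, 0, 0), side=4)
        b = Cube(center=(50, 0, 0), side=4)
        assert iou_cube(a, b) == 0.0

    def test_half_offset_on_one_axis(self):
        a = Cube(center=(0, 0, 0), side=10)
        b = Cube(center=(5, 0, 0), side=10)
        assert iou_cube(a, b) == pytest.approx(1 / 3)  # 500 / 1500

    def test_symmetry(self, rng):
        a = rng.uniform(0, 20, size=(5, 4)) + [0, 0, 0, 1]
        b = rng.uniform(0, 20, size=(6, 4)) + [0, 0, 0, 1]
        np.testing.assert_allclose(iou_cubes(a, b), iou_cubes(b, a).T)


class TestAssignment:
    CFG = DetectorConfig.tiny()

    def _plain_cfg(self):
        cfg = DetectorConfig.tiny()
        cfg.force_match = False
        return cfg

    def test_no_truths_all_negative(self):
        anchors = anchors_for_level((4, 4, 4), 2, [3, 5])
        labels, matched = assign_anchors(anchors, np.empty((0, 4)), self.CFG)
        assert (labels == 0).all() and (matched == -1).all()

    def test_coincident_anchor_positive(self):
        anchors = np.array([[8.0, 8.0, 8.0, 10.0]])
        truths = np.array([[8.0, 8.0, 8.0, 10.0]])
        labels, matched = assign_anchors(anchors, truths, self._plain_cfg())
        assert labels[0] == 1 and matched[0] == 0

    def test_intermediate_iou_ignored(self):
        # side-10 cubes offset 5 on one axis: IoU = 1/3, inside (0.02, 0.4]
        anchors = np.array([[5.0, 0.0, 0.0, 10.0]])
        truths = np.array([[0.0, 0.0, 0.0, 10.0]])
        labels, _ = assign_anchors(anchors, truths, self._plain_cfg())
        assert labels[0] == -1

    def test_tiny_overlap_negative(self):
        anchors = np.array([[9.9, 0.0, 0.0, 10.0]])
        truths = np.array([[0.0, 0.0, 0.0, 10.0]])
        assert iou_cube(Cube((9.9, 0, 0), 10), Cube((0, 0, 0), 10)) < 0.02
        labels, _ = assign_anchors(anchors, truths, self._plain_cfg())
        assert labels[0] == 0

    def test_force_match_rescues_orphan_truth(self):
        cfg = DetectorConfig.tiny()
        anchors = anchors_for_level((8, 8, 8), 4, [5, 10])
        truths = np.array([[15.0, 15.0, 15.0, 7.0]])  # between anchor sides
        plain, _ = assign_anchors(anchors, truths, self._plain_cfg())
        assert (plain == 1).sum() == 0
        forced, _ = assign_anchors(anchors, truths, cfg)
        assert (forced == 1).sum() == 1


class TestBoxCoding:
    def test_zero_offsets_decode_to_anchor(self):
        anchor = np.array([[4.0, 6.0, 8.0, 10.0]])
        decoded = decode_boxes(anchor, np.zeros((1, 4)))
        np.testing.assert_allclose(decoded, anchor)

    def test_log2_size_offset_doubles_side(self):
        anchor = np.array([[0.0, 0.0, 0.0, 5.0]])
        decoded = decode_boxes(anchor, np.array([[0, 0, 0, np.log(2)]]))
        assert decoded[0, 3] == pytest.approx(10.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.tuples(*[st.floats(-20, 20) for _ in range(3)]),
           st.floats(1.0, 30.0))
    def test_encode_decode_round_trip(self, center, side):
        anchor = np.array([[5.0, 5.0, 5.0, 8.0]])
        truth = np.array([[*center, side]])
        out = decode_boxes(anchor, encode_boxes(anchor, truth))
        np.testing.assert_allclose(out, truth, atol=1e-9)


class TestDetectionLoss:
    def test_perfect_predictions_zero_loss(self):
        labels = np.array([1, 0], dtype=np.int8)
        logits = np.array([60.0, -60.0], dtype=np.float32)
        reg = np.array([[0.1, 0.2, 0.3, 0.0], [0, 0, 0, 0]], dtype=np.float32)
        targets = reg.copy()
        (lc, lr, lt), _ = detection_loss(logits, reg, labels, targets)
        assert lt == pytest.approx(0.0, abs=1e-9)

    def test_all_ignored_zero_loss_with_warning(self, caplog):
        labels = np.array([-1, -1], dtype=np.int8)
        with caplog.at_level(logging.WARNING):
            (lc, lr, lt), (dc, dr) = detection_loss(
                np.zeros(2, np.float32), np.zeros((2, 4), np.float32),
                labels, np.zeros((2, 4)))
        assert lt == 0.0 and not dc.any() and not dr.any()
        assert any("no anchors" in r.message for r in caplog.records)

    def test_two_anchor_hand_case(self):
        """One positive with an offset error, one negative: each term equals
        direct scalar arithmetic."""
        labels = np.array([1, 0], dtype=np.int8)
        logits = np.array([0.0, 0.0], dtype=np.float32)
        reg = np.array([[0.5, 0, 0, 0], [0, 0, 0, 0]], dtype=np.float32)
        targets = np.zeros((2, 4))
        (lc, lr, lt), _ = detection_loss(logits, reg, labels, targets)
        assert lc == pytest.approx(np.log(2))          # BCE at p=0.5, both anchors
        assert lr == pytest.approx(0.5 * 0.25 / 4)      # smooth-L1 mean over 4 dims
        assert lt == pytest.approx(lc + lr)

    def test_no_positives_zero_reg_term(self):
        labels = np.array([0, 0], dtype=np.int8)
        (_, lr, _), _ = detection_loss(np.zeros(2, np.float32),
                                       np.ones((2, 4), np.float32),
                                       labels, np.zeros((2, 4)))
        assert lr == 0.0


class TestNMS:
    def _cand(self, x, score, d=6.0):
        return Candidate(center_world=(x, 0, 0), diameter_mm=d, score=score)

    def test_single_candidate_kept(self):
        c = self._cand(0, 0.5)
        assert nms3d([c], 0.1) == [c]

    def test_coincident_keeps_higher_score(self):
        a, b = self._cand(0, 0.9), self._cand(0, 0.8)
        assert nms3d([b, a], 0.1) == [a]

    def test_chain_below_threshold_all_kept(self):
        chain = [self._cand(9 * i, 0.9 - 0.1 * i) for i in range(4)]
        # adjacent IoU: overlap 6-(9-6)... side 6 cubes 9 apart are disjoint
        assert nms3d(chain, 0.1) == chain

    def test_output_properties(self, rng):
        cands = [self._cand(float(rng.uniform(0, 30)),
                            float(rng.uniform(0, 1))) for _ in range(20)]
        kept = nms3d(cands, 0.2)
        assert all(c in cands for c in kept)
        scores = [c.score for c in kept]
        assert scores == sorted(scores, reverse=True)
        cubes = np.array([[c.center_world[2], c.center_world[1],
                           c.center_world[0], c.diameter_mm] for c in kept])
        iou = iou_cubes(cubes, cubes)
        np.fill_diagonal(iou, 0.0)
        assert iou.max(initial=0.0) <= 0.2 + 1e-12


class TestWindows:
    def test_small_volume_single_window(self):
        assert window_starts(64, 96, 32) == [0]

    def test_tiling_matches_enumeration(self):
        assert window_starts(160, 96, 32) == [0, 64]
        assert window_starts(200, 96, 32) == [0, 64, 104]
        # oracle: every voxel covered, last window flush with the edge
        for size in (96, 130, 160, 223):
            starts = window_starts(size, 96, 32)
            covered = np.zeros(size, bool)
            for s in starts:
                covered[s:s + 96] = True
            assert covered.all() and starts[-1] + 96 >= size

    def test_small_volume_detection_runs_one_padded_window(self):
        cfg = DetectorConfig.tiny()
        cfg.input_window = 96
        vol = CTVolume(data=np.full((64, 64, 64), 50, np.float32),
                       spacing=(1, 1, 1),
                       intensity_space=IntensitySpace.GRAY255)
        model = FPN3D(cfg, seed=0)
        cands = sliding_window_detect(vol, model, cfg)  # must not raise
        assert isinstance(cands, list)


def test_pyramid_geometry_full_config():
    """On a 96^3 input the stages are 96,48,24,12,6 cubed and every pyramid
    level carries the configured 64 channels."""
    cfg = DetectorConfig(
        input_window=96, pyramid_channels=64,
        backbone=BackboneConfig(widths=(4, 4, 8, 8, 16), blocks_per_stage=0))
    model = FPN3D(cfg, seed=0)
    x = np.zeros((1, 1, 96, 96, 96), dtype=np.float32)
    cs = model.backbone.forward(x, train=False)
    assert [c.shape[2] for c in cs] == [96, 48, 24, 12, 6]
    model.forward(x, train=False)
    p_shapes = model._p_shapes
    assert [p_shapes[i][1] for i in range(4)] == [64, 64, 64, 64]
    assert [p_shapes[i][2] for i in range(4)] == [48, 24, 12, 6]


def test_anchor_level_grouping():
    cfg = DetectorConfig()
    assert cfg.anchor_levels() == [[3, 5], [10, 15], [20, 25], [30]]
    tiny = DetectorConfig.tiny()
    assert tiny.anchor_levels() == [[3, 5], [10], [], []]
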