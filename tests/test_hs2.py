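import numpy as np
import pytest

import pulmo3d.hs2 as hs2mod
from pulmo3d.froc_eval import froc_sensitivities, match_candidates
from pulmo3d.hs2 import (HS2Config, HS2Net, classify_candidates,
                         filter_positives, train_hs2, _balance)
from pulmo3d.io_formats import Candidate, CandidateLabel, NoduleAnnotation
from pulmo3d.lhi import LHIPatch


def _patch(img=None, threshold=30.0, rng=None, bright="left"):
    if img is None:
        img = np.zeros((48, 48), dtype=np.float32)
        if rng is not None:
            img += rng.uniform(0, 1, size=(48, 48))
        sl = np.s_[:, :20] if bright == "left" else np.s_[:, 28:]
        img[sl] += 8.0
        img = np.clip(img, 0, 10)
    return LHIPatch(image=img.astype(np.float32), threshold=threshold)


class TestTraining:
    def test_balance_undersamples_majority(self, rng):
        x = np.zeros((210, 1, 4, 4), dtype=np.float32)
        y = np.array([1] * 10 + [0] * 200)
        xb, yb = _balance(x, y, rng)
        counts = np.bincount(yb)
        assert counts[1] == 10
        assert abs(int(counts[0]) - 10) <= 1

    def test_single_class_rejected(self, rng):
        patches = [_patch(rng=rng) for _ in range(6)]
        with pytest.raises(ValueError):
            train_hs2(patches, ["nodule"] * 6)

    def test_separable_patches_memorized(self, rng):
        """Left-bright vs right-bright LHIs: a capacity check the network
        must pass with 100% training accuracy (augmentation off, since
        flips exchange the classes)."""
        patches = [_patch(rng=rng, bright="left") for _ in range(8)] + \
                  [_patch(rng=rng, bright="right") for _ in range(8)]
        labels = ["nodule"] * 8 + ["tissue"] * 8
        cfg = HS2Config(epochs=12, augment=False, batch_size=8)
        model, losses = train_hs2(patches, labels, cfg, seed=0)
        probs = hs2mod.predict_proba(model, patches)
        pred = probs >= 0.5
        truth = np.array([l == "nodule" for l in labels])
        assert (pred == truth).all()
        assert losses[-1] < losses[0]


class _ConstantProba:
    """Stand-in classifier wiring a fixed P(nodule) through the filter."""

    def __init__(self, p):
        self.p = p


def _patched_predict(monkeypatch, p):
    monkeypatch.setattr(hs2mod, "predict_proba",
                        lambda model, patches, batch_size=64:
                        np.full(len(patches), p))


def _cands(n=4, uid="s"):
    return [Candidate(center_world=(float(i * 10), 0, 0), diameter_mm=6,
                      score=0.5 + 0.1 * i, seriesuid=uid) for i in range(n)]


class TestClassify:
    def test_probability_exactly_half_is_nodule(self, monkeypatch):
        _patched_predict(monkeypatch, 0.5)
        cands = _cands(1)
        out = classify_candidates(cands, [[_patch()]], _ConstantProba(0.5))
        assert out[0].label is CandidateLabel.NODULE

    def test_count_coordinates_scores_preserved(self, monkeypatch, rng):
        _patched_predict(monkeypatch, 0.1)
        cands = _cands(5)
        out = classify_candidates(cands, [[_patch()]] * 5, _ConstantProba(0.1))
        assert len(out) == len(cands)
        for before, after in zip(cands, out):
            assert after.center_world == before.center_world
            assert after.score == before.score
            assert after.label is CandidateLabel.TISSUE

    def test_candidate_without_patch_left_unfiltered(self, monkeypatch,
                                                     caplog):
        _patched_predict(monkeypatch, 0.9)
        out = classify_candidates(_cands(2), [[_patch()], []],
                                  _ConstantProba(0.9))
        assert out[0].label is CandidateLabel.NODULE
        assert out[1].label is CandidateLabel.UNFILTERED

    def test_mismatched_patch_lists_rejected(self):
        with pytest.raises(ValueError):
            classify_candidates(_cands(2), [[_patch()]], _ConstantProba(1.0))


class TestFilteringInvariants:
    def _setup(self):
        truths = {"s": [NoduleAnnotation(center_world=(0, 0, 0),
                                         diameter_mm=6),
                        NoduleAnnotation(center_world=(30, 0, 0),
                                         diameter_mm=6)]}
        cands = {"s": [Candidate(center_world=(0, 0, 0), diameter_mm=6,
                                 score=0.9, seriesuid="s"),
                       Candidate(center_world=(30, 0, 0), diameter_mm=6,
                                 score=0.8, seriesuid="s"),
                       Candidate(center_world=(60, 0, 0), diameter_mm=6,
                                 score=0.7, seriesuid="s")]}
        return cands, truths

    def test_always_nodule_classifier_is_froc_identity(self, monkeypatch):
        _patched_predict(monkeypatch, 1.0)
        cands, truths = self._setup()
        labelled = classify_candidates(cands["s"], [[_patch()]] * 3,
                                       _ConstantProba(1.0))
        filtered = {"s": filter_positives(labelled)}
        base = froc_sensitivities(match_candidates(cands, truths))
        after = froc_sensitivities(match_candidates(filtered, truths))
        assert base.sensitivities == after.sensitivities
        assert base.cpm == after.cpm

    def test_filtering_never_creates_candidates(self, monkeypatch):
        _patched_predict(monkeypatch, 0.0)
        cands, _ = self._setup()
        labelled = classify_candidates(cands["s"], [[_patch()]] * 3,
                                       _ConstantProba(0.0))
        assert len(labelled) == 3
        assert filter_positives(labelled) == []


def test_config_validation():
    with pytest.raises(ValueError):
        HS2Config(decision_threshold=1.5)
    with pytest.raises(ValueError):
        HS2Config(conv_channels=(0, 50))


def test_network_output_shape(rng):
    cfg = HS2Config(conv_channels=(4, 6), fc_widths=(32, 16, 8))
    net = HS2Net(cfg, rng)
    out = net.forward(rng.normal(size=(3, 1, 48, 48)).astype(np.float32),
                      train=False)
    assert out.shape == (3, 2)
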