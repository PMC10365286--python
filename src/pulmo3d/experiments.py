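"""Reproducible desk-scale experiments on seeded phantoms.

These drivers define the study conditions under which the pipeline is
exercised end to end on one CPU core: phantom geometry, nodule/vessel
populations, train/test splits and network configurations. Both the test
suite and the results-reproduction script call them, so the numbers they
produce are always recomputed from scratch.

Conditions (fixed once):
* Detection phantoms: 64x64x64 voxels at 1 mm, parenchyma gray 50, Gaussian
  noise sd 8; one to three nodules of 4-12 mm diameter and contrast ~120;
  two to four vessel-like tubes of 1.5-2.5 mm radius, contrast ~100,
  drifting 1-3 voxels per slice in a random lateral direction.
* Pretext phantoms: 32x32x32 voxels with the chest envelope (body wall,
  lung fields, posterior spine marker) plus one or two nodules, so axial
  rotations are identifiable from anatomy.
* Candidate sequences: 11-slice stacks, disc radius 4-10 px; tissue drift
  magnitude 1-3 px per slice, uniformly random direction.
"""

from __future__ import annotations

import numpy as np

from .fpn3d import DetectorConfig, sliding_window_detect, train_detector
from .froc_eval import FP_LEVELS, froc_sensitivities, match_candidates
from .hs2 import (HS2Config, classify_candidates, filter_positives, train_hs2)
from .io_formats import CTVolume, NoduleAnnotation
from .lhi import LHIConfig, extract_lhi_patch, stack_lhi_patches
from .phantom import (CandidateSequence, NoduleSpec, PhantomSpec, VesselSpec,
                      generate_phantom, make_candidate_sequence)
from .pretext_rotation import (RotationTaskConfig, rotation_accuracy,
                               train_pretext)
from .backbone import BackboneConfig


# ---------------------------------------------------------------------------
# phantom populations
# ---------------------------------------------------------------------------

def sample_detection_spec(rng: np.random.Generator, *, shape=(64, 64, 64),
                          seed: int | None = None) -> PhantomSpec:
    """One detection phantom: nodules plus drifting vessel distractors."""
    n_nod = int(rng.integers(1, 4))
    n_ves = int(rng.integers(2, 5))
    nodules = []
    for _ in range(n_nod):
        center = rng.uniform(14, shape[0] - 14, size=3)  # world mm == voxels
        nodules.append(NoduleSpec(center=tuple(center[::-1]),
                                  diameter_mm=float(rng.uniform(4, 12)),
                                  contrast=float(rng.uniform(100, 140))))
    vessels = []
    for _ in range(n_ves):
        theta = rng.uniform(0, 2 * np.pi)
        mag = rng.uniform(1.0, 3.0) / shape[0] * 64  # ~1-3 px/slice
        vessels.append(VesselSpec(
            start=(float(rng.uniform(8, shape[2] - 8)),
                   float(rng.uniform(8, shape[1] - 8))),
            radius_mm=float(rng.uniform(1.5, 2.5)),
            contrast=float(rng.uniform(80, 110)),
            drift=(float(mag * np.cos(theta)), float(mag * np.sin(theta)))))
    return PhantomSpec(shape=shape, nodules=nodules, vessels=vessels,
                       seed=int(seed if seed is not None
                                else rng.integers(2 ** 31)))


def make_detection_phantoms(n: int, seed: int, shape=(64, 64, 64)
                            ) -> list[tuple[CTVolume, list[NoduleAnnotation]]]:
    rng = np.random.default_rng(seed)
    return [generate_phantom(sample_detection_spec(rng, shape=shape))
            for _ in range(n)]


def make_pretext_phantoms(n: int, seed: int, shape=(32, 32, 32)
                          ) -> list[CTVolume]:
    """Chest-envelope phantoms whose anatomy encodes axial orientation."""
    rng = np.random.default_rng(seed)
    volumes = []
    for _ in range(n):
        n_nod = int(rng.integers(1, 3))
        nodules = [NoduleSpec(center=tuple(rng.uniform(10, shape[0] - 10,
                                                       size=3)[::-1]),
                              diameter_mm=float(rng.uniform(3, 8)))
                   for _ in range(n_nod)]
        spec = PhantomSpec(shape=shape, body=True, nodules=nodules,
                           seed=int(rng.integers(2 ** 31)))
        volumes.append(generate_phantom(spec)[0])
    return volumes


def make_sequence_dataset(n: int, seed: int, lhi_cfg: LHIConfig | None = None
                          ) -> tuple[list, list[str]]:
    """n candidate sequences (half nodule, half tissue) -> LHI patches+labels.

    Each sequence contributes one patch per configured difference threshold,
    labelled with the sequence's true class.
    """
    lhi_cfg = lhi_cfg or LHIConfig()
    rng = np.random.default_rng(seed)
    patches, labels = [], []
    for i in range(n):
        kind = "nodule" if i % 2 == 0 else "tissue"
        theta = rng.uniform(0, 2 * np.pi)
        mag = rng.uniform(1.0, 3.0)
        seq = make_candidate_sequence(
            kind, radius_px=float(rng.uniform(4, 10)),
            drift=(float(mag * np.cos(theta)), float(mag * np.sin(theta))),
            seed=int(rng.integers(2 ** 31)))
        for patch in stack_lhi_patches(seq.stack, lhi_cfg):
            patches.append(patch)
            labels.append(kind)
    return patches, labels


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def pretext_experiment(n_train: int = 30, n_test: int = 10, seed: int = 0,
                       cfg: RotationTaskConfig | None = None) -> dict:
    """Train the rotation classifier and score held-out rotation accuracy."""
    cfg = cfg or RotationTaskConfig.desk()
    train = make_pretext_phantoms(n_train, seed=seed + 11)
    test = make_pretext_phantoms(n_test, seed=seed + 13)
    model, losses = train_pretext(train, cfg, seed=seed)
    return {"model": model,
            "train_loss": losses,
            "train_accuracy": rotation_accuracy(model, train, cfg),
            "test_accuracy": rotation_accuracy(model, test, cfg)}


def hs2_experiment(n_train: int = 200, n_test: int = 100, seed: int = 0,
                   cfg: HS2Config | None = None,
                   lhi_cfg: LHIConfig | None = None) -> dict:
    """Train HS2 on synthetic nodule/tissue LHI patches; held-out accuracy.

    ``n_train``/``n_test`` count patches; each simulated sequence yields one
    patch per configured difference threshold.
    """
    cfg = cfg or HS2Config()
    lhi_cfg = lhi_cfg or LHIConfig()
    per_seq = len(lhi_cfg.diff_thresholds)
    train_patches, train_labels = make_sequence_dataset(
        n_train // per_seq, seed=seed + 21, lhi_cfg=lhi_cfg)
    test_patches, test_labels = make_sequence_dataset(
        n_test // per_seq, seed=seed + 23, lhi_cfg=lhi_cfg)
    model, losses = train_hs2(train_patches, train_labels, cfg, seed=seed)
    from .hs2 import predict_proba
    probs = predict_proba(model, test_patches)
    pred = probs >= cfg.decision_threshold
    truth = np.asarray([lab == "nodule" for lab in test_labels])
    return {"model": model, "train_loss": losses,
            "test_accuracy": float(np.mean(pred == truth))}


def detect_all(model, phantoms, cfg: DetectorConfig):
    """Run detection over phantoms; returns candidates/truths keyed by scan."""
    cands, truths = {}, {}
    for i, (vol, anns) in enumerate(phantoms):
        uid = f"scan{i:03d}"
        cands[uid] = sliding_window_detect(vol, model, cfg, seriesuid=uid)
        truths[uid] = anns
    return cands, truths


def hs2_patches_from_detections(model, phantoms, cfg: DetectorConfig,
                                lhi_cfg: LHIConfig | None = None
                                ) -> tuple[list, list[str]]:
    """Label the detector's own candidates on ``phantoms`` for HS2 training.

    Candidates hitting a ground-truth nodule (centre within its radius)
    become "nodule" patches, the rest "tissue", each extracted through the
    same LHI path used at inference — so the classifier trains on exactly
    the patch distribution it will filter.
    """
    lhi_cfg = lhi_cfg or LHIConfig()
    patches, labels = [], []
    for vol, anns in phantoms:
        cands = sliding_window_detect(vol, model, cfg)
        centers = np.asarray([a.center_world for a in anns], dtype=float)
        radii = np.asarray([a.diameter_mm / 2 for a in anns])
        for c in cands:
            if len(anns):
                dist = np.linalg.norm(centers - np.asarray(c.center_world),
                                      axis=1)
                is_hit = bool((dist < radii).any())
            else:
                is_hit = False
            for patch in extract_lhi_patch(vol, c, lhi_cfg):
                patches.append(patch)
                labels.append("nodule" if is_hit else "tissue")
    return patches, labels


def detection_experiment(n_train: int = 30, n_test: int = 10, seed: int = 0,
                         cfg: DetectorConfig | None = None,
                         with_hs2: bool = False,
                         hs2_cfg: HS2Config | None = None,
                         lhi_cfg: LHIConfig | None = None,
                         init_backbone: dict | None = None) -> dict:
    """Train the tiny detector on phantoms and evaluate FROC on held-out ones.

    With ``with_hs2`` the classifier is trained on the detector's own
    training-set candidates, test-set candidates are filtered, and both
    FROC curves plus FP counts are reported.
    """
    cfg = cfg or DetectorConfig.tiny()
    lhi_cfg = lhi_cfg or LHIConfig()
    train = make_detection_phantoms(n_train, seed=seed + 31)
    test = make_detection_phantoms(n_test, seed=seed + 33)
    model, history = train_detector(train, cfg, seed=seed,
                                    init_backbone=init_backbone)
    cands, truths = detect_all(model, test, cfg)
    match = match_candidates(cands, truths)
    froc = froc_sensitivities(match)
    result = {"model": model, "train_history": history,
              "test_phantoms": test, "candidates": cands, "truths": truths,
              "froc": froc}
    if with_hs2:
        train_patches, train_labels = hs2_patches_from_detections(
            model, train, cfg, lhi_cfg)
        if len(set(train_labels)) < 2:
            # degenerate detector output (no hits or no misses): fall back
            # to simulated sequences so the experiment still completes
            train_patches, train_labels = make_sequence_dataset(
                100, seed=seed + 53, lhi_cfg=lhi_cfg)
        hs2_model, _ = train_hs2(train_patches, train_labels, hs2_cfg,
                                 seed=seed + 53)
        result["hs2_model"] = hs2_model
        filtered = {}
        for i, (vol, _) in enumerate(test):
            uid = f"scan{i:03d}"
            plists = [extract_lhi_patch(vol, c, lhi_cfg) for c in cands[uid]]
            labelled = classify_candidates(cands[uid], plists, hs2_model,
                                           hs2_cfg)
            filtered[uid] = filter_positives(labelled)
        match_f = match_candidates(filtered, truths)
        result["candidates_filtered"] = filtered
        result["froc_filtered"] = froc_sensitivities(match_f)
        result["fp_count_before"] = sum(
            s.count("FP") for s in match.candidate_status.values())
        result["fp_count_after"] = sum(
            s.count("FP") for s in match_f.candidate_status.values())
    return result
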