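"""End-to-end pipeline orchestration and run configuration.

``run_pipeline`` chains the eight stages — simulate, preprocess, pretrain,
train-detector, detect, lhi, filter, evaluate — on seeded phantoms and
writes ``froc.json`` plus a ``manifest.json`` recording the package version,
the configuration hash, the fanned-out per-stage seeds and the completed
stages, so every artifact is reproducible from manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

from . import __version__
from .experiments import (detect_all, hs2_patches_from_detections,
                          make_detection_phantoms, make_pretext_phantoms,
                          make_sequence_dataset)
from .fpn3d import DetectorConfig, train_detector
from .froc_eval import froc_sensitivities, match_candidates, stratified_cpm
from .hs2 import HS2Config, classify_candidates, filter_positives, train_hs2
from .lhi import LHIConfig, extract_lhi_patch
from .preprocess import PreprocessConfig, resample_isotropic
from .pretext_rotation import RotationTaskConfig, train_pretext

log = logging.getLogger(__name__)

# fixed offsets fanning the global seed out to stages, so any stage can be
# rerun in isolation with the same randomness
SEED_OFFSETS = {"simulate_train": 31, "simulate_test": 33, "pretrain": 41,
                "train_detector": 43, "hs2": 47}

STAGES = ("simulate", "preprocess", "pretrain", "train_detector",
          "detect", "lhi", "filter", "evaluate")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run_output"
    n_train: int = 8
    n_test: int = 4
    pretrain_volumes: int = 12
    hs2_train_patches: int = 120
    use_pretrain: bool = True
    use_hs2: bool = True
    log_level: str = "INFO"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    pretext: RotationTaskConfig = field(default_factory=RotationTaskConfig.desk)
    detector: DetectorConfig = field(default_factory=DetectorConfig.tiny)
    lhi: LHIConfig = field(default_factory=LHIConfig)
    hs2: HS2Config = field(default_factory=HS2Config)

    # -- JSON round trip --------------------------------------------------
    def to_dict(self) -> dict:
        def conv(v):
            if dataclasses.is_dataclass(v):
                return {f.name: conv(getattr(v, f.name))
                        for f in dataclasses.fields(v)}
            if isinstance(v, (list, tuple)):
                return [conv(i) for i in v]
            return v
        return conv(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @staticmethod
    def from_dict(data: dict) -> "RunConfig":
        def build(cls, payload):
            fields = {f.name: f for f in dataclasses.fields(cls)}
            unknown = set(payload) - set(fields)
            if unknown:
                raise ValueError(
                    f"unknown key(s) in {cls.__name__}: {sorted(unknown)}")
            kwargs = {}
            for name, value in payload.items():
                ftype = fields[name].type
                if isinstance(value, dict):
                    sub = _SUBCONFIGS.get(name)
                    if sub is None:
                        raise ValueError(f"unexpected nested object {name!r}")
                    kwargs[name] = build(sub, value)
                elif isinstance(value, list):
                    kwargs[name] = tuple(value)
                else:
                    kwargs[name] = value
            return cls(**kwargs)
        return build(RunConfig, data)

    @staticmethod
    def from_json(text: str) -> "RunConfig":
        return RunConfig.from_dict(json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


from .backbone import BackboneConfig  # noqa: E402  (used by _SUBCONFIGS)

_SUBCONFIGS = {"preprocess": PreprocessConfig, "pretext": RotationTaskConfig,
               "detector": DetectorConfig, "lhi": LHIConfig, "hs2": HS2Config,
               "backbone": BackboneConfig}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full phantom pipeline; returns the evaluation report."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    os.makedirs(cfg.out_dir, exist_ok=True)
    completed: list[dict] = []
    t_start = time.time()

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                out = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            completed.append({"stage": name,
                              "seconds": round(time.time() - t0, 2)})
            log.info("stage %s done (%.1fs)", name, time.time() - t0)
            return out
        return wrap

    seed = cfg.seed
    train, test = stage("simulate")(lambda: (
        make_detection_phantoms(cfg.n_train, seed=seed + SEED_OFFSETS["simulate_train"]),
        make_detection_phantoms(cfg.n_test, seed=seed + SEED_OFFSETS["simulate_test"])))

    def do_preprocess():
        pp = lambda pair: (resample_isotropic(pair[0], cfg.preprocess), pair[1])
        return [pp(p) for p in train], [pp(p) for p in test]
    train, test = stage("preprocess")(do_preprocess)

    init_backbone = None
    if cfg.use_pretrain:
        def do_pretrain():
            vols = make_pretext_phantoms(cfg.pretrain_volumes,
                                         seed=seed + SEED_OFFSETS["pretrain"])
            model, _ = train_pretext(vols, cfg.pretext,
                                     seed=seed + SEED_OFFSETS["pretrain"],
                                     backbone_cfg=cfg.detector.backbone)
            return model.backbone.state_dict()
        init_backbone = stage("pretrain")(do_pretrain)
    else:
        completed.append({"stage": "pretrain", "seconds": 0.0,
                          "skipped": True})

    detector, _history = stage("train_detector")(lambda: train_detector(
        train, cfg.detector, seed=seed + SEED_OFFSETS["train_detector"],
        init_backbone=init_backbone))

    cands, truths = stage("detect")(
        lambda: detect_all(detector, test, cfg.detector))

    def do_lhi():
        patches = {}
        for i, (vol, _) in enumerate(test):
            uid = f"scan{i:03d}"
            patches[uid] = [extract_lhi_patch(vol, c, cfg.lhi)
                            for c in cands[uid]]
        return patches
    patch_map = stage("lhi")(do_lhi)

    if cfg.use_hs2:
        def do_filter():
            # preferred: train on the detector's own training-set candidates;
            # fall back to simulated sequences when those are single-class
            # (e.g. severely under-trained bookkeeping runs)
            tp, tl = hs2_patches_from_detections(detector, train,
                                                 cfg.detector, cfg.lhi)
            if len(set(tl)) < 2:
                log.warning("detection-derived patches are single-class; "
                            "training HS2 on simulated sequences instead")
                tp, tl = make_sequence_dataset(
                    cfg.hs2_train_patches // len(cfg.lhi.diff_thresholds),
                    seed=seed + SEED_OFFSETS["hs2"], lhi_cfg=cfg.lhi)
            hs2_model, _ = train_hs2(tp, tl, cfg.hs2,
                                     seed=seed + SEED_OFFSETS["hs2"])
            filtered = {}
            for uid in cands:
                labelled = classify_candidates(cands[uid], patch_map[uid],
                                               hs2_model, cfg.hs2)
                filtered[uid] = filter_positives(labelled)
            return filtered
        filtered = stage("filter")(do_filter)
    else:
        filtered = cands
        completed.append({"stage": "filter", "seconds": 0.0, "skipped": True})

    def do_evaluate():
        match = match_candidates(cands, truths)
        froc = froc_sensitivities(match)
        report = {"fp_levels": list(froc.fp_levels),
                  "sensitivities": list(froc.sensitivities),
                  "cpm": round(froc.cpm, 3),
                  "strata_cpm": stratified_cpm(match)}
        if cfg.use_hs2:
            match_f = match_candidates(filtered, truths)
            froc_f = froc_sensitivities(match_f)
            report["filtered"] = {
                "sensitivities": list(froc_f.sensitivities),
                "cpm": round(froc_f.cpm, 3),
                "fp_count_before": sum(s.count("FP")
                                       for s in match.candidate_status.values()),
                "fp_count_after": sum(s.count("FP")
                                      for s in match_f.candidate_status.values())}
        return report
    report = stage("evaluate")(do_evaluate)

    manifest = {"package_version": __version__,
                "seed": cfg.seed,
                "stage_seeds": {k: cfg.seed + v for k, v in SEED_OFFSETS.items()},
                "config_hash": cfg.config_hash(),
                "config": cfg.to_dict(),
                "stages": completed,
                "total_seconds": round(time.time() - t_start, 2)}
    with open(os.path.join(cfg.out_dir, "froc.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"report": report, "manifest": manifest}
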