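"""Model checkpoints: a named-parameter map in an .npz archive.

The archive stores every parameter and batch-norm buffer under its dotted
module path, plus a JSON-encoded config blob under ``__config__`` and the
model kind under ``__kind__``.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np


def _config_to_dict(cfg) -> dict:
    if dataclasses.is_dataclass(cfg):
        return {f.name: _config_to_dict(getattr(cfg, f.name))
                for f in dataclasses.fields(cfg)}
    if isinstance(cfg, (list, tuple)):
        return [_config_to_dict(v) for v in cfg]
    return cfg


def save_model(path, model, kind: str, cfg) -> None:
    state = model.state_dict()
    state["__kind__"] = np.asarray(kind)
    state["__config__"] = np.asarray(json.dumps(_config_to_dict(cfg)))
    np.savez(path, **state)


def load_state(path) -> tuple[str, dict, dict]:
    """Returns (kind, config dict, state dict)."""
    with np.load(path, allow_pickle=False) as archive:
        kind = str(archive["__kind__"])
        cfg = json.loads(str(archive["__config__"]))
        state = {k: archive[k] for k in archive.files
                 if not k.startswith("__")}
    return kind, cfg, state


def load_detector(path):
    from .backbone import BackboneConfig
    from .fpn3d import FPN3D, DetectorConfig
    kind, cfg, state = load_state(path)
    if kind != "detector":
        raise ValueError(f"{path} is a {kind!r} checkpoint, not a detector")
    cfg["backbone"] = BackboneConfig(
        widths=tuple(cfg["backbone"]["widths"]),
        blocks_per_stage=cfg["backbone"]["blocks_per_stage"])
    for key in ("anchor_sides", "lr_milestones"):
        cfg[key] = tuple(cfg[key])
    model = FPN3D(DetectorConfig(**cfg))
    model.load_state_dict(state)
    return model


def load_hs2(path):
    from .hs2 import HS2Config, HS2Net
    kind, cfg, state = load_state(path)
    if kind != "hs2":
        raise ValueError(f"{path} is a {kind!r} checkpoint, not an HS2 model")
    for key in ("conv_channels", "fc_widths"):
        cfg[key] = tuple(cfg[key])
    model = HS2Net(HS2Config(**cfg), np.random.default_rng(0))
    model.load_state_dict(state)
    return model


def load_pretext(path):
    from .backbone import BackboneConfig
    from .pretext_rotation import PretextModel, RotationTaskConfig
    kind, cfg, state = load_state(path)
    if kind != "pretext":
        raise ValueError(f"{path} is a {kind!r} checkpoint, not a pretext model")
    backbone = BackboneConfig(widths=tuple(cfg["backbone"]["widths"]),
                              blocks_per_stage=cfg["backbone"]["blocks_per_stage"])
    task = cfg["task"]
    for key in ("angles", "lr_milestones"):
        task[key] = tuple(task[key])
    model = PretextModel(backbone, RotationTaskConfig(**task),
                         np.random.default_rng(0))
    model.load_state_dict(state)
    return model
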