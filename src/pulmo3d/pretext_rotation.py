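"""Self-supervised rotation pretext task.

Each CT volume is rotated in the axial (y, x) plane by 0, 90, 180 and 270
degrees, and a classifier (the detector backbone plus two fully connected
layers) is trained to recognise which rotation was applied. Solving the task
requires orientation-sensitive features of chest anatomy, which then
initialise the detector backbone.

Rotation convention: 90 degrees maps (y, x) -> (x, H-1-y) on every axial
slice; z is untouched. The rotation is a pure voxel permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .backbone import Backbone, BackboneConfig
from .io_formats import CTVolume

log = logging.getLogger(__name__)


@dataclass
class RotationTaskConfig:
    """Training configuration for the rotation-classification pretext task.

    ``reference()`` carries the reference-scale schedule (lr 0.1 halved after epochs 70
    and 85, weight decay 5e-4, 100 epochs, batch 16); ``desk()`` is the
    CPU-scale run used on 32-voxel phantoms.
    """

    k: int = 4
    angles: tuple[int, ...] = (0, 90, 180, 270)
    lr: float = 0.1
    lr_milestones: tuple[int, ...] = (70, 85)
    lr_gamma: float = 0.5
    weight_decay: float = 5e-4
    epochs: int = 100
    batch_size: int = 16
    hidden: int = 64  # width of the first of the two FC head layers

    def __post_init__(self):
        if self.k != len(self.angles):
            raise ValueError("k must equal the number of angles")
        if any(a % 90 for a in self.angles):
            raise ValueError("angles must be multiples of 90 degrees")

    @staticmethod
    def reference() -> "RotationTaskConfig":
        return RotationTaskConfig()

    @staticmethod
    def desk() -> "RotationTaskConfig":
        return RotationTaskConfig(lr=0.02, lr_milestones=(12, 17),
                                  epochs=20, batch_size=16)


def rotate_axial(vol: CTVolume, k: int) -> CTVolume:
    """Rotate every axial slice by k*90 degrees (k in 0..3).

    Lossless voxel permutation; for odd k the y/x spacing components swap.
    """
    if not 0 <= int(k) <= 3:
        raise ValueError(f"rotation class must be in 0..3, got {k}")
    k = int(k)
    data = np.rot90(vol.data, k=-k, axes=(1, 2)).copy()
    sz, sy, sx = vol.spacing
    spacing = (sz, sx, sy) if k % 2 else (sz, sy, sx)
    return CTVolume(data=data, spacing=spacing, origin=vol.origin,
                    intensity_space=vol.intensity_space)


def rotation_loss(probs_per_rotation: np.ndarray) -> float:
    """Mean negative log-probability each rotated copy assigns its own class.

    ``probs_per_rotation`` is (K, K): row r holds the predicted class
    probabilities for the copy rotated by class r. Natural log.
    """
    p = np.asarray(probs_per_rotation, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError(f"expected a (K, K) probability matrix, got {p.shape}")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each probability vector must sum to 1")
    diag = np.diag(p)
    if np.any(diag < 1e-12):
        log.warning("rotation_loss: clamping zero true-class probability")
        diag = np.maximum(diag, 1e-12)
    return float(-np.mean(np.log(diag)))


class PretextModel(nn.Module):
    """Backbone C5 features -> global average pool -> two FC layers -> K."""

    def __init__(self, backbone_cfg: BackboneConfig, cfg: RotationTaskConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.backbone_cfg = backbone_cfg
        self.backbone = Backbone(backbone_cfg, rng)
        self.head = nn.Sequential(
            nn.GlobalAvgPool(),
            nn.Linear(backbone_cfg.widths[-1], cfg.hidden, rng=rng),
            nn.ReLU(),
            nn.Linear(cfg.hidden, cfg.k, rng=rng))

    def forward(self, x, train: bool = True):
        feats = self.backbone.forward(x, train=train)
        return self.head.forward(feats[-1], train=train)

    def backward(self, grad):
        g = self.head.backward(grad)
        return self.backbone.backward([None, None, None, None, g])


def _normalize(data: np.ndarray) -> np.ndarray:
    return (np.asarray(data, dtype=np.float32) / 128.0) - 1.0


def build_rotation_dataset(volumes: list[CTVolume], cfg: RotationTaskConfig
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Expand each volume into its K rotated copies with class labels.

    The result is exactly class balanced: every volume contributes one
    sample per rotation class.
    """
    if not volumes:
        raise ValueError("empty volume list")
    xs, ys = [], []
    for vol in volumes:
        for k in range(cfg.k):
            xs.append(_normalize(rotate_axial(vol, k).data)[None])
            ys.append(k)
    return np.stack(xs), np.asarray(ys, dtype=np.int64)


def train_pretext(volumes: list[CTVolume],
                  cfg: RotationTaskConfig | None = None,
                  seed: int = 0,
                  backbone_cfg: BackboneConfig | None = None
                  ) -> tuple[PretextModel, list[float]]:
    """Train the rotation classifier; returns the model and per-epoch loss."""
    cfg = cfg or RotationTaskConfig.desk()
    backbone_cfg = backbone_cfg or BackboneConfig.tiny()
    x, y = build_rotation_dataset(volumes, cfg)
    rng = np.random.default_rng(seed)
    model = PretextModel(backbone_cfg, cfg, rng)
    opt = nn.SGD(model.parameters(), lr=cfg.lr, momentum=0.9,
                 weight_decay=cfg.weight_decay)
    sched = nn.StepSchedule(cfg.lr, cfg.lr_milestones, cfg.lr_gamma)
    losses = []
    n = x.shape[0]
    for epoch in range(cfg.epochs):
        opt.lr = sched.lr_at(epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model.forward(x[idx], train=True)
            loss, grad = nn.softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / n)
    nn.recalibrate_bn(model, (x[i:i + cfg.batch_size]
                              for i in range(0, n, cfg.batch_size)))
    return model, losses


def predict_rotation(model: PretextModel, volumes: list[CTVolume],
                     cfg: RotationTaskConfig | None = None) -> np.ndarray:
    """Predicted rotation class for each (volume x rotation) sample."""
    cfg = cfg or RotationTaskConfig.desk()
    x, _ = build_rotation_dataset(volumes, cfg)
    preds = []
    for i in range(0, x.shape[0], cfg.batch_size):
        logits = model.forward(x[i:i + cfg.batch_size], train=False)
        preds.append(np.argmax(logits, axis=1))
    return np.concatenate(preds)


def rotation_accuracy(model: PretextModel, volumes: list[CTVolume],
                      cfg: RotationTaskConfig | None = None) -> float:
    cfg = cfg or RotationTaskConfig.desk()
    _, y = build_rotation_dataset(volumes, cfg)
    preds = predict_rotation(model, volumes, cfg)
    return float(np.mean(preds == y))


def transfer_weights(pretext: PretextModel, detector) -> None:
    """Copy backbone weights (and batch-norm stats) into a detector in place."""
    detector.backbone.load_state_dict(pretext.backbone.state_dict())
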