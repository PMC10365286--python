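"""Densely connected 3D feature-pyramid nodule detector.

Architecture
------------
A residual bottom-up backbone yields stages C2..C5 at strides 2..16. Each
stage is projected to a common channel width by a 1x1x1 lateral conv, and
every pyramid level P2..P5 fuses *all four* laterals: coarser levels are
upsampled by learned block-transposed convolutions, finer levels are
max-pooled down, the matching level passes through unchanged. Each pyramid
level carries a 3x3x3 conv tower followed by two sibling 1x1x1 convs: an
objectness (classification) head with one logit per anchor and a regression
head with four offsets per anchor ((dz, dy, dx)/side and log size ratio).

Anchors are cubes of fixed sides tiled over each level at its stride;
anchors are matched to ground-truth cubes by intersection-over-union, with
IoU < 0.02 negative, IoU > 0.4 positive and the band between ignored.
Additionally the single best-overlapping anchor of every ground-truth cube
is forced positive, so nodules whose diameter falls between two anchor
sides still receive a training signal. Training supervises every
non-ignored anchor with class-balanced binary cross-entropy (the positive
class weighted by the negative/positive count ratio) plus smooth-L1
regression on positives. Inference tiles the volume with overlapping
windows, thresholds
the objectness probability at 0.1, maps detections to world millimetres and
merges them with greedy 3D non-maximum suppression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone import Backbone, BackboneConfig
from .io_formats import (Candidate, CTVolume, IntensitySpace,
                         voxel_to_world, world_to_voxel)

log = logging.getLogger(__name__)

PYRAMID_STRIDES = (2, 4, 8, 16)  # P2..P5


@dataclass
class DetectorConfig:
    input_window: int = 96
    pyramid_channels: int = 64
    anchor_sides: tuple[float, ...] = (3, 5, 10, 15, 20, 25, 30)
    iou_neg: float = 0.02
    iou_pos: float = 0.4
    score_threshold: float = 0.1   # applied before NMS
    nms_iou: float = 0.1
    pre_nms_top_k: int = 300       # highest-scoring boxes kept per window
    window_overlap: int = 32
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    force_match: bool = True       # best anchor per truth is always positive
    lr: float = 0.01
    lr_milestones: tuple[int, ...] = (30,)
    lr_gamma: float = 0.1
    weight_decay: float = 1e-4
    epochs: int = 40
    head_channels: int | None = None

    def __post_init__(self):
        if not self.iou_neg < self.iou_pos:
            raise ValueError("iou_neg must be below iou_pos")
        if tuple(sorted(self.anchor_sides)) != tuple(self.anchor_sides):
            raise ValueError("anchor sides must be sorted ascending")
        if self.window_overlap >= self.input_window:
            raise ValueError("window_overlap must be below input_window")

    @staticmethod
    def tiny() -> "DetectorConfig":
        """Desk-scale configuration trainable on one CPU core."""
        return DetectorConfig(input_window=64, pyramid_channels=8,
                              anchor_sides=(3, 5, 10),
                              backbone=BackboneConfig.tiny(),
                              epochs=25, lr=0.02, lr_milestones=(18,))

    def anchor_levels(self) -> list[list[float]]:
        """Assign anchor sides to P2..P5 by receptive-field scale."""
        groups: list[list[float]] = [[], [], [], []]
        for side in self.anchor_sides:
            if side <= 8:
                groups[0].append(side)
            elif side <= 18:
                groups[1].append(side)
            elif side <= 28:
                groups[2].append(side)
            else:
                groups[3].append(side)
        return groups


@dataclass(frozen=True)
class Cube:
    """Axis-aligned cube: centre (z, y, x) in voxels plus side length."""

    center: tuple[float, float, float]
    side: float

    def __post_init__(self):
        if self.side <= 0:
            raise ValueError(f"cube side must be positive, got {self.side}")

    def as_array(self) -> np.ndarray:
        return np.asarray([*self.center, self.side], dtype=np.float64)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def iou_cubes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between cube arrays (M, 4) and (N, 4) -> (M, N)."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    inter = np.ones((a.shape[0], b.shape[0]))
    for ax in range(3):
        lo = np.maximum(a[:, None, ax] - a[:, None, 3] / 2,
                        b[None, :, ax] - b[None, :, 3] / 2)
        hi = np.minimum(a[:, None, ax] + a[:, None, 3] / 2,
                        b[None, :, ax] + b[None, :, 3] / 2)
        inter *= np.clip(hi - lo, 0.0, None)
    vol_a = a[:, 3] ** 3
    vol_b = b[:, 3] ** 3
    union = vol_a[:, None] + vol_b[None, :] - inter
    return inter / union


def iou_cube(a: Cube, b: Cube) -> float:
    return float(iou_cubes(a.as_array(), b.as_array())[0, 0])


def anchors_for_level(feature_shape, stride: int, sides) -> np.ndarray:
    """Anchor cubes (A * D * H * W, 4) tiled over a feature grid.

    Cell (i, j, k) at a given stride sits at input voxel (i + 0.5) * stride
    per axis. Flattening order matches a C-order reshape of an
    (A, D, H, W) map.
    """
    d, h, w = feature_shape
    zz, yy, xx = np.meshgrid((np.arange(d) + 0.5) * stride,
                             (np.arange(h) + 0.5) * stride,
                             (np.arange(w) + 0.5) * stride, indexing="ij")
    grid = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)
    out = []
    for side in sides:
        cubes = np.concatenate(
            [grid, np.full((grid.shape[0], 1), float(side))], axis=1)
        out.append(cubes)
    return np.concatenate(out, axis=0) if out else np.empty((0, 4))


def assign_anchors(anchors: np.ndarray, truths: np.ndarray,
                   cfg: DetectorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Label anchors: 1 positive, 0 negative, -1 ignored; plus matched truth.

    IoU below ``iou_neg`` is negative, above ``iou_pos`` positive (matched to
    the argmax truth), in between ignored. The best anchor of each truth is
    forced positive. With no truths, every anchor is negative.
    """
    m = anchors.shape[0]
    labels = np.zeros(m, dtype=np.int8)
    matched = np.full(m, -1, dtype=np.int64)
    if truths is None or len(truths) == 0:
        return labels, matched
    iou = iou_cubes(anchors, truths)
    best = iou.max(axis=1)
    arg = iou.argmax(axis=1)
    labels[(best >= cfg.iou_neg) & (best <= cfg.iou_pos)] = -1
    pos = best > cfg.iou_pos
    labels[pos] = 1
    matched[pos] = arg[pos]
    if cfg.force_match:
        # the best-overlapping anchor per truth is positive regardless, so a
        # nodule between two anchor sizes still gets a training signal
        for t in range(iou.shape[1]):
            a = int(iou[:, t].argmax())
            labels[a] = 1
            matched[a] = arg[a]
    return labels, matched


def encode_boxes(anchors: np.ndarray, truths: np.ndarray) -> np.ndarray:
    """(dz, dy, dx) / anchor_side and log(truth_side / anchor_side)."""
    anchors = np.atleast_2d(anchors)
    truths = np.atleast_2d(truths)
    off = (truths[:, :3] - anchors[:, :3]) / anchors[:, 3:4]
    size = np.log(truths[:, 3:4] / anchors[:, 3:4])
    return np.concatenate([off, size], axis=1)


def decode_boxes(anchors: np.ndarray, offsets: np.ndarray,
                 max_log_scale: float = 6.0) -> np.ndarray:
    """Inverse of ``encode_boxes``. The size offset is clamped to
    ``max_log_scale`` so an untrained regression head cannot produce
    degenerate (near-zero or enormous) box sides."""
    anchors = np.atleast_2d(anchors)
    offsets = np.atleast_2d(offsets)
    centers = anchors[:, :3] + offsets[:, :3] * anchors[:, 3:4]
    log_scale = np.clip(offsets[:, 3:4], -max_log_scale, max_log_scale)
    sides = anchors[:, 3:4] * np.exp(log_scale)
    return np.concatenate([centers, sides], axis=1)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def detection_loss(cls_logits: np.ndarray, reg_offsets: np.ndarray,
                   labels: np.ndarray, reg_targets: np.ndarray,
                   cls_mask: np.ndarray | None = None,
                   pos_weight: float | None = None):
    """(cls, reg, total) plus gradients w.r.t. logits and offsets.

    BCE runs over anchors selected by ``cls_mask`` (default: every non-
    ignored anchor); smooth-L1 regression runs over positives only. With no
    contributing anchors the loss is zero (logged). ``pos_weight`` rescales
    the positive class in the BCE (training balances the handful of positive
    anchors against the sampled negatives this way).
    """
    labels = np.asarray(labels)
    if cls_mask is None:
        cls_mask = labels >= 0
    dcls = np.zeros_like(cls_logits, dtype=np.float32)
    dreg = np.zeros_like(reg_offsets, dtype=np.float32)
    if not cls_mask.any():
        log.warning("detection_loss: no anchors selected; zero loss")
        return (0.0, 0.0, 0.0), (dcls, dreg)
    sel = (labels[cls_mask] == 1).astype(np.float64)
    weights = None if pos_weight is None else np.where(sel == 1, pos_weight, 1.0)
    cls_loss, g = nn.bce_with_logits(cls_logits[cls_mask], sel, weights)
    dcls[cls_mask] = g
    pos = labels == 1
    if pos.any():
        reg_loss, gr = nn.smooth_l1(reg_offsets[pos], reg_targets[pos])
        dreg[pos] = gr
    else:
        reg_loss = 0.0
    return (float(cls_loss), float(reg_loss), float(cls_loss + reg_loss)), \
        (dcls, dreg)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class _LevelFusion(nn.Module):
    """Fuse the four lateral maps into one pyramid level (dense connectivity)."""

    def __init__(self, level: int, channels: int, rng: np.random.Generator):
        super().__init__()
        self.level = level
        self.ops: list[nn.Module | None] = []
        for src in range(4):
            if src == level:
                op = None  # identity
            elif src > level:
                op = nn.BlockDeconvNd(3, channels, channels,
                                      2 ** (src - level), rng=rng)
            else:
                op = nn.MaxPoolNd(3, 2 ** (level - src))
            self.ops.append(op)
            if op is not None:
                setattr(self, f"from{src}", op)
        self.relu = nn.ReLU()

    def forward(self, laterals, train: bool = True):
        total = None
        for src, op in enumerate(self.ops):
            contrib = laterals[src] if op is None else \
                op.forward(laterals[src], train=train)
            total = contrib if total is None else total + contrib
        return self.relu.forward(total, train=train)

    def backward(self, grad):
        g = self.relu.backward(grad)
        grads = []
        for op in self.ops:
            grads.append(g if op is None else op.backward(g))
        return grads  # aligned with the four laterals


class _Head(nn.Module):
    """3x3x3 conv tower plus sibling 1x1x1 classification/regression convs."""

    def __init__(self, channels: int, n_anchors: int, head_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.n_anchors = n_anchors
        self.tower = nn.Sequential(
            nn.Conv3d(channels, head_channels, 3, padding=1, rng=rng),
            nn.ReLU())
        self.cls = nn.Conv3d(head_channels, n_anchors, 1, rng=rng)
        self.reg = nn.Conv3d(head_channels, 4 * n_anchors, 1, rng=rng)
        # bias objectness towards background so early training is stable
        self.cls.bias.data[...] = -2.0

    def forward(self, x, train: bool = True):
        t = self.tower.forward(x, train=train)
        return self.cls.forward(t, train=train), self.reg.forward(t, train=train)

    def backward(self, grad_cls, grad_reg):
        g = self.cls.backward(grad_cls) + self.reg.backward(grad_reg)
        return self.tower.backward(g)


class FPN3D(nn.Module):
    """The detector network: backbone, laterals, dense fusion, heads."""

    def __init__(self, cfg: DetectorConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        pc = cfg.pyramid_channels
        hc = cfg.head_channels or pc
        self.backbone = Backbone(cfg.backbone, rng)
        widths = cfg.backbone.widths
        for i in range(4):  # laterals for C2..C5
            setattr(self, f"lateral{i}",
                    nn.Conv3d(widths[i + 1], pc, 1, rng=rng))
        self.anchor_groups = cfg.anchor_levels()
        self.active_levels = [i for i, g in enumerate(self.anchor_groups) if g]
        for i in range(4):
            setattr(self, f"fuse{i}", _LevelFusion(i, pc, rng))
        for i in self.active_levels:
            setattr(self, f"head{i}",
                    _Head(pc, len(self.anchor_groups[i]), hc, rng))

    def forward(self, x, train: bool = True):
        """Returns {level: (cls_map, reg_map)} for levels that carry anchors."""
        cs = self.backbone.forward(x, train=train)
        laterals = [getattr(self, f"lateral{i}").forward(cs[i + 1], train=train)
                    for i in range(4)]
        outputs = {}
        self._p_shapes = {}
        for i in range(4):
            p = getattr(self, f"fuse{i}").forward(laterals, train=train)
            self._p_shapes[i] = p.shape
            if i in self.active_levels:
                outputs[i] = getattr(self, f"head{i}").forward(p, train=train)
        return outputs

    def backward(self, grads: dict[int, tuple[np.ndarray, np.ndarray]]):
        lat_grads = [None] * 4
        for i in range(4):
            if i in grads:
                gp = getattr(self, f"head{i}").backward(*grads[i])
            else:
                gp = np.zeros(self._p_shapes[i], dtype=np.float32)
            contribs = getattr(self, f"fuse{i}").backward(gp)
            for src in range(4):
                lat_grads[src] = contribs[src] if lat_grads[src] is None \
                    else lat_grads[src] + contribs[src]
        c_grads = [None] * 5
        for i in range(4):
            c_grads[i + 1] = getattr(self, f"lateral{i}").backward(lat_grads[i])
        return self.backbone.backward(c_grads)


# ---------------------------------------------------------------------------
# training and inference helpers
# ---------------------------------------------------------------------------

def _normalize(data: np.ndarray) -> np.ndarray:
    return (np.asarray(data, dtype=np.float32) / 128.0) - 1.0


def window_starts(size: int, window: int, overlap: int) -> list[int]:
    """Start offsets of sliding windows along one axis (edges clamped)."""
    if size <= window:
        return [0]
    stride = window - overlap
    starts = list(range(0, size - window + 1, stride))
    if starts[-1] != size - window:
        starts.append(size - window)
    return starts


def _window_anchors(cfg: DetectorConfig) -> dict[int, np.ndarray]:
    w = cfg.input_window
    groups = cfg.anchor_levels()
    return {i: anchors_for_level((w // s,) * 3, s, groups[i])
            for i, s in enumerate(PYRAMID_STRIDES) if groups[i]}


def _flatten_maps(outputs: dict[int, tuple[np.ndarray, np.ndarray]],
                  levels) -> tuple[np.ndarray, np.ndarray, list]:
    """Concatenate per-level maps in anchor order; returns split metadata."""
    cls_parts, reg_parts, meta = [], [], []
    for i in levels:
        cls_map, reg_map = outputs[i]
        n, a = cls_map.shape[:2]
        sp = cls_map.shape[2:]
        cls_parts.append(cls_map.reshape(-1))
        reg_parts.append(reg_map.reshape(n, a, 4, *sp)
                         .transpose(0, 1, 3, 4, 5, 2).reshape(-1, 4))
        meta.append((i, cls_map.shape, reg_map.shape))
    return np.concatenate(cls_parts), np.concatenate(reg_parts), meta


def _unflatten_grads(dcls: np.ndarray, dreg: np.ndarray, meta
                     ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    grads = {}
    pos = 0
    for i, cls_shape, reg_shape in meta:
        n, a = cls_shape[:2]
        sp = cls_shape[2:]
        count = int(np.prod(cls_shape))
        g_cls = dcls[pos:pos + count].reshape(cls_shape)
        g_reg = dreg[pos:pos + count].reshape(n, a, *sp, 4) \
            .transpose(0, 1, 5, 2, 3, 4).reshape(reg_shape)
        grads[i] = (np.ascontiguousarray(g_cls), np.ascontiguousarray(g_reg))
        pos += count
    return grads


def _truth_cubes(vol: CTVolume, annotations) -> np.ndarray:
    """Ground-truth nodules as voxel cubes of side = diameter / spacing."""
    cubes = []
    for ann in annotations:
        center = world_to_voxel(ann.center_world, vol)
        side = ann.diameter_mm / float(np.mean(vol.spacing))
        cubes.append([*center, side])
    return np.asarray(cubes, dtype=np.float64).reshape(-1, 4)


def _training_windows(vol: CTVolume, truth_cubes: np.ndarray,
                      cfg: DetectorConfig):
    """Tile a volume into training windows with window-local truth cubes."""
    w = cfg.input_window
    data = _normalize(vol.data)
    nz, ny, nx = data.shape
    windows = []
    for z0 in window_starts(nz, w, cfg.window_overlap):
        for y0 in window_starts(ny, w, cfg.window_overlap):
            for x0 in window_starts(nx, w, cfg.window_overlap):
                patch = data[z0:z0 + w, y0:y0 + w, x0:x0 + w]
                if patch.shape != (w, w, w):
                    padded = np.full((w, w, w), -1.0, dtype=np.float32)
                    padded[:patch.shape[0], :patch.shape[1],
                           :patch.shape[2]] = patch
                    patch = padded
                start = np.asarray([z0, y0, x0], dtype=np.float64)
                if len(truth_cubes):
                    local = truth_cubes.copy()
                    local[:, :3] -= start
                    inside = np.all((local[:, :3] >= 0)
                                    & (local[:, :3] < w), axis=1)
                    local = local[inside]
                else:
                    local = truth_cubes
                windows.append((patch, local, start))
    return windows


def train_detector(samples, cfg: DetectorConfig | None = None, seed: int = 0,
                   init_backbone: dict | None = None
                   ) -> tuple[FPN3D, list[tuple[float, float, float]]]:
    """Train the detector on (volume, annotations) pairs.

    ``init_backbone`` is an optional backbone state dict from the pretext
    model. Returns the model plus per-epoch (cls, reg, total) losses.
    Deterministic for a fixed seed under single-threaded execution.
    """
    cfg = cfg or DetectorConfig.tiny()
    if not samples:
        raise ValueError("no training samples")
    rng = np.random.default_rng(seed)
    model = FPN3D(cfg, seed=int(rng.integers(2 ** 31)))
    if init_backbone is not None:
        model.backbone.load_state_dict(init_backbone)
    anchors_by_level = _window_anchors(cfg)
    levels = sorted(anchors_by_level)
    anchors = np.concatenate([anchors_by_level[i] for i in levels])

    windows = []
    for vol, anns in samples:
        cubes = _truth_cubes(vol, anns)
        windows.extend(_training_windows(vol, cubes, cfg))
    # precompute assignments, regression targets and class weights per window
    prepared = []
    for patch, local_truths, _ in windows:
        labels, matched = assign_anchors(anchors, local_truths, cfg)
        targets = np.zeros((anchors.shape[0], 4), dtype=np.float64)
        pos = labels == 1
        if pos.any():
            targets[pos] = encode_boxes(anchors[pos],
                                        local_truths[matched[pos]])
        n_pos = int(pos.sum())
        n_neg = int((labels == 0).sum())
        prepared.append((patch[None, None], labels, targets,
                         n_neg / max(n_pos, 1)))

    opt = nn.SGD(model.parameters(), lr=cfg.lr, momentum=0.9,
                 weight_decay=cfg.weight_decay)
    sched = nn.StepSchedule(cfg.lr, cfg.lr_milestones, cfg.lr_gamma)
    history = []
    for epoch in range(cfg.epochs):
        opt.lr = sched.lr_at(epoch)
        order = rng.permutation(len(prepared))
        sums = np.zeros(3)
        for wi in order:
            patch, labels, targets, pos_weight = prepared[wi]
            outputs = model.forward(patch, train=True)
            cls_flat, reg_flat, meta = _flatten_maps(outputs, levels)
            # dense supervision: every non-ignored anchor contributes, with
            # the positive class reweighted to balance the negatives
            (lc, lr_, lt), (dcls, dreg) = detection_loss(
                cls_flat, reg_flat, labels, targets, pos_weight=pos_weight)
            opt.zero_grad()
            model.backward(_unflatten_grads(dcls, dreg, meta))
            opt.step()
            sums += (lc, lr_, lt)
        history.append(tuple(sums / len(prepared)))
    nn.recalibrate_bn(model, (p[0] for p in prepared))
    return model, history


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def detect_in_window(model: FPN3D, patch: np.ndarray, cfg: DetectorConfig
                     ) -> np.ndarray:
    """Detections in one window: rows (z, y, x, side, score), window-local."""
    anchors_by_level = _window_anchors(cfg)
    levels = sorted(anchors_by_level)
    anchors = np.concatenate([anchors_by_level[i] for i in levels])
    outputs = model.forward(patch[None, None], train=False)
    cls_flat, reg_flat, _ = _flatten_maps(outputs, levels)
    probs = _sigmoid(cls_flat)
    keep = np.flatnonzero(probs > cfg.score_threshold)
    if keep.size == 0:
        return np.empty((0, 5))
    if keep.size > cfg.pre_nms_top_k:
        keep = keep[np.argsort(probs[keep], kind="stable")[::-1]
                    [:cfg.pre_nms_top_k]]
    boxes = decode_boxes(anchors[keep], reg_flat[keep])
    return np.concatenate([boxes, probs[keep, None]], axis=1)


def sliding_window_detect(vol: CTVolume, model: FPN3D,
                          cfg: DetectorConfig | None = None,
                          seriesuid: str = "") -> list[Candidate]:
    """Run the detector over a whole preprocessed volume."""
    cfg = cfg or model.cfg
    if vol.intensity_space is not IntensitySpace.GRAY255:
        raise ValueError("detector expects a preprocessed GRAY255 volume")
    w = cfg.input_window
    margin = cfg.window_overlap // 2
    data = _normalize(vol.data)
    nz, ny, nx = data.shape
    rows = []
    for z0 in window_starts(nz, w, cfg.window_overlap):
        for y0 in window_starts(ny, w, cfg.window_overlap):
            for x0 in window_starts(nx, w, cfg.window_overlap):
                patch = data[z0:z0 + w, y0:y0 + w, x0:x0 + w]
                if patch.shape != (w, w, w):
                    padded = np.full((w, w, w), -1.0, dtype=np.float32)
                    padded[:patch.shape[0], :patch.shape[1],
                           :patch.shape[2]] = patch
                    patch = padded
                dets = detect_in_window(model, patch, cfg)
                if not len(dets):
                    continue
                dets = dets.copy()
                dets[:, :3] += (z0, y0, x0)
                # each window answers only for its central region (half the
                # overlap as margin, except at the volume border), so a
                # structure in an overlap zone is reported by exactly one
                # window — the one that sees it with the most context
                keep = np.ones(len(dets), dtype=bool)
                for ax, (start, size) in enumerate(((z0, nz), (y0, ny),
                                                    (x0, nx))):
                    lo = start + margin if start > 0 else -np.inf
                    hi = start + w - margin if start + w < size else np.inf
                    keep &= (dets[:, ax] >= lo) & (dets[:, ax] < hi)
                if keep.any():
                    rows.append(dets[keep])
    if not rows:
        return []
    dets = np.concatenate(rows)
    candidates = []
    for z, y, x, side, score in dets:
        world = voxel_to_world((z, y, x), vol)
        candidates.append(Candidate(
            center_world=tuple(world),
            diameter_mm=float(side * np.mean(vol.spacing)),
            score=float(score), seriesuid=seriesuid))
    return nms3d(candidates, cfg.nms_iou)


def _candidate_cubes(cands: list[Candidate]) -> np.ndarray:
    return np.asarray([[c.center_world[2], c.center_world[1],
                        c.center_world[0], c.diameter_mm] for c in cands])


def nms3d(cands: list[Candidate], nms_iou: float = 0.1) -> list[Candidate]:
    """Greedy non-maximum suppression on candidate cubes in world mm.

    Candidates are visited by descending score (ties keep input order); a
    candidate is suppressed when it overlaps an already-kept one with
    IoU > ``nms_iou`` *or* when the two detection spheres intersect
    (centre distance below the sum of the radii) — same-nodule duplicates
    from neighbouring anchors or windows can disagree in box size enough to
    slip under the IoU test alone, while two genuinely distinct nodules
    have disjoint spheres. Output scores are non-increasing.
    """
    if len(cands) <= 1:
        return list(cands)
    cubes = _candidate_cubes(cands)
    order = sorted(range(len(cands)), key=lambda i: (-cands[i].score, i))
    kept: list[int] = []
    for i in order:
        if kept:
            iou = iou_cubes(cubes[i:i + 1], cubes[kept])[0]
            dist = np.linalg.norm(cubes[kept][:, :3] - cubes[i, :3], axis=1)
            radius_sum = (cubes[kept][:, 3] + cubes[i, 3]) / 2
            if np.any((iou > nms_iou) | (dist < radius_sum)):
                continue
        kept.append(i)
    return [cands[i] for i in kept]
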