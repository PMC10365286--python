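"""HS2: the high-sensitivity / high-specificity false-positive-reduction
classifier over location-history-image patches.

A small CNN — two valid 5x5 convolutions (30 and 50 channels, each followed
by ReLU, batch norm and 2x2 max pooling) and three fully connected layers
(2048, 1024, 512) — maps a 48x48 LHI to a two-way softmax over
{nodule, tissue}. Class imbalance is handled by undersampling the majority
(tissue) class to within one sample of the minority; augmentation applies
random flips, 90-degree rotations and 0.9-crops (resized back) each epoch.
At inference, the probabilities of a candidate's patches (one per difference
threshold) are averaged and compared to the decision threshold: candidates
at or above it keep the nodule label, the rest are relabelled tissue. The
filter only changes labels — never coordinates, scores or the list length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import nn
from .io_formats import Candidate, CandidateLabel
from .lhi import LHIPatch

log = logging.getLogger(__name__)

LABEL_TO_INT = {"nodule": 1, "tissue": 0}


@dataclass
class HS2Config:
    conv_channels: tuple[int, int] = (30, 50)
    fc_widths: tuple[int, int, int] = (2048, 1024, 512)
    lr: float = 0.01
    lr_step: int = 500          # divide lr by 10 every lr_step epochs
    epochs: int = 15            # desk-scale run; reference-scale below
    epochs_reference: int = 2000
    batch_size: int = 32
    decision_threshold: float = 0.5
    crop_fraction: float = 0.9
    augment: bool = True
    balance: bool = True
    in_size: int = 48

    def __post_init__(self):
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision threshold must be in (0, 1)")
        if any(w <= 0 for w in self.conv_channels + self.fc_widths):
            raise ValueError("channel and layer widths must be positive")


class HS2Net(nn.Module):
    def __init__(self, cfg: HS2Config, rng: np.random.Generator):
        super().__init__()
        c1, c2 = cfg.conv_channels
        f1, f2, f3 = cfg.fc_widths
        # 48 -> conv5 -> 44 -> pool -> 22 -> conv5 -> 18 -> pool -> 9
        feat = ((cfg.in_size - 4) // 2 - 4) // 2
        self.body = nn.Sequential(
            nn.Conv2d(1, c1, 5, rng=rng), nn.ReLU(), nn.BatchNorm(c1),
            nn.MaxPoolNd(2, 2),
            nn.Conv2d(c1, c2, 5, rng=rng), nn.ReLU(), nn.BatchNorm(c2),
            nn.MaxPoolNd(2, 2),
            nn.Flatten(),
            nn.Linear(c2 * feat * feat, f1, rng=rng), nn.ReLU(),
            nn.Linear(f1, f2, rng=rng), nn.ReLU(),
            nn.Linear(f2, f3, rng=rng), nn.ReLU(),
            nn.Linear(f3, 2, rng=rng))

    def forward(self, x, train: bool = True):
        return self.body.forward(x, train=train)

    def backward(self, grad):
        return self.body.backward(grad)


def _augment_batch(batch: np.ndarray, cfg: HS2Config,
                   rng: np.random.Generator) -> np.ndarray:
    out = batch.copy()
    for i in range(out.shape[0]):
        img = out[i, 0]
        if rng.random() < 0.5:
            img = img[:, ::-1]
        if rng.random() < 0.5:
            img = img[::-1, :]
        img = np.rot90(img, k=int(rng.integers(4)))
        if rng.random() < 0.5:
            side = int(round(cfg.in_size * cfg.crop_fraction))
            y0 = int(rng.integers(cfg.in_size - side + 1))
            x0 = int(rng.integers(cfg.in_size - side + 1))
            img = resize(img[y0:y0 + side, x0:x0 + side],
                         (cfg.in_size, cfg.in_size), order=1,
                         preserve_range=True, anti_aliasing=False)
        out[i, 0] = img
    return out


def _balance(x: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Undersample the majority class to within +/-1 of the minority count."""
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    n = min(len(idx_pos), len(idx_neg))
    take = lambda idx: idx if len(idx) <= n + 1 else \
        rng.choice(idx, size=n, replace=False)
    keep = np.concatenate([take(idx_pos), take(idx_neg)])
    keep.sort()
    return x[keep], y[keep]


def patches_to_array(patches: list[LHIPatch], tau: float = 10.0) -> np.ndarray:
    """Stack patch images into (N, 1, H, W), scaled to [0, 1] by tau."""
    return np.stack([p.image for p in patches])[:, None].astype(np.float32) / tau


def train_hs2(patches: list[LHIPatch], labels, cfg: HS2Config | None = None,
              seed: int = 0) -> tuple[HS2Net, list[float]]:
    """Train the classifier on labelled LHI patches.

    ``labels`` holds "nodule"/"tissue" strings (or 1/0) per patch. Both
    classes must be present. Returns the network and the per-epoch loss log.
    """
    cfg = cfg or HS2Config()
    y = np.asarray([LABEL_TO_INT.get(lab, lab) for lab in labels],
                   dtype=np.int64)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("training requires both nodule and tissue patches")
    x = patches_to_array(patches)
    rng = np.random.default_rng(seed)
    if cfg.balance:
        x, y = _balance(x, y, rng)
    model = HS2Net(cfg, rng)
    opt = nn.SGD(model.parameters(), lr=cfg.lr, momentum=0.9)
    losses = []
    n = x.shape[0]
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr * (0.1 ** (epoch // cfg.lr_step))
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = x[idx]
            if cfg.augment:
                batch = _augment_batch(batch, cfg, rng)
            logits = model.forward(batch, train=True)
            loss, grad = nn.softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            total += loss * len(idx)
        losses.append(total / n)
    nn.recalibrate_bn(model, (x[i:i + cfg.batch_size]
                              for i in range(0, n, cfg.batch_size)))
    return model, losses


def predict_proba(model: HS2Net, patches: list[LHIPatch],
                  batch_size: int = 64) -> np.ndarray:
    """P(nodule) per patch."""
    x = patches_to_array(patches)
    probs = []
    for i in range(0, x.shape[0], batch_size):
        logits = model.forward(x[i:i + batch_size], train=False)
        probs.append(nn.softmax(logits)[:, 1])
    return np.concatenate(probs) if probs else np.empty(0)


def classify_candidates(cands: list[Candidate],
                        patches_per_candidate: list[list[LHIPatch]],
                        model: HS2Net,
                        cfg: HS2Config | None = None) -> list[Candidate]:
    """Label each candidate nodule/tissue from its averaged patch probability.

    Probability >= the decision threshold keeps the candidate as a nodule;
    below it the label becomes tissue. Coordinates and scores are untouched
    and the output has exactly one entry per input candidate. A candidate
    without patches is labelled unfiltered, with a warning.
    """
    cfg = cfg or HS2Config()
    if len(cands) != len(patches_per_candidate):
        raise ValueError("need one patch list per candidate")
    flat = [p for plist in patches_per_candidate for p in plist]
    probs = predict_proba(model, flat) if flat else np.empty(0)
    out = []
    pos = 0
    for cand, plist in zip(cands, patches_per_candidate):
        if not plist:
            log.warning("candidate %s has no LHI patch; left unfiltered",
                        cand.center_world)
            label = CandidateLabel.UNFILTERED
        else:
            p = float(np.mean(probs[pos:pos + len(plist)]))
            pos += len(plist)
            label = CandidateLabel.NODULE if p >= cfg.decision_threshold \
                else CandidateLabel.TISSUE
        out.append(Candidate(center_world=cand.center_world,
                             diameter_mm=cand.diameter_mm, score=cand.score,
                             label=label, seriesuid=cand.seriesuid))
    return out


def filter_positives(cands: list[Candidate]) -> list[Candidate]:
    """Candidates still counted as detections after filtering
    (tissue-labelled candidates are dropped from the positive set)."""
    return [c for c in cands if c.label is not CandidateLabel.TISSUE]
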