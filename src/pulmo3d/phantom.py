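"""Seeded synthetic-CT phantom generator.

Produces grayscale chest-like volumes containing two kinds of structures
that matter downstream:

* spherical nodules, whose axial cross-section expands and then contracts
  across consecutive slices (circular-cap radius profile), and
* tubular vessel-like distractors, whose cross-section keeps its size but
  translates laterally from slice to slice.

These two dynamics are exactly what the location-history image separates,
so every stage of the pipeline is testable on phantoms alone. An optional
chest envelope (elliptical body wall, two low-density lung fields and a
bright posterior spine marker) provides the orientation cues the rotation
pretext task needs and the low-density components the lung-mask stage
extracts. All randomness flows through one explicit seed.

Default gray levels mirror a [-1200, 600] HU window: exterior air ~25,
lung parenchyma ~50, body wall ~170, soft-tissue structures add ~100-120
of contrast. Noise is i.i.d. Gaussian (sd 8 gray levels) clipped to [0,255].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import CTVolume, IntensitySpace, NoduleAnnotation

log = logging.getLogger(__name__)

MIN_DIAMETER_MM = 3.0
MAX_DIAMETER_MM = 30.0


@dataclass
class NoduleSpec:
    """center is world mm (x, y, z); diameter in [3, 30] mm."""

    center: tuple[float, float, float]
    diameter_mm: float
    contrast: float = 120.0


@dataclass
class VesselSpec:
    """A z-axis tube: lateral start (x, y) mm, radius mm, and a per-slice
    lateral drift (dx, dy) in voxels."""

    start: tuple[float, float]
    radius_mm: float = 2.0
    contrast: float = 100.0
    drift: tuple[float, float] = (0.0, 0.0)


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 64)  # (z, y, x) voxels
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background_level: float = 50.0
    noise_sd: float = 8.0
    nodules: list[NoduleSpec] = field(default_factory=list)
    vessels: list[VesselSpec] = field(default_factory=list)
    body: bool = False
    air_level: float = 25.0
    body_level: float = 170.0
    spine_level: float = 220.0
    seed: int = 0

    def __post_init__(self):
        for nod in self.nodules:
            if not MIN_DIAMETER_MM <= nod.diameter_mm <= MAX_DIAMETER_MM:
                raise ValueError(
                    f"nodule diameter {nod.diameter_mm} outside "
                    f"[{MIN_DIAMETER_MM}, {MAX_DIAMETER_MM}] mm")
            if nod.contrast <= self.noise_sd:
                raise ValueError("nodule contrast must exceed noise_sd")


def _soft_ball(dist_mm: np.ndarray, radius_mm: float, voxel_mm: float) -> np.ndarray:
    """Antialiased indicator: 1 inside, 0 outside, linear over one voxel."""
    return np.clip(0.5 + (radius_mm - dist_mm) / voxel_mm, 0.0, 1.0)


def _world_to_voxel_zyx(spec: PhantomSpec, p_xyz) -> np.ndarray:
    p_zyx = np.asarray(p_xyz, dtype=np.float64)[::-1]
    return (p_zyx - np.asarray(spec.origin)) / np.asarray(spec.spacing)


def lung_field_mask(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth mask of the two low-density lung ellipsoids (body mode)."""
    nz, ny, nx = spec.shape
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    mask = np.zeros(spec.shape, dtype=bool)
    # ellipsoids sized to stay strictly inside the body wall on every slice
    for cx in (nx * 0.34, nx * 0.66):
        d = ((zz - nz / 2) / (nz * 0.38)) ** 2 \
            + ((yy - ny * 0.48) / (ny * 0.22)) ** 2 \
            + ((xx - cx) / (nx * 0.13)) ** 2
        mask |= d <= 1.0
    return mask


def _render_body(spec: PhantomSpec) -> np.ndarray:
    nz, ny, nx = spec.shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    ellipse = ((yy - ny * 0.5) / (ny * 0.40)) ** 2 \
        + ((xx - nx * 0.5) / (nx * 0.46)) ** 2 <= 1.0
    spine = (yy - ny * 0.82) ** 2 + (xx - nx * 0.5) ** 2 <= (nx * 0.07) ** 2
    slice_img = np.full((ny, nx), spec.air_level, dtype=np.float32)
    slice_img[ellipse] = spec.body_level
    vol = np.broadcast_to(slice_img, spec.shape).copy()
    vol[lung_field_mask(spec)] = spec.background_level
    vol[:, spine & ellipse] = spec.spine_level
    return vol


def generate_phantom(spec: PhantomSpec
                     ) -> tuple[CTVolume, list[NoduleAnnotation]]:
    """Render a phantom volume plus its exact ground-truth annotation list.

    Deterministic given ``spec.seed``. Overlapping nodule requests are
    rendered anyway, with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    sz, sy, sx = spec.spacing
    if spec.body:
        vol = _render_body(spec)
    else:
        vol = np.full(spec.shape, spec.background_level, dtype=np.float32)

    # pairwise overlap warning
    for i in range(len(spec.nodules)):
        for j in range(i + 1, len(spec.nodules)):
            a, b = spec.nodules[i], spec.nodules[j]
            gap = np.linalg.norm(np.subtract(a.center, b.center))
            if gap < (a.diameter_mm + b.diameter_mm) / 2:
                log.warning("overlapping nodules at %s and %s", a.center, b.center)

    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij", sparse=True)
    for nod in spec.nodules:
        cz, cy, cx = _world_to_voxel_zyx(spec, nod.center)
        dist = np.sqrt(((zz - cz) * sz) ** 2 + ((yy - cy) * sy) ** 2
                       + ((xx - cx) * sx) ** 2)
        vol += nod.contrast * _soft_ball(dist, nod.diameter_mm / 2,
                                         float(np.mean(spec.spacing)))

    y2d, x2d = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    for ves in spec.vessels:
        x0 = (ves.start[0] - spec.origin[2]) / sx
        y0 = (ves.start[1] - spec.origin[1]) / sy
        for z in range(nz):
            cy = y0 + ves.drift[1] * z
            cx = x0 + ves.drift[0] * z
            dist = np.sqrt(((y2d - cy) * sy) ** 2 + ((x2d - cx) * sx) ** 2)
            vol[z] += ves.contrast * _soft_ball(dist, ves.radius_mm,
                                                float(np.mean((sy, sx))))

    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, size=spec.shape)
    vol = np.clip(vol, 0.0, 255.0).astype(np.float32)

    annotations = [NoduleAnnotation(center_world=n.center,
                                    diameter_mm=n.diameter_mm)
                   for n in spec.nodules]
    ct = CTVolume(data=vol, spacing=spec.spacing, origin=spec.origin,
                  intensity_space=IntensitySpace.GRAY255)
    return ct, annotations


# ---------------------------------------------------------------------------
# candidate slice-stacks for the false-positive-reduction classifier
# ---------------------------------------------------------------------------

SEQUENCE_DEPTH = 11  # current slice plus five before and after


@dataclass
class CandidateSequence:
    """An 11-slice stack centred on a candidate, plus its true class."""

    stack: np.ndarray  # (11, size, size) gray
    truth_label: str   # "nodule" or "tissue"

    def __post_init__(self):
        if self.stack.shape[0] != SEQUENCE_DEPTH:
            raise ValueError(f"stack depth must be {SEQUENCE_DEPTH}")
        if self.truth_label not in ("nodule", "tissue"):
            raise ValueError(f"unknown truth label {self.truth_label!r}")


def make_candidate_sequence(kind: str, *, size: int = 32,
                            radius_px: float = 6.0, contrast: float = 120.0,
                            background: float = 50.0, noise_sd: float = 8.0,
                            drift: tuple[float, float] = (2.0, 0.0),
                            seed: int = 0) -> CandidateSequence:
    """Simulate the slice stack around one candidate.

    ``kind="nodule"``: a disc whose radius follows the circular-cap profile
    r(s) = sqrt(max(0, R^2 - (s - s0)^2)) of a sphere crossed by consecutive
    slices — it grows to R at the central slice and shrinks again,
    concentrically. ``kind="tissue"``: a fixed-radius disc translating at
    ``drift`` (dx, dy) voxels per slice, the vessel-like pattern.
    """
    if kind not in ("nodule", "tissue"):
        raise ValueError(f"kind must be 'nodule' or 'tissue', got {kind!r}")
    rng = np.random.default_rng(seed)
    s0 = SEQUENCE_DEPTH // 2
    c = (size - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    stack = np.full((SEQUENCE_DEPTH, size, size), background, dtype=np.float32)
    for s in range(SEQUENCE_DEPTH):
        if kind == "nodule":
            r = np.sqrt(max(0.0, radius_px ** 2 - (s - s0) ** 2))
            cy, cx = c, c
        else:
            r = radius_px
            cy = c + drift[1] * (s - s0)
            cx = c + drift[0] * (s - s0)
        if r > 0:
            dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
            stack[s] += contrast * _soft_ball(dist, r, 1.0)
    stack += rng.normal(0.0, noise_sd, size=stack.shape)
    stack = np.clip(stack, 0.0, 255.0).astype(np.float32)
    return CandidateSequence(stack=stack, truth_label=kind)
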