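"""Location History Images: decaying per-pixel records of supra-threshold
intensity change across consecutive CT slices.

An LHI is the slice-stack analogue of a Motion History Image. Scanning the
stack in order, a pixel whose absolute intensity difference between two
consecutive slices exceeds a threshold is reset to the ceiling ``tau``;
otherwise its value decays by 1 per slice, floored at zero. Nodules (discs
growing/shrinking concentrically) and vessels (discs translating laterally)
leave visibly different LHI patterns, which the false-positive-reduction
classifier exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .io_formats import Candidate, CTVolume, world_to_voxel


@dataclass
class LHIConfig:
    tau: int = 10                       # decay ceiling; 10 slice pairs in an 11-slice stack
    diff_thresholds: tuple[float, ...] = (30.0, 40.0)  # gray-level change thresholds
    patch_scale: float = 2.0            # patch side = scale * candidate diameter
    out_size: int = 48                  # LHIs are resized to out_size x out_size
    half_depth: int = 5                 # slices each side of the candidate slice

    def __post_init__(self):
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if any(t <= 0 for t in self.diff_thresholds):
            raise ValueError("diff thresholds must be positive")


@dataclass
class LHIPatch:
    """A resized LHI with the threshold that produced it."""

    image: np.ndarray          # (out_size, out_size), values in [0, tau]
    threshold: float
    candidate: Candidate | None = None


def compute_lhi(stack: np.ndarray, threshold: float, tau: int = 10) -> np.ndarray:
    """Accumulate the location-history image over a slice stack.

    ``f`` starts at zero; for each consecutive slice pair, pixels where
    ``|I_s - I_{s-1}| > threshold`` (strict) are set to ``tau`` and all others
    decay by one, floored at zero. Returns the final ``f`` as float32.
    """
    stack = np.asarray(stack, dtype=np.float32)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (S, H, W) with S >= 2")
    f = np.zeros(stack.shape[1:], dtype=np.float32)
    for s in range(1, stack.shape[0]):
        fired = np.abs(stack[s] - stack[s - 1]) > threshold
        f = np.where(fired, float(tau), np.maximum(0.0, f - 1.0))
    return f.astype(np.float32)


def extract_candidate_stack(vol: CTVolume, cand: Candidate,
                            cfg: LHIConfig | None = None) -> np.ndarray:
    """Crop the 11-slice stack around a candidate, twice its size in y and x.

    Out-of-grid regions are zero-padded; a candidate outside the z range is
    clamped to the nearest valid slice.
    """
    cfg = cfg or LHIConfig()
    cz, cy, cx = world_to_voxel(cand.center_world, vol)
    nz, ny, nx = vol.shape
    zc = int(round(min(max(cz, 0), nz - 1)))
    half_y = max(int(round(cfg.patch_scale * cand.diameter_mm
                           / vol.spacing[1])), 2) // 2
    half_x = max(int(round(cfg.patch_scale * cand.diameter_mm
                           / vol.spacing[2])), 2) // 2
    side_y, side_x = 2 * half_y, 2 * half_x
    y0 = int(round(cy)) - half_y
    x0 = int(round(cx)) - half_x
    depth = 2 * cfg.half_depth + 1
    stack = np.zeros((depth, side_y, side_x), dtype=np.float32)
    data = np.asarray(vol.data, dtype=np.float32)
    ys0, ys1 = max(y0, 0), min(y0 + side_y, ny)
    xs0, xs1 = max(x0, 0), min(x0 + side_x, nx)
    if ys0 >= ys1 or xs0 >= xs1:
        return stack  # crop entirely outside the grid: all padding
    for i, z in enumerate(range(zc - cfg.half_depth, zc + cfg.half_depth + 1)):
        if not 0 <= z < nz:
            continue
        stack[i, ys0 - y0:ys1 - y0, xs0 - x0:xs1 - x0] = \
            data[z, ys0:ys1, xs0:xs1]
    return stack


def extract_lhi_patch(vol: CTVolume, cand: Candidate,
                      cfg: LHIConfig | None = None) -> list[LHIPatch]:
    """One resized LHI patch per configured difference threshold."""
    cfg = cfg or LHIConfig()
    stack = extract_candidate_stack(vol, cand, cfg)
    patches = []
    for thr in cfg.diff_thresholds:
        img = compute_lhi(stack, thr, cfg.tau)
        img = resize(img, (cfg.out_size, cfg.out_size), order=1,
                     preserve_range=True, anti_aliasing=False).astype(np.float32)
        patches.append(LHIPatch(image=img, threshold=float(thr), candidate=cand))
    return patches


def stack_lhi_patches(stack: np.ndarray, cfg: LHIConfig | None = None
                      ) -> list[LHIPatch]:
    """LHI patches straight from a pre-cropped slice stack (one per threshold)."""
    cfg = cfg or LHIConfig()
    patches = []
    for thr in cfg.diff_thresholds:
        img = compute_lhi(stack, thr, cfg.tau)
        img = resize(img, (cfg.out_size, cfg.out_size), order=1,
                     preserve_range=True, anti_aliasing=False).astype(np.float32)
        patches.append(LHIPatch(image=img, threshold=float(thr)))
    return patches
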