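"""CT preprocessing: HU windowing to gray, isotropic resampling, lung masking.

The mask stage is the classical threshold / connected-component / closing
pipeline: Gaussian smoothing, low-density thresholding, removal of the air
connected to the image border, retention of the largest low-density
components inside the body, then morphological closing. Masking is optional
and detection runs without it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_formats import CTVolume, IntensitySpace

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """HU window (low, high), target isotropic spacing in mm, mask switch."""

    hu_window: tuple[float, float] = (-1200.0, 600.0)
    target_spacing: float = 1.0
    mask_enabled: bool = False
    mask_crop: bool = False  # zero non-lung voxels by default; crop if set

    def __post_init__(self):
        low, high = self.hu_window
        if not low < high:
            raise ValueError(f"hu_window must satisfy low < high, got {self.hu_window}")
        if self.target_spacing <= 0:
            raise ValueError(f"target_spacing must be > 0, got {self.target_spacing}")


def hu_to_gray(vol: CTVolume, cfg: PreprocessConfig | None = None) -> CTVolume:
    """Window HU values into gray [0, 255] by a linear map.

    g = clip(round(255 * (h - low) / (high - low)), 0, 255) with round-half-up.
    """
    cfg = cfg or PreprocessConfig()
    if vol.intensity_space is not IntensitySpace.HU:
        raise ValueError("hu_to_gray expects an HU volume")
    low, high = cfg.hu_window
    scaled = 255.0 * (vol.data.astype(np.float64) - low) / (high - low)
    gray = np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)
    return CTVolume(data=gray, spacing=vol.spacing, origin=vol.origin,
                    intensity_space=IntensitySpace.GRAY255)


def resample_isotropic(vol: CTVolume, cfg: PreprocessConfig | None = None,
                       *, nearest: bool = False) -> CTVolume:
    """Resample to isotropic ``target_spacing`` with trilinear interpolation.

    Output size per axis is round(extent_mm / target), so the physical extent
    is preserved to within one output voxel. ``nearest`` selects
    nearest-neighbour interpolation (for label/mask volumes).
    """
    cfg = cfg or PreprocessConfig()
    target = float(cfg.target_spacing)
    spacing = np.asarray(vol.spacing, dtype=np.float64)
    if np.allclose(spacing, target):
        return CTVolume(data=vol.data.copy(), spacing=(target,) * 3,
                        origin=vol.origin, intensity_space=vol.intensity_space)
    shape = np.asarray(vol.shape, dtype=np.float64)
    new_shape = np.maximum(np.round(shape * spacing / target), 1).astype(int)
    zoom = new_shape / shape
    data = ndimage.zoom(vol.data.astype(np.float32), zoom,
                        order=0 if nearest else 1, mode="nearest",
                        grid_mode=True)
    if vol.intensity_space is IntensitySpace.GRAY255:
        data = np.clip(data, 0, 255)
    return CTVolume(data=data, spacing=(target,) * 3, origin=vol.origin,
                    intensity_space=vol.intensity_space)


def lung_mask(vol: CTVolume, *, sigma: float = 1.0,
              low_density_threshold: float = 110.0,
              body_threshold: float = 120.0,
              keep_components: int = 2,
              closing_radius: int = 2) -> np.ndarray:
    """Binary lung mask from a GRAY255 volume.

    Steps: Gaussian smoothing; low-density thresholding; drop the exterior
    air (the low-density component touching the volume border); keep the
    largest remaining low-density components inside the body envelope; close
    morphologically. Returns a uint8 {0,1} array; an empty mask (no lung-like
    component) is returned with a warning rather than an error.
    """
    if vol.intensity_space is not IntensitySpace.GRAY255:
        raise ValueError("lung_mask expects a GRAY255 volume")
    smoothed = ndimage.gaussian_filter(vol.data.astype(np.float32), sigma)
    low = smoothed < low_density_threshold
    body = smoothed >= body_threshold
    if not body.any():
        log.warning("lung_mask: no body envelope found; returning empty mask")
        return np.zeros(vol.shape, dtype=np.uint8)

    labels, n = ndimage.label(low)
    if n == 0:
        log.warning("lung_mask: no low-density component found; empty mask")
        return np.zeros(vol.shape, dtype=np.uint8)
    border_labels = np.unique(np.concatenate([
        labels[0].ravel(), labels[-1].ravel(),
        labels[:, 0].ravel(), labels[:, -1].ravel(),
        labels[:, :, 0].ravel(), labels[:, :, -1].ravel()]))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1] + 1
    inside = [lab for lab in order if lab not in border_labels]
    if not inside:
        log.warning("lung_mask: no interior low-density component; empty mask")
        return np.zeros(vol.shape, dtype=np.uint8)
    mask = np.isin(labels, inside[:keep_components])
    if closing_radius > 0:
        structure = ndimage.generate_binary_structure(3, 1)
        mask = ndimage.binary_closing(
            mask, structure=structure, iterations=closing_radius)
    # never grow past the body envelope
    mask &= ndimage.binary_fill_holes(body)
    return mask.astype(np.uint8)


def apply_mask(vol: CTVolume, mask: np.ndarray, *, crop: bool = False
               ) -> CTVolume:
    """Zero voxels outside the mask; with ``crop``, also cut the volume to
    the mask's bounding box (origin shifted so world coordinates hold)."""
    mask = mask.astype(bool)
    data = np.where(mask, vol.data, 0)
    origin = vol.origin
    if crop and mask.any():
        lo, hi = [], []
        for ax in range(3):
            proj = mask.any(axis=tuple(i for i in range(3) if i != ax))
            idx = np.flatnonzero(proj)
            lo.append(int(idx[0]))
            hi.append(int(idx[-1]) + 1)
        data = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        origin = tuple(o + l * s for o, l, s in
                       zip(vol.origin, lo, vol.spacing))
    return CTVolume(data=data, spacing=vol.spacing, origin=origin,
                    intensity_space=vol.intensity_space)
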