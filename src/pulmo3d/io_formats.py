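"""CT volume and annotation I/O plus world/voxel coordinate transforms.

Conventions
-----------
* In-memory grids are indexed ``(z, y, x)``; ``spacing`` and ``origin`` are
  stored in the same ``(z, y, x)`` order so they align with the array axes.
* World coordinates in CSV files follow the LUNA16 dialect: columns
  ``coordX, coordY, coordZ`` in millimetres, plus ``diameter_mm``.
* Voxel indices are 0-based and continuous; a nodule centre is a real-valued
  position, never a rounded voxel.
* Only axis-aligned volumes are supported; a non-identity direction matrix
  raises ``UnsupportedFormatError``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
import SimpleITK as sitk


class FormatError(ValueError):
    """Malformed file contents (bad header, missing column, bad value)."""


class UnsupportedFormatError(FormatError):
    """File is readable but uses features this package does not support."""


class IntensitySpace(str, Enum):
    HU = "HU"
    GRAY255 = "GRAY255"


ANNOTATION_COLUMNS = ["seriesuid", "coordX", "coordY", "coordZ", "diameter_mm"]
CANDIDATE_COLUMNS = ANNOTATION_COLUMNS + ["score", "label"]


@dataclass
class CTVolume:
    """A 3D scalar grid with physical geometry.

    ``data`` is indexed (z, y, x); ``spacing`` is mm per voxel and ``origin``
    the world position (mm) of voxel (0, 0, 0), both in (z, y, x) order.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_space: IntensitySpace = IntensitySpace.HU

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must have 3 axes, got {self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.intensity_space = IntensitySpace(self.intensity_space)
        if self.intensity_space is IntensitySpace.GRAY255:
            lo, hi = float(self.data.min(initial=0)), float(self.data.max(initial=0))
            if lo < 0 or hi > 255:
                raise ValueError(
                    f"GRAY255 data must lie in [0,255], got [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class NoduleAnnotation:
    """Ground-truth nodule: world-mm centre (x, y, z) and diameter in mm."""

    center_world: tuple[float, float, float]
    diameter_mm: float

    def __post_init__(self):
        self.center_world = tuple(float(c) for c in self.center_world)
        self.diameter_mm = float(self.diameter_mm)
        if self.diameter_mm <= 0:
            raise ValueError(f"diameter must be positive, got {self.diameter_mm}")


class CandidateLabel(str, Enum):
    UNFILTERED = "unfiltered"
    NODULE = "nodule"
    TISSUE = "tissue"


@dataclass
class Candidate:
    """A detection: world-mm centre (x, y, z), diameter, confidence, label."""

    center_world: tuple[float, float, float]
    diameter_mm: float
    score: float
    label: CandidateLabel = CandidateLabel.UNFILTERED
    seriesuid: str = ""

    def __post_init__(self):
        self.center_world = tuple(float(c) for c in self.center_world)
        self.diameter_mm = float(self.diameter_mm)
        self.score = float(self.score)
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0,1], got {self.score}")
        self.label = CandidateLabel(self.label)


# ---------------------------------------------------------------------------
# volume I/O (MetaImage and NIfTI via SimpleITK)
# ---------------------------------------------------------------------------

_SUPPORTED_SUFFIXES = (".mhd", ".mha", ".nii", ".nii.gz")


def load_volume(path: str | os.PathLike,
                intensity_space: IntensitySpace | str = IntensitySpace.HU
                ) -> CTVolume:
    """Read a MetaImage or NIfTI volume.

    The file stores no intensity-space flag, so the caller states it;
    raw scanner output is HU (the default), preprocessed output GRAY255.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if not str(path).endswith(_SUPPORTED_SUFFIXES):
        raise UnsupportedFormatError(
            f"unsupported volume format: {path} (expected one of "
            f"{_SUPPORTED_SUFFIXES})")
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # SimpleITK wraps header errors in RuntimeError
        raise FormatError(f"cannot read {path}: {exc}") from exc
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise UnsupportedFormatError(
            f"{path}: non-axis-aligned direction matrix is not supported")
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing_xyz = img.GetSpacing()
    origin_xyz = img.GetOrigin()
    return CTVolume(data=data,
                    spacing=tuple(spacing_xyz[::-1]),
                    origin=tuple(origin_xyz[::-1]),
                    intensity_space=intensity_space)


def write_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume as MetaImage or NIfTI, preserving geometry."""
    path = os.fspath(path)
    if not str(path).endswith(_SUPPORTED_SUFFIXES):
        raise UnsupportedFormatError(f"unsupported volume format: {path}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data))
    img.SetSpacing(tuple(vol.spacing[::-1]))
    img.SetOrigin(tuple(vol.origin[::-1]))
    sitk.WriteImage(img, path)


# ---------------------------------------------------------------------------
# annotation / candidate tables
# ---------------------------------------------------------------------------

def _read_table(path, required_columns):
    if not os.path.exists(os.fspath(path)):
        raise FileNotFoundError(os.fspath(path))
    df = pd.read_csv(path, dtype={"seriesuid": str})
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    for col in required_columns:
        if col in ("seriesuid", "label"):
            continue
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna() & df[col].notna()]
        if len(bad):
            raise FormatError(
                f"{path}: non-numeric value in column {col!r} at row {bad[0]}")
        df[col] = values
    return df


def load_annotations(path) -> dict[str, list[NoduleAnnotation]]:
    """Read a LUNA16-style annotations CSV, grouped by scan identifier."""
    df = _read_table(path, ANNOTATION_COLUMNS)
    grouped: dict[str, list[NoduleAnnotation]] = {}
    for row in df.itertuples(index=False):
        grouped.setdefault(str(row.seriesuid), []).append(
            NoduleAnnotation(center_world=(row.coordX, row.coordY, row.coordZ),
                             diameter_mm=row.diameter_mm))
    return grouped


def save_annotations(annotations: dict[str, list[NoduleAnnotation]], path) -> None:
    rows = [
        {"seriesuid": uid, "coordX": a.center_world[0],
         "coordY": a.center_world[1], "coordZ": a.center_world[2],
         "diameter_mm": a.diameter_mm}
        for uid, anns in annotations.items() for a in anns
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def load_candidates(path) -> dict[str, list[Candidate]]:
    """Read a candidates CSV (annotation columns plus score and label)."""
    df = _read_table(path, ANNOTATION_COLUMNS + ["score"])
    has_label = "label" in df.columns
    grouped: dict[str, list[Candidate]] = {}
    for row in df.itertuples(index=False):
        label = getattr(row, "label", "unfiltered") if has_label else "unfiltered"
        grouped.setdefault(str(row.seriesuid), []).append(
            Candidate(center_world=(row.coordX, row.coordY, row.coordZ),
                      diameter_mm=row.diameter_mm, score=row.score,
                      label=label, seriesuid=str(row.seriesuid)))
    return grouped


def save_candidates(candidates: dict[str, list[Candidate]], path) -> None:
    rows = [
        {"seriesuid": uid, "coordX": c.center_world[0],
         "coordY": c.center_world[1], "coordZ": c.center_world[2],
         "diameter_mm": c.diameter_mm, "score": c.score,
         "label": c.label.value}
        for uid, cands in candidates.items() for c in cands
    ]
    pd.DataFrame(rows, columns=CANDIDATE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# coordinate transforms
# ---------------------------------------------------------------------------

def world_to_voxel(p_xyz, vol: CTVolume) -> np.ndarray:
    """Map a world-mm point (x, y, z) to a continuous (z, y, x) voxel index."""
    p_zyx = np.asarray(p_xyz, dtype=np.float64)[::-1]
    return (p_zyx - np.asarray(vol.origin)) / np.asarray(vol.spacing)


def voxel_to_world(idx_zyx, vol: CTVolume) -> np.ndarray:
    """Map a continuous (z, y, x) voxel index to a world-mm point (x, y, z)."""
    idx = np.asarray(idx_zyx, dtype=np.float64)
    return (idx * np.asarray(vol.spacing) + np.asarray(vol.origin))[::-1]


def in_grid(idx_zyx, vol: CTVolume) -> bool:
    """Whether a continuous voxel index falls inside the grid extent."""
    idx = np.asarray(idx_zyx, dtype=np.float64)
    return bool(np.all(idx >= 0) and np.all(idx <= np.asarray(vol.shape) - 1))
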