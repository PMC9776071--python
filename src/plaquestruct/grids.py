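"""Image-grid containers shared by every pipeline stage.

All volumes live on an axis-aligned grid with 0-based indices and voxel
centers at ``world = origin + index * spacing``; lengths are millimetres.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import nibabel as nib
import numpy as np

#: Channel order used everywhere a multi-contrast stack is stored as 4D.
CHANNELS = ("T1W", "T2W", "PDW", "TOF")


class Tissue(IntEnum):
    """Voxel classes of a :class:`LabelVolume` (closed set)."""

    BACKGROUND = 0
    LUMEN = 1
    WALL = 2
    LIPID = 3
    CALCIFICATION = 4


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size == 1:
        v = np.repeat(v, 3)
    if v.size != 3:
        raise ValueError(f"expected scalar or length-3 vector, got {x!r}")
    return v


@dataclass
class ContrastStack:
    """Co-registered multi-contrast 3D volumes (T1W/T2W/PDW/TOF)."""

    channels: dict[str, np.ndarray]
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.spacing = _as_vec3(self.spacing)
        self.origin = _as_vec3(self.origin)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"no channel {name!r}; have {sorted(self.channels)}")
        return self.channels[name]

    def to_nifti(self, path: str | Path) -> None:
        data = np.stack([self.channels[ch] for ch in CHANNELS], axis=-1)
        nib.save(nib.Nifti1Image(data.astype(np.float32), self._affine()), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "ContrastStack":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4 or data.shape[-1] != len(CHANNELS):
            raise ValueError("expected a 4D stack with one volume per contrast")
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
        origin = np.asarray(img.affine[:3, 3], dtype=float)
        return cls({ch: data[..., i] for i, ch in enumerate(CHANNELS)}, spacing, origin)

    def _affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


@dataclass
class LabelVolume:
    """Per-voxel tissue class on the same grid as its :class:`ContrastStack`."""

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.spacing = _as_vec3(self.spacing)
        self.origin = _as_vec3(self.origin)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        self.labels = np.asarray(self.labels)
        valid = {int(t) for t in Tissue}
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise ValueError(f"unknown label values {sorted(present - valid)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def mask(self, *tissues: Tissue) -> np.ndarray:
        return np.isin(self.labels, [int(t) for t in tissues])

    def class_counts(self) -> dict[Tissue, int]:
        return {t: int(np.count_nonzero(self.labels == int(t))) for t in Tissue}

    def to_nifti(self, path: str | Path) -> None:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), aff), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "LabelVolume":
        img = nib.load(str(path))
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
        origin = np.asarray(img.affine[:3, 3], dtype=float)
        return cls(np.asarray(img.dataobj, dtype=np.int16), spacing, origin)


def index_to_world(idx, spacing, origin) -> np.ndarray:
    return np.asarray(origin, float) + np.asarray(idx, float) * np.asarray(spacing, float)


def world_to_index(point, spacing, origin) -> np.ndarray:
    """Nearest voxel index of a world point (no bounds check)."""
    rel = (np.asarray(point, float) - np.asarray(origin, float)) / np.asarray(spacing, float)
    return np.round(rel).astype(int)
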