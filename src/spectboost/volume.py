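"""Core in-memory container: a 3-D scalar field with voxel spacing and modality.

Axis convention throughout the package: arrays are indexed ``(slice, row, col)``
with slice 0 at the top face of the simulated object.  Voxel centers sit at
``origin + index * spacing`` in world millimetres; orientation is identity
(simulator-native data — clinical orientation handling is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

from .exceptions import ContractError

#: Recognised modality tags.
MODALITIES = ("spect_counts", "ct", "mask", "activity", "suv")


def _as_spacing(voxel_size_mm) -> Tuple[float, float, float]:
    if np.isscalar(voxel_size_mm):
        voxel_size_mm = (voxel_size_mm,) * 3
    s = tuple(float(v) for v in voxel_size_mm)
    if len(s) != 3 or any(v <= 0 for v in s):
        raise ContractError(f"voxel size must be 3 strictly positive entries, got {voxel_size_mm!r}")
    return s


@dataclass
class Volume:
    """A 3-D scalar field with per-axis voxel spacing and a modality tag."""

    data: np.ndarray
    voxel_size_mm: Tuple[float, float, float]
    modality: str = "activity"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ContractError(f"Volume data must be 3-D, got shape {self.data.shape}")
        self.voxel_size_mm = _as_spacing(self.voxel_size_mm)
        if self.modality not in MODALITIES:
            raise ContractError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if self.modality == "mask":
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ContractError("mask volumes may only contain {0, 1}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def with_data(self, data, modality: str | None = None) -> "Volume":
        """A copy of this volume carrying new voxel data (same grid)."""
        return Volume(np.asarray(data), self.voxel_size_mm,
                      modality if modality is not None else self.modality)

    def same_grid(self, other: "Volume", rtol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.voxel_size_mm, other.voxel_size_mm, rtol=rtol))


@dataclass
class GridSpec:
    """Target sampling grid: shape, spacing and world position of voxel (0,0,0)."""

    shape: Tuple[int, int, int]
    voxel_size_mm: Tuple[float, float, float]
    origin_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.shape = tuple(int(n) for n in self.shape)
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ContractError(f"grid shape entries must be >= 1, got {self.shape}")
        self.voxel_size_mm = _as_spacing(self.voxel_size_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @classmethod
    def of(cls, vol: Volume, origin_mm=(0.0, 0.0, 0.0)) -> "GridSpec":
        return cls(vol.shape, vol.voxel_size_mm, origin_mm)


def require_same_grid(*vols: Volume, what: str = "volumes"):
    from .exceptions import AlignmentError

    first = vols[0]
    for v in vols[1:]:
        if not first.same_grid(v):
            raise AlignmentError(
                f"{what} must share one grid: {first.shape}@{first.voxel_size_mm} "
                f"vs {v.shape}@{v.voxel_size_mm}")
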