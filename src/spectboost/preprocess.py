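"""Mean normalization, axial slicing into training samples, and channel
concatenation of SPECT and CT inputs.

Every volume (fast SPECT, CT, standard SPECT) is divided by its own mean over
all voxels; the divisors are kept with the samples so network outputs return
to count scale.  At deployment only the fast volume's statistics exist, so
inference restores scale with the fast divisor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .exceptions import AlignmentError, ContractError, NormalizationError
from .volume import Volume, require_same_grid


def normalize_by_mean(vol: Volume) -> Tuple[Volume, float]:
    """Divide a volume by its mean over all voxels; returns (volume, divisor).

    The normalized volume has mean 1; invert with :func:`denormalize`.
    """
    mean = float(np.mean(vol.data))
    if mean <= 0:
        raise NormalizationError(
            f"cannot mean-normalize a volume with mean {mean} (all-zero input?)")
    return vol.with_data(np.asarray(vol.data, dtype=np.float64) / mean), mean


def denormalize(vol: Volume, divisor: float) -> Volume:
    """Multiply voxelwise by the stored divisor (inverse of normalize_by_mean)."""
    if divisor <= 0:
        raise ContractError(f"divisor must be > 0, got {divisor}")
    return vol.with_data(np.asarray(vol.data) * divisor)


@dataclass
class PairedSample:
    """One axial training slice: normalized fast/CT inputs, normalized
    standard-SPECT target, binary lesion mask, and the per-volume divisors."""

    fast_slice: np.ndarray
    ct_slice: np.ndarray
    target_slice: np.ndarray
    mask_slice: np.ndarray
    norm_fast: float
    norm_ct: float
    norm_target: float
    index: int = 0
    case: str = ""

    def __post_init__(self):
        shapes = {a.shape for a in (self.fast_slice, self.ct_slice,
                                    self.target_slice, self.mask_slice)}
        if len(shapes) != 1:
            raise AlignmentError(f"sample slices disagree in shape: {shapes}")
        if min(self.norm_fast, self.norm_ct, self.norm_target) <= 0:
            raise ContractError("normalization divisors must be positive")


def make_samples(fast: Volume, ct_on_spect_grid: Volume, standard: Volume,
                 mask: Volume, plane: str = "axial", case: str = "") -> List[PairedSample]:
    """Slice four aligned volumes into per-axial-slice training samples.

    Normalization divisors are computed once per volume, not per slice.  CT is
    shifted to be non-negative before mean normalization (HU-like values are
    signed; a signed mean is a meaningless divisor).
    """
    if plane != "axial":
        raise ContractError(f"only axial slicing is supported, got {plane!r}")
    require_same_grid(fast, ct_on_spect_grid, standard, mask, what="paired volumes")

    fast_n, div_fast = normalize_by_mean(fast)
    ct_shift = ct_on_spect_grid.with_data(
        np.asarray(ct_on_spect_grid.data, dtype=np.float64)
        - min(float(np.min(ct_on_spect_grid.data)), 0.0), "activity")
    ct_n, div_ct = normalize_by_mean(ct_shift)
    std_n, div_std = normalize_by_mean(standard)
    mdata = np.asarray(mask.data)

    return [PairedSample(fast_n.data[i], ct_n.data[i], std_n.data[i],
                         mdata[i].astype(np.uint8), div_fast, div_ct, div_std,
                         index=i, case=case)
            for i in range(fast.shape[0])]


def concat_channels(sample: PairedSample, use_ct: bool = True) -> np.ndarray:
    """Stack network input channels: channel 0 = fast SPECT, channel 1 = CT
    when ``use_ct`` (the ablation arm drops the CT channel)."""
    if use_ct:
        return np.stack([sample.fast_slice, sample.ct_slice])
    return sample.fast_slice[None]


def reassemble(slices: List[np.ndarray], divisor: float, template: Volume,
               modality: str = "spect_counts") -> Volume:
    """Stack per-slice outputs back into a volume on the template grid and
    restore count scale with the given divisor."""
    data = np.stack(slices) * divisor
    if data.shape != template.shape:
        raise AlignmentError(f"reassembled shape {data.shape} != template {template.shape}")
    return Volume(np.clip(data, 0, None), template.voxel_size_mm, modality)
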