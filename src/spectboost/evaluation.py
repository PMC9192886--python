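"""Quantitative assessment: PSNR, SSIM, SUV conversion, per-sphere statistics,
detectability counts and difference maps.

PSNR follows the printed definition 10*log10(MAX_gt^2 / MSE) with MAX taken
from the reference volume.  SSIM shares its sliding-window implementation
with the SSIM loss term.  Sphere ROIs come from the known analytic phantom
geometry; detectability uses a contrast-to-noise Rose criterion as a
reproducible surrogate for visual sphere identification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from .exceptions import ContractError, GeometryError
from .loss import ssim_index
from .phantom_sim import PhantomSpec, _grid_coords_mm
from .volume import Volume

ArrayOrVolume = Union[np.ndarray, Volume]


def _data(x: ArrayOrVolume) -> np.ndarray:
    return np.asarray(x.data if isinstance(x, Volume) else x, dtype=np.float64)


@dataclass
class MetricsReport:
    psnr_db: float
    ssim: float
    scope: str = "volume"
    per_slice: Optional[List[dict]] = None

    def as_dict(self) -> dict:
        d = {"psnr_db": self.psnr_db, "ssim": self.ssim, "scope": self.scope}
        if self.per_slice is not None:
            d["per_slice"] = self.per_slice
        return d


@dataclass
class SUVReport:
    sphere_id: int           # 1..6, 1 = largest diameter
    diameter_mm: float
    suv_max: float
    suv_mean: float
    detectable: bool = True
    cnr: float = math.inf

    def __post_init__(self):
        if self.suv_max < self.suv_mean - 1e-9:
            raise ContractError("suv_max must be >= suv_mean")


def mse(pred: ArrayOrVolume, gt: ArrayOrVolume) -> float:
    p, g = _data(pred), _data(gt)
    if p.shape != g.shape:
        raise ContractError(f"shape mismatch: {p.shape} vs {g.shape}")
    return float(np.mean((p - g) ** 2))


def psnr(pred: ArrayOrVolume, gt: ArrayOrVolume) -> float:
    """10*log10(MAX_gt^2 / MSE); identical images give +inf."""
    g = _data(gt)
    peak = float(g.max())
    if peak <= 0:
        raise ContractError("PSNR undefined: reference has no positive values")
    err = mse(pred, gt)
    if err == 0:
        return math.inf
    return 10.0 * math.log10(peak * peak / err)


def ssim(pred: ArrayOrVolume, gt: ArrayOrVolume, window: int = 11,
         data_range: Optional[float] = None) -> float:
    """Mean local SSIM.  3-D inputs are scored per axial slice with a shared
    dynamic range from the reference volume, then averaged."""
    p, g = _data(pred), _data(gt)
    if p.shape != g.shape:
        raise ContractError(f"shape mismatch: {p.shape} vs {g.shape}")
    if p.ndim == 2:
        return ssim_index(p, g, window, data_range)
    if p.ndim != 3:
        raise ContractError(f"expected 2-D or 3-D input, got {p.ndim}-D")
    if data_range is None:
        r = float(np.ptp(g))
        data_range = r if r > 0 else 1.0
    return float(np.mean([ssim_index(p[i], g[i], window, data_range)
                          for i in range(p.shape[0])]))


def metrics_report(pred: ArrayOrVolume, gt: ArrayOrVolume, window: int = 11,
                   per_slice: bool = False) -> MetricsReport:
    if not per_slice:
        return MetricsReport(psnr(pred, gt), ssim(pred, gt, window))
    p, g = _data(pred), _data(gt)
    rows = [{"slice": i, "psnr_db": psnr(p[i], g[i]) if g[i].max() > 0 else math.nan,
             "ssim": ssim_index(p[i], g[i], window, float(np.ptp(g)) or 1.0)}
            for i in range(p.shape[0])]
    return MetricsReport(psnr(pred, gt), ssim(pred, gt, window), "per_slice", rows)


def to_suv(vol: Volume, weight_g: float, dose_mbq: float) -> Volume:
    """SUV = pixel value * weight[g] / dose[MBq], exactly as defined."""
    if weight_g <= 0 or dose_mbq <= 0:
        raise ContractError("weight_g and dose_mbq must be positive")
    return Volume(np.asarray(vol.data, dtype=np.float64) * weight_g / dose_mbq,
                  vol.voxel_size_mm, "suv")


def sphere_voxel_masks(spec: PhantomSpec, shape, voxel_size_mm) -> List[np.ndarray]:
    """Boolean ROI per sphere from the analytic geometry, ordered 1..6
    (largest diameter first)."""
    nz, ny, nx = shape
    v = float(voxel_size_mm[0]) if not np.isscalar(voxel_size_mm) else float(voxel_size_mm)
    z, y, x = _grid_coords_mm(shape, v)
    rois = []
    for (cz, cy, cx), d in zip(spec.sphere_centers_mm(), spec.diameters_descending()):
        rad = d / 2.0
        if (cz + rad > nz * v or cz - rad < 0
                or abs(cy) + rad > ny * v / 2 or abs(cx) + rad > nx * v / 2):
            raise GeometryError(f"sphere of diameter {d} mm extends outside the grid")
        rois.append((z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= rad * rad)
    return rois


def background_voxel_mask(spec: PhantomSpec, shape, voxel_size_mm,
                          slab_half_width_mm: float = 25.0,
                          sphere_margin_mm: float = 10.0,
                          edge_margin_mm: float = 12.0) -> np.ndarray:
    """Background annulus: cylinder-interior voxels in the sphere-plane slab,
    away from the shell and from every sphere."""
    v = float(voxel_size_mm[0]) if not np.isscalar(voxel_size_mm) else float(voxel_size_mm)
    z, y, x = _grid_coords_mm(shape, v)
    R = spec.cylinder_radius_mm
    bg = ((y * y + x * x <= (R - edge_margin_mm) ** 2)
          & (np.abs(z - spec.sphere_plane_depth_mm) <= slab_half_width_mm)
          & (z >= 0) & (z <= spec.interior_length_mm))
    for (cz, cy, cx), d in zip(spec.sphere_centers_mm(), spec.diameters_descending()):
        keep_out = (d / 2.0 + sphere_margin_mm) ** 2
        bg &= (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 > keep_out
    return bg


def sphere_stats(suv: Volume, spec: PhantomSpec, cnr_threshold: float = 4.0) -> List[SUVReport]:
    """Per-sphere SUVmax/SUVmean over the analytic sphere ROIs, with the
    Rose-criterion detectability flag."""
    data = _data(suv)
    rois = sphere_voxel_masks(spec, data.shape, suv.voxel_size_mm)
    bg = background_voxel_mask(spec, data.shape, suv.voxel_size_mm)
    bg_mean = float(data[bg].mean()) if bg.any() else 0.0
    bg_sd = float(data[bg].std()) if bg.any() else 0.0
    reports = []
    for k, (roi, d) in enumerate(zip(rois, spec.diameters_descending()), start=1):
        vals = data[roi]
        if vals.size == 0:
            raise GeometryError(f"sphere {k} contains no voxels at this grid resolution")
        contrast = float(vals.mean()) - bg_mean
        if bg_sd == 0:
            cnr = math.inf if contrast > 0 else (-math.inf if contrast < 0 else 0.0)
        else:
            cnr = contrast / bg_sd
        reports.append(SUVReport(k, d, float(vals.max()), float(vals.mean()),
                                 detectable=cnr > cnr_threshold, cnr=cnr))
    return reports


def count_detectable_spheres(vol: Volume, spec: PhantomSpec,
                             cnr_threshold: float = 4.0) -> int:
    """Number of spheres whose ROI contrast-to-noise ratio exceeds the Rose
    threshold; with a degenerate (zero-sd) background, positive contrast counts."""
    return sum(r.detectable for r in sphere_stats(vol, spec, cnr_threshold))


def difference_map(pred: Volume, gt: Volume) -> Volume:
    """Signed difference gt - pred (the display convention standard-minus-image)."""
    p, g = _data(pred), _data(gt)
    if p.shape != g.shape:
        raise ContractError(f"shape mismatch: {p.shape} vs {g.shape}")
    return Volume(g - p, gt.voxel_size_mm, "activity")


def suggested_display_bounds(diff: Volume, fraction: float = 1 / 6) -> tuple:
    """Symmetric display window, a fixed fraction of the reference range."""
    lim = float(np.max(np.abs(diff.data))) * fraction
    return (-lim, lim)
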