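"""Voxelized NEMA IEC body phantom, synthetic subjects and paired fast/standard
SPECT acquisition simulation.

The acquisition forward model is an image-domain surrogate for a real
scanner-plus-reconstruction chain: the activity map is blurred with an
isotropic Gaussian PSF (system resolution) and independent Poisson counts are
drawn per voxel with expectation proportional to activity x sensitivity x
total scan time.  This preserves the property the enhancement network is
trained on — a fast scan (3 s/projection) is a 3/20-expectation Poisson
realization of the same underlying image as the standard scan
(20 s/projection) — without modelling projections, attenuation or scatter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .exceptions import ContractError, GeometryError, PlacementError
from .volume import Volume

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: pseudo-CT class values (HU-like)
CT_AIR = -1000.0
CT_WATER = 0.0
CT_SHELL = 120.0
CT_BONE = 700.0
CT_LESION = 300.0


@dataclass
class PhantomSpec:
    """Geometry of the NEMA IEC body phantom surrogate.

    The fillable cylinder holds ``cylinder_volume_ml`` of background solution;
    six spheres of graded diameter sit with centres on a ring of
    ``ring_radius_mm`` in a plane ``sphere_plane_depth_mm`` below the top
    face, filled at ``activity_ratio`` : 1 relative to the background.
    The cylinder interior length follows the NEMA IEC standard (180 mm) and
    the radius is solved from the fill volume.
    """

    grid_shape: Tuple[int, int, int] = (200, 256, 256)
    voxel_size_mm: float = 1.95
    cylinder_volume_ml: float = 9700.0
    sphere_diameters_mm: Tuple[float, ...] = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
    ring_radius_mm: float = 50.0
    sphere_plane_depth_mm: float = 70.0
    activity_ratio: float = 12.0
    interior_length_mm: float = 180.0
    shell_thickness_mm: float = 3.0

    def __post_init__(self):
        d = tuple(float(x) for x in self.sphere_diameters_mm)
        if any(x <= 0 for x in d) or any(b <= a for a, b in zip(d, d[1:])):
            raise ContractError("sphere diameters must be positive and strictly increasing")
        if self.ring_radius_mm < max(d) / 2:
            raise ContractError("ring radius must be at least the largest sphere radius")
        if self.activity_ratio <= 0:
            raise ContractError("activity_ratio must be positive")
        self.sphere_diameters_mm = d

    @property
    def cylinder_radius_mm(self) -> float:
        return math.sqrt(self.cylinder_volume_ml * 1000.0
                         / (math.pi * self.interior_length_mm))

    def sphere_centers_mm(self) -> List[Tuple[float, float, float]]:
        """Centres (z, y, x) mm ordered sphere 1..6 = largest..smallest.

        Spheres sit at 60 degree spacing around the ring, largest at angle 0;
        y/x are measured from the cylinder axis, z from the top face.
        """
        z = self.sphere_plane_depth_mm
        out = []
        for k in range(6):
            ang = math.radians(60.0 * k)
            out.append((z, self.ring_radius_mm * math.cos(ang),
                        self.ring_radius_mm * math.sin(ang)))
        return out

    def diameters_descending(self) -> Tuple[float, ...]:
        return tuple(sorted(self.sphere_diameters_mm, reverse=True))


@dataclass
class AcquisitionSpec:
    """Scan-physics parameters of the image-domain forward model."""

    seconds_per_projection: float = 20.0
    n_projections: int = 60
    psf_fwhm_mm: float = 8.0
    #: expected counts per voxel per (activity unit x second); the default
    #: puts the standard-scan background at 50 counts/voxel for unit activity
    sensitivity_counts_per_kBq_s: float = 50.0 / (20.0 * 60.0)
    background_counts_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.seconds_per_projection <= 0:
            raise ContractError("seconds_per_projection must be > 0")
        if self.n_projections < 1:
            raise ContractError("n_projections must be >= 1")
        if self.psf_fwhm_mm < 0:
            raise ContractError("psf_fwhm_mm must be >= 0")
        if self.background_counts_rate < 0:
            raise ContractError("background_counts_rate must be >= 0")

    @property
    def total_time_s(self) -> float:
        return self.seconds_per_projection * self.n_projections


def _grid_coords_mm(shape, voxel):
    """World coordinates of voxel centres: z from the top face (slice 0 centre
    half a voxel below it), y/x from the grid centre."""
    nz, ny, nx = shape
    z = (np.arange(nz) + 0.5) * voxel
    y = (np.arange(ny) - (ny - 1) / 2.0) * voxel
    x = (np.arange(nx) - (nx - 1) / 2.0) * voxel
    return z[:, None, None], y[None, :, None], x[None, None, :]


def build_phantom(spec: PhantomSpec) -> Tuple[Volume, Volume, Volume]:
    """Voxelize the phantom: (activity, lesion_mask, pseudo_ct).

    Activity is 1 in the background fill, ``activity_ratio`` inside the
    spheres and 0 outside; the pseudo-CT encodes air / water / plexiglass
    shell as constant values.
    """
    nz, ny, nx = spec.grid_shape
    v = spec.voxel_size_mm
    R = spec.cylinder_radius_mm
    L = spec.interior_length_mm
    t = spec.shell_thickness_mm

    if (R + t) * 2 > ny * v:
        raise GeometryError(f"cylinder diameter {2*(R+t):.1f} mm exceeds row extent {ny*v:.1f} mm")
    if (R + t) * 2 > nx * v:
        raise GeometryError(f"cylinder diameter {2*(R+t):.1f} mm exceeds col extent {nx*v:.1f} mm")
    if L + t > nz * v:
        raise GeometryError(f"cylinder length {L+t:.1f} mm exceeds slice extent {nz*v:.1f} mm")

    z, y, x = _grid_coords_mm(spec.grid_shape, v)
    r2 = y * y + x * x
    interior = (r2 <= R * R) & (z >= 0) & (z <= L)
    shell = (r2 <= (R + t) ** 2) & (z >= -t) & (z <= L + t) & ~interior

    activity = np.zeros(spec.grid_shape, dtype=np.float64)
    activity[interior] = 1.0
    mask = np.zeros(spec.grid_shape, dtype=np.uint8)
    for (cz, cy, cx), d in zip(spec.sphere_centers_mm(), spec.diameters_descending()):
        rad = d / 2.0
        inside = (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= rad * rad
        activity[inside] = spec.activity_ratio
        mask[inside] = 1

    ct = np.full(spec.grid_shape, CT_AIR, dtype=np.float64)
    ct[shell] = CT_SHELL
    ct[interior] = CT_WATER

    return (Volume(activity, v, "activity"), Volume(mask, v, "mask"), Volume(ct, v, "ct"))


def blur_activity(activity: Volume, psf_fwhm_mm: float) -> Volume:
    """Gaussian system-resolution blur (total activity preserved up to edges)."""
    if psf_fwhm_mm == 0:
        return activity
    sigma_vox = [psf_fwhm_mm * FWHM_TO_SIGMA / s for s in activity.voxel_size_mm]
    return activity.with_data(ndimage.gaussian_filter(
        np.asarray(activity.data, dtype=np.float64), sigma_vox, mode="constant"))


def expected_counts(activity: Volume, acq: AcquisitionSpec) -> Volume:
    """Noise-free expectation of the count image for one acquisition."""
    if activity.modality != "activity":
        raise ContractError(f"expected an activity volume, got {activity.modality!r}")
    if np.any(activity.data < 0):
        raise ContractError("activity values must be non-negative")
    blurred = blur_activity(activity, acq.psf_fwhm_mm)
    T = acq.total_time_s
    lam = blurred.data * acq.sensitivity_counts_per_kBq_s * T + acq.background_counts_rate * T
    return activity.with_data(lam, "activity")


def simulate_acquisition(activity: Volume, acq: AcquisitionSpec) -> Volume:
    """Draw one Poisson count realization of an acquisition.

    Deterministic for a fixed ``acq.rng_seed`` and inputs.
    """
    lam = expected_counts(activity, acq).data
    rng = np.random.default_rng(acq.rng_seed)
    counts = rng.poisson(lam).astype(np.int64)
    return Volume(counts, activity.voxel_size_mm, "spect_counts")


# -- synthetic subjects ---------------------------------------------------
def generate_synthetic_subject(
        rng_seed: int, n_lesions: int, grid_shape: Tuple[int, int, int] = (200, 256, 256),
        voxel_size_mm: float = 1.95, bone_uptake: float = 3.0, lesion_uptake: float = 8.0,
        max_retries: int = 500) -> Tuple[Volume, Volume, Volume]:
    """A body-like activity map: soft-tissue ellipsoid background (activity 1),
    skeletal rods/plates at ``bone_uptake`` and ``n_lesions`` non-overlapping
    hot ellipsoids at ``lesion_uptake``.  The pseudo-CT shares the geometry at
    CT contrast (bone bright, lesions mildly sclerotic).  Deterministic given
    ``rng_seed``."""
    if n_lesions < 0:
        raise ContractError("n_lesions must be >= 0")
    rng = np.random.default_rng(rng_seed)
    nz, ny, nx = grid_shape
    v = voxel_size_mm
    z, y, x = _grid_coords_mm(grid_shape, v)
    cz = nz * v / 2.0

    # torso: axial ellipsoid filling most of the grid
    az = nz * v * (0.42 + 0.04 * rng.random())
    ay = ny * v * (0.32 + 0.04 * rng.random())
    ax = nx * v * (0.37 + 0.04 * rng.random())
    body = (((z - cz) / az) ** 2 + (y / ay) ** 2 + (x / ax) ** 2) <= 1.0

    activity = np.zeros(grid_shape, dtype=np.float64)
    activity[body] = 1.0
    bone = np.zeros(grid_shape, dtype=bool)

    # spine: posterior rod running the body length
    spine_y = -0.45 * ay + rng.normal(0, 2.0)
    spine_r = max(0.06 * ay, 1.5 * v)
    spine = ((y - spine_y) ** 2 + x ** 2 <= spine_r ** 2) & body
    bone |= spine

    # rib-like transverse plates at random heights
    for _ in range(3):
        pz = cz + rng.uniform(-0.7, 0.7) * az
        th = rng.uniform(1.0, 2.0) * v
        ring_out = rng.uniform(0.75, 0.9)
        ring_in = ring_out - 0.18
        rr = np.sqrt((y / ay) ** 2 + (x / ax) ** 2)
        plate = (np.abs(z - pz) <= th) & (rr <= ring_out) & (rr >= ring_in) & body
        bone |= plate

    activity[bone] = bone_uptake

    # hot lesions: non-overlapping ellipsoids inside the torso
    mask = np.zeros(grid_shape, dtype=np.uint8)
    placed: List[Tuple[np.ndarray, float]] = []
    for i in range(n_lesions):
        for attempt in range(max_retries):
            u = rng.uniform(-0.75, 0.75, size=3)
            c = np.array([cz + u[0] * az, u[1] * ay, u[2] * ax])
            semi = rng.uniform(6.0, 14.0, size=3)
            semi = np.maximum(semi, 1.6 * v)  # at least a voxel-scale object
            reach = float(semi.max())
            if any(np.linalg.norm(c - pc) < pr + reach + 2.5 * v for pc, pr in placed):
                continue
            inside = (((z - c[0]) / semi[0]) ** 2 + ((y - c[1]) / semi[1]) ** 2
                      + ((x - c[2]) / semi[2]) ** 2) <= 1.0
            if not inside.any():
                continue
            placed.append((c, reach))
            activity[inside] = lesion_uptake
            mask[inside] = 1
            break
        else:
            raise PlacementError(
                f"could not place lesion {i + 1}/{n_lesions} after {max_retries} retries")

    ct = np.full(grid_shape, CT_AIR, dtype=np.float64)
    ct[body] = CT_WATER
    ct[bone] = CT_BONE
    ct[mask.astype(bool)] = CT_LESION

    return (Volume(activity, v, "activity"), Volume(mask, v, "mask"), Volume(ct, v, "ct"))


class PairedVolumes(NamedTuple):
    """One training/evaluation case: fast scan, CT, standard scan, lesion mask."""

    fast: Volume
    ct: Volume
    standard: Volume
    mask: Volume
    name: str
    activity: Optional[Volume] = None


def make_paired_dataset(
        fast_acq: AcquisitionSpec, std_acq: AcquisitionSpec, seed: int = 0,
        phantom_spec: Optional[PhantomSpec] = None, n_subjects: int = 0,
        subject_grid_shape: Tuple[int, int, int] = (200, 256, 256),
        subject_voxel_mm: float = 1.95, n_lesions_range: Tuple[int, int] = (1, 4),
        keep_activity: bool = False, **subject_kwargs) -> List[PairedVolumes]:
    """Simulate paired (fast, ct, standard, mask) cases.

    Fast and standard scans are independent Poisson realizations of the same
    blurred activity; the two acquisition specs may differ only in dwell time
    (and seed stream).
    """
    for attr in ("n_projections", "psf_fwhm_mm", "sensitivity_counts_per_kBq_s",
                 "background_counts_rate"):
        if getattr(fast_acq, attr) != getattr(std_acq, attr):
            raise ContractError(
                f"fast and standard acquisitions may differ only in dwell time; {attr} differs")

    rng = np.random.default_rng(seed)
    out: List[PairedVolumes] = []

    def _simulate(activity, ct, mask, name):
        fa = replace(fast_acq, rng_seed=int(rng.integers(2 ** 31)))
        sa = replace(std_acq, rng_seed=int(rng.integers(2 ** 31)))
        fast = simulate_acquisition(activity, fa)
        standard = simulate_acquisition(activity, sa)
        out.append(PairedVolumes(fast, ct, standard, mask, name,
                                 activity if keep_activity else None))

    if phantom_spec is not None:
        activity, mask, ct = build_phantom(phantom_spec)
        _simulate(activity, ct, mask, "phantom")

    for i in range(n_subjects):
        sseed = int(rng.integers(2 ** 31))
        n_les = int(rng.integers(n_lesions_range[0], n_lesions_range[1] + 1))
        activity, mask, ct = generate_synthetic_subject(
            sseed, n_les, subject_grid_shape, subject_voxel_mm, **subject_kwargs)
        _simulate(activity, ct, mask, f"subject_{i:02d}")

    return out
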