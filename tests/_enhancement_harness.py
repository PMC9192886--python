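"""Shared harness for the end-to-end enhancement and ablation checks.

One *arm* = simulate the desk-scale paired dataset for a seed, train the
generator under the given configuration, and measure held-out image quality,
phantom SUV accuracy, lesion-region error and bone-structure recovery.

The problem sizes here (64x64 slices at 6 mm, one phantom + three subjects,
six epochs) are the package's desk-scale test conditions; docs/methods.md
records them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from spectboost import evaluation as ev
from spectboost.loss import LossWeights, l1_loss
from spectboost.network import U2NetConfig, build_u2net
from spectboost.phantom_sim import (AcquisitionSpec, PhantomSpec,
                                    make_paired_dataset)
from spectboost.preprocess import make_samples, normalize_by_mean
from spectboost.training import TrainConfig, enhance_volume, train
from spectboost.workflow import counts_to_suv, phantom_ground_truth_dose
from spectboost.evaluation import sphere_stats, to_suv

GRID = (32, 64, 64)
VOXEL = 6.0
PHANTOM_TRAIN_FROM = 16  # slices >= this train; the sphere plane tests
EPOCHS = 6
LR = 1e-3
BASE_CHANNELS = 8


def _norm(vol):
    return normalize_by_mean(vol)[0].data


def _bone_bbox(ct_data: np.ndarray, pad: int = 2):
    """Bounding box of the skeletal structure in the pseudo-CT."""
    bone = np.asarray(ct_data) >= 600.0
    idx = np.where(bone)
    lo = [max(int(i.min()) - pad, 0) for i in idx]
    hi = [min(int(i.max()) + pad + 1, s) for i, s in zip(idx, bone.shape)]
    return tuple(slice(l, h) for l, h in zip(lo, hi))


def run_arm(seed: int, use_ct: bool = True, beta: float = 100.0,
            epochs: int = EPOCHS, lr: float = LR) -> Dict[str, float]:
    fast_acq = AcquisitionSpec(seconds_per_projection=3.0, psf_fwhm_mm=12.0)
    std_acq = AcquisitionSpec(seconds_per_projection=20.0, psf_fwhm_mm=12.0)
    spec = PhantomSpec(grid_shape=GRID, voxel_size_mm=VOXEL)
    cases = make_paired_dataset(fast_acq, std_acq, seed=seed, phantom_spec=spec,
                                n_subjects=3, subject_grid_shape=GRID,
                                subject_voxel_mm=VOXEL, keep_activity=True)
    phantom, train_subjects, test_subject = cases[0], cases[1:3], cases[3]

    samples = make_samples(phantom.fast, phantom.ct, phantom.standard,
                           phantom.mask, case="phantom")[PHANTOM_TRAIN_FROM:]
    for c in train_subjects:
        samples += make_samples(c.fast, c.ct, c.standard, c.mask, case=c.name)

    model = build_u2net(U2NetConfig(in_channels=2 if use_ct else 1,
                                    base_channels=BASE_CHANNELS, seed=seed))
    weights = LossWeights(beta=beta)
    cfg = TrainConfig(epochs=epochs, lr=lr, lr_drop_epoch=epochs, seed=seed,
                      use_ct=use_ct)
    model, history = train(model, samples, weights, cfg)

    out: Dict[str, float] = {"final_train_loss": history[-1].loss,
                             "first_train_loss": history[0].loss}

    # held-out subject: whole-volume quality on the mean scale
    enh = enhance_volume(model, test_subject.fast, test_subject.ct, use_ct=use_ct)
    f, e, s = (_norm(test_subject.fast), _norm(enh), _norm(test_subject.standard))
    out["psnr_fast"] = ev.psnr(f, s)
    out["psnr_enhanced"] = ev.psnr(e, s)
    out["ssim_fast"] = ev.ssim(f, s)
    out["ssim_enhanced"] = ev.ssim(e, s)

    # lesion-region accuracy on the held-out subject
    mask = np.asarray(test_subject.mask.data, dtype=bool)
    if mask.any():
        out["masked_l1_fast"] = float(np.abs(f - s)[mask].mean())
        out["masked_l1_enhanced"] = float(np.abs(e - s)[mask].mean())

    # bone-structure recovery inside the CT-visible skeleton's bounding box
    bbox = _bone_bbox(test_subject.ct.data)
    r = float(np.ptp(s))
    out["bbox_ssim_fast"] = ev.ssim(f[bbox], s[bbox], window=7, data_range=r)
    out["bbox_ssim_enhanced"] = ev.ssim(e[bbox], s[bbox], window=7, data_range=r)

    # phantom: per-sphere SUVmean absolute error vs ground truth
    enh_ph = enhance_volume(model, phantom.fast, phantom.ct, use_ct=use_ct)
    suv_fast = counts_to_suv(phantom.fast, fast_acq, spec)
    suv_enh = counts_to_suv(enh_ph, fast_acq, spec)
    suv_gt = to_suv(phantom.activity, spec.cylinder_volume_ml,
                    phantom_ground_truth_dose(spec))
    st_f = sphere_stats(suv_fast, spec)
    st_e = sphere_stats(suv_enh, spec)
    st_g = sphere_stats(suv_gt, spec)
    for k in range(3):  # three largest spheres
        out[f"suv_err_fast_{k + 1}"] = abs(st_f[k].suv_mean - st_g[k].suv_mean)
        out[f"suv_err_enhanced_{k + 1}"] = abs(st_e[k].suv_mean - st_g[k].suv_mean)
    return out
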