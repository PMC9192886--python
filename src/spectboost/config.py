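"""Run configuration: nested blocks mirroring each module's knobs, YAML
round-trip, and the desk-scale preset.

The desk preset keeps the published method unchanged (topology, losses,
optimizer) but shrinks widths, grids and epochs to sizes a single CPU
handles in minutes; every run writes its fully resolved config next to its
outputs.
"""

from __future__ import annotations

import copy
from typing import Optional

import yaml

from .exceptions import ContractError


def default_config() -> dict:
    """Full-scale defaults: the published acquisition geometry and schedule."""
    return {
        "seed": 0,
        "desk_preset": False,
        "simulate": {
            "phantom": {"grid_shape": [200, 256, 256], "voxel_size_mm": 1.95},
            "n_train_subjects": 10,
            "n_test_subjects": 10,
            "subject_grid_shape": [200, 256, 256],
            "subject_voxel_mm": 1.95,
            "fast_dwell_s": 3.0,
            "std_dwell_s": 20.0,
            "n_projections": 60,
            "psf_fwhm_mm": 8.0,
            "background_counts_rate": 0.0,
            "n_lesions_range": [1, 4],
            # phantom axial split: slices >= this index train, the rest
            # (containing the sphere plane) test
            "phantom_train_from_slice": 80,
        },
        "preprocess": {"use_ct": True, "inference_plane": "axial"},
        "network": {"base_channels": 64, "in_channels": 2, "dtype": "float32"},
        "loss": {"alpha": 0.5, "beta": 100.0, "w_side": [1.0] * 6, "w_final": 1.0,
                 "ssim_window": 11},
        "train": {"epochs": 100, "batch_size": 4, "lr": 2.0e-4,
                  "lr_drop_epoch": 80, "lr_drop_factor": 10.0},
        "evaluate": {"ssim_window": 11, "cnr_threshold": 4.0,
                     "intensity_scale": "mean"},
    }


def desk_config() -> dict:
    """Desk-scale preset: same method, CPU-tractable sizes.

    64x64 slices at 6 mm voxels (the phantom cylinder still fits), a narrow
    (base 8) network, a wider 12 mm PSF matching the coarse grid, and a short
    fixed schedule.
    """
    cfg = default_config()
    cfg["desk_preset"] = True
    cfg["simulate"].update({
        "phantom": {"grid_shape": [32, 64, 64], "voxel_size_mm": 6.0},
        "n_train_subjects": 3,
        "n_test_subjects": 1,
        "subject_grid_shape": [32, 64, 64],
        "subject_voxel_mm": 6.0,
        "psf_fwhm_mm": 12.0,
        "phantom_train_from_slice": 16,
    })
    cfg["network"]["base_channels"] = 8
    # shorter schedule, proportionally higher rate: the narrow model sees two
    # orders of magnitude fewer gradient steps than the full-scale run
    cfg["train"].update({"epochs": 12, "lr": 1.0e-3, "lr_drop_epoch": 10})
    return cfg


def load_config(path: Optional[str] = None, preset: str = "full",
                overrides: Optional[dict] = None) -> dict:
    """Resolve a config: preset defaults <- YAML file <- explicit overrides."""
    if preset == "full":
        cfg = default_config()
    elif preset == "desk":
        cfg = desk_config()
    else:
        raise ContractError(f"unknown preset {preset!r} (use 'full' or 'desk')")
    if path is not None:
        with open(path) as f:
            _deep_update(cfg, yaml.safe_load(f) or {})
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=False)


def _deep_update(base: dict, extra: dict) -> dict:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = copy.deepcopy(v)
    return base
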