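"""Lesion-attention composite loss with deep supervision.

Per output image the base loss is  L = L1 + alpha * L_ssim  (alpha = 0.5),
where L_ssim = 1 - mean(local SSIM map) computed over sliding windows.
The lesion-attention loss re-evaluates L over the lesion-mask region and
adds it with weight beta (= 100):

    l = L + beta * L|_mask

and the training loss sums l over the six side outputs and the final output
with configurable weights (all 1 by default).

Everything here is written against the autodiff tensor engine so the same
code path yields training gradients and evaluation numbers; plain ndarray
inputs are accepted and produce plain floats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from . import nn
from .exceptions import ContractError
from .nn import Tensor

log = logging.getLogger(__name__)

ArrayLike = Union[np.ndarray, Tensor]


@dataclass
class LossWeights:
    """Weights and SSIM parameters of the composite loss.

    ``alpha`` balances SSIM against L1; ``beta`` scales the lesion-region
    term; ``w_side``/``w_final`` weight the deep-supervision components.
    ``ssim_k1``/``ssim_k2`` give the conventional stability constants
    c1 = (k1*R)^2, c2 = (k2*R)^2 with R the dynamic range of the target.
    """

    alpha: float = 0.5
    beta: float = 100.0
    w_side: Tuple[float, ...] = (1.0,) * 6
    w_final: float = 1.0
    ssim_window: int = 11
    ssim_k1: float = 0.01
    ssim_k2: float = 0.03

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ContractError("alpha and beta must be >= 0")
        self.w_side = tuple(float(w) for w in self.w_side)
        if len(self.w_side) != 6:
            raise ContractError("w_side must have 6 entries")
        if self.ssim_window % 2 == 0:
            raise ContractError("ssim_window must be odd")


def _prep(pred: ArrayLike, target: ArrayLike) -> Tuple[Tensor, Tensor, bool]:
    was_array = not isinstance(pred, Tensor)
    p, t = nn.as_tensor(pred), nn.as_tensor(target)
    if p.shape != t.shape:
        raise ContractError(f"shape mismatch: pred {p.shape} vs target {t.shape}")
    return p, t, was_array


def _maybe_item(t: Tensor, as_float: bool):
    return t.item() if as_float else t


def l1_loss(pred: ArrayLike, target: ArrayLike, mask: Optional[ArrayLike] = None):
    """Mean absolute error, over all pixels or over mask-positive pixels."""
    p, t, as_float = _prep(pred, target)
    diff = nn.absolute(p - t)
    if mask is None:
        return _maybe_item(nn.tmean(diff), as_float)
    m = np.asarray(mask.data if isinstance(mask, Tensor) else mask)
    _check_mask(m, p.shape)
    n_pos = m.sum()
    if n_pos == 0:
        log.debug("l1_loss: empty mask, masked term is 0")
        return 0.0 if as_float else nn.tsum(diff * Tensor(np.zeros_like(m, dtype=p.dtype)))
    out = nn.tsum(diff * Tensor(m.astype(p.dtype))) / float(n_pos)
    return _maybe_item(out, as_float)


def _check_mask(m: np.ndarray, shape):
    if m.shape != tuple(shape):
        raise ContractError(f"mask shape {m.shape} does not match images {shape}")
    if not np.all((m == 0) | (m == 1)):
        raise ContractError("mask must be binary")


def _ssim_map(pred: Tensor, target: Tensor, window: int, k1: float, k2: float,
              data_range: Optional[float]) -> Tensor:
    """Local SSIM over valid sliding-window positions.

    Inputs are (N, 1, H, W); the map has spatial sides reduced by window-1.
    Uses a uniform window and population (biased) moments.
    """
    H, W = pred.shape[-2:]
    if window > min(H, W):
        raise ContractError(f"ssim window {window} exceeds image side {min(H, W)}")
    if data_range is None:
        r = float(np.ptp(target.data))
        data_range = r if r > 0 else 1.0
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2

    mu_x = nn.box_mean_valid(pred, window)
    mu_y = nn.box_mean_valid(target, window)
    xx = nn.box_mean_valid(pred * pred, window)
    yy = nn.box_mean_valid(target * target, window)
    xy = nn.box_mean_valid(pred * target, window)
    var_x = xx - mu_x * mu_x
    var_y = yy - mu_y * mu_y
    cov = xy - mu_x * mu_y
    num = (2.0 * mu_x * mu_y + c1) * (2.0 * cov + c2)
    den = (mu_x * mu_x + mu_y * mu_y + c1) * (var_x + var_y + c2)
    return num / den


def _to_n1hw(t: Tensor) -> Tensor:
    if t.data.ndim == 4:
        return t
    if t.data.ndim == 2:
        return _reshape4(t)
    raise ContractError(f"expected 2-D image or (N,1,H,W) batch, got shape {t.shape}")


def _reshape4(t: Tensor) -> Tensor:
    data = t.data[None, None]

    def bw(g):
        from .nn.tensor import _accum
        _accum(t, g[0, 0])

    from .nn.tensor import _node
    return _node(data, (t,), bw)


def ssim_loss(pred: ArrayLike, target: ArrayLike, mask: Optional[ArrayLike] = None,
              weights: Optional[LossWeights] = None, data_range: Optional[float] = None):
    """1 - mean local SSIM; with a mask, the SSIM map is averaged over the
    window positions whose centre pixel is mask-positive."""
    w = weights or LossWeights()
    p, t, as_float = _prep(pred, target)
    p4, t4 = _to_n1hw(p), _to_n1hw(t)
    smap = _ssim_map(p4, t4, w.ssim_window, w.ssim_k1, w.ssim_k2, data_range)
    if mask is None:
        return _maybe_item(1.0 - nn.tmean(smap), as_float)
    m = np.asarray(mask.data if isinstance(mask, Tensor) else mask)
    _check_mask(m, p.shape)
    half = w.ssim_window // 2
    m4 = m[None, None] if m.ndim == 2 else m
    m_valid = m4[:, :, half:m4.shape[-2] - half, half:m4.shape[-1] - half]
    n_pos = m_valid.sum()
    if n_pos == 0:
        log.debug("ssim_loss: empty mask, masked term is 0")
        return 0.0 if as_float else nn.tsum(smap * Tensor(np.zeros_like(m_valid, dtype=p.dtype)))
    masked_mean = nn.tsum(smap * Tensor(m_valid.astype(p.dtype))) / float(n_pos)
    return _maybe_item(1.0 - masked_mean, as_float)


def combined_loss(pred: ArrayLike, target: ArrayLike, weights: Optional[LossWeights] = None,
                  mask: Optional[ArrayLike] = None, data_range: Optional[float] = None):
    """L = L1 + alpha * L_ssim (optionally restricted to the mask region)."""
    w = weights or LossWeights()
    out = l1_loss(pred, target, mask) + w.alpha * ssim_loss(pred, target, mask, w, data_range)
    return out


def lesion_attention_loss(pred: ArrayLike, target: ArrayLike, mask: ArrayLike,
                          weights: Optional[LossWeights] = None,
                          data_range: Optional[float] = None):
    """l = L + beta * L|_mask — the whole-image loss plus the loss
    re-evaluated over the lesion region, scaled by beta."""
    w = weights or LossWeights()
    whole = combined_loss(pred, target, w, None, data_range)
    m = np.asarray(mask.data if isinstance(mask, Tensor) else mask)
    if m.sum() == 0:
        return whole
    return whole + w.beta * combined_loss(pred, target, w, m, data_range)


def total_loss(final: ArrayLike, side_outputs: Sequence[ArrayLike], target: ArrayLike,
               mask: ArrayLike, weights: Optional[LossWeights] = None,
               data_range: Optional[float] = None):
    """Deep-supervision total: sum_i w_side[i] * l(side_i) + w_final * l(final)."""
    w = weights or LossWeights()
    if len(side_outputs) != 6:
        raise ContractError(f"expected exactly 6 side outputs, got {len(side_outputs)}")
    out = w.w_final * lesion_attention_loss(final, target, mask, w, data_range)
    for ws, side in zip(w.w_side, side_outputs):
        if ws != 0.0:
            out = out + ws * lesion_attention_loss(side, target, mask, w, data_range)
    return out


def ssim_index(pred: np.ndarray, target: np.ndarray, window: int = 11,
               data_range: Optional[float] = None, k1: float = 0.01,
               k2: float = 0.03) -> float:
    """Mean local SSIM of two 2-D images (the evaluation-facing scalar).

    Shares the sliding-window implementation with the SSIM loss term:
    ssim_index == 1 - ssim_loss for the same parameters.
    """
    w = LossWeights(ssim_window=window, ssim_k1=k1, ssim_k2=k2)
    return 1.0 - ssim_loss(np.asarray(pred, dtype=np.float64),
                           np.asarray(target, dtype=np.float64),
                           None, w, data_range)
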