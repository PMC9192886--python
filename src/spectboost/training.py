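"""Adam training loop with deep supervision and slice-wise volume inference.

The schedule is fixed-epoch (no early stopping): learning rate 2e-4, divided
by ``lr_drop_factor`` from epoch ``lr_drop_epoch`` onward, batches of 4 axial
slices, seeded shuffling, single process — two runs with the same seed
produce identical loss histories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import AlignmentError, ContractError
from .loss import LossWeights, total_loss
from .network import U2Net
from .nn import Adam
from .preprocess import PairedSample, concat_channels, normalize_by_mean, reassemble
from .volume import Volume

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization hyperparameters (full-scale values as defaults)."""

    epochs: int = 100
    batch_size: int = 4
    lr: float = 2e-4
    lr_drop_epoch: int = 80
    lr_drop_factor: float = 10.0
    seed: int = 0
    use_ct: bool = True
    adam_betas: Tuple[float, float] = (0.9, 0.999)

    def __post_init__(self):
        if self.lr <= 0:
            raise ContractError("lr must be > 0")
        if not 0 < self.lr_drop_epoch <= self.epochs:
            raise ContractError("lr_drop_epoch must lie in (0, epochs]")
        if self.batch_size < 1 or self.epochs < 1:
            raise ContractError("batch_size and epochs must be >= 1")


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    loss: float

    def as_row(self):
        return {"epoch": self.epoch, "lr": self.lr, "loss": self.loss}


def _stack_batch(samples: Sequence[PairedSample], use_ct: bool, dtype):
    x = np.stack([concat_channels(s, use_ct) for s in samples]).astype(dtype)
    y = np.stack([s.target_slice[None] for s in samples]).astype(dtype)
    m = np.stack([s.mask_slice[None] for s in samples]).astype(np.uint8)
    return x, y, m


def train(model: U2Net, samples: Sequence[PairedSample],
          loss_weights: Optional[LossWeights] = None,
          cfg: Optional[TrainConfig] = None) -> Tuple[U2Net, List[EpochRecord]]:
    """Optimize ``total_loss`` over the sample set; returns the model and the
    per-epoch mean loss history."""
    if len(samples) == 0:
        raise ContractError("need at least one training sample")
    cfg = cfg or TrainConfig()
    weights = loss_weights or LossWeights()
    if cfg.use_ct and model.cfg.in_channels < 2:
        raise ContractError("use_ct=True requires a 2-channel model")

    dtype = np.dtype(model.cfg.dtype)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr, betas=cfg.adam_betas)
    history: List[EpochRecord] = []
    model.train()

    order = np.arange(len(samples))
    for epoch in range(cfg.epochs):
        lr = cfg.lr / cfg.lr_drop_factor if epoch >= cfg.lr_drop_epoch else cfg.lr
        opt.lr = lr
        rng.shuffle(order)
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [samples[i] for i in order[start:start + cfg.batch_size]]
            x, y, m = _stack_batch(batch, cfg.use_ct, dtype)
            final, sides = model(x)
            loss = total_loss(final, sides, y, m, weights)
            val = loss.item()
            if not np.isfinite(val):
                raise FloatingPointError(
                    f"non-finite loss {val} at epoch {epoch}, batch {start // cfg.batch_size}")
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(val)
        history.append(EpochRecord(epoch, lr, float(np.mean(epoch_losses))))
        log.debug("epoch %d lr %.2e loss %.5f", epoch, lr, history[-1].loss)
    return model, history


def enhance_volume(model: U2Net, fast: Volume, ct: Optional[Volume] = None,
                   use_ct: bool = True, chunk: int = 8) -> Volume:
    """Synthesize a standard-scan volume from a fast scan (and CT).

    Inputs are normalized by their own means, each axial slice is run through
    the network keeping only the final output, and the stack is returned to
    count scale with the fast volume's divisor (the only scale statistic
    available at deployment), clamping negatives to zero.
    """
    if use_ct:
        if ct is None:
            raise ContractError("use_ct=True requires a CT volume")
        if not fast.same_grid(ct):
            raise AlignmentError(
                f"fast and CT must share the SPECT grid: {fast.shape} vs {ct.shape}")
    dtype = np.dtype(model.cfg.dtype)
    fast_n, div_fast = normalize_by_mean(fast)
    if use_ct:
        ct_shift = ct.with_data(np.asarray(ct.data, dtype=np.float64)
                                - min(float(np.min(ct.data)), 0.0), "activity")
        ct_n, _ = normalize_by_mean(ct_shift)
        stack = np.stack([fast_n.data, ct_n.data], axis=1).astype(dtype)
    else:
        stack = fast_n.data[:, None].astype(dtype)

    model.eval()
    out_slices: List[np.ndarray] = []
    for start in range(0, stack.shape[0], chunk):
        final, _ = model(stack[start:start + chunk])
        out_slices.extend(np.asarray(final.data[:, 0], dtype=np.float64))
    model.train()
    return reassemble(out_slices, div_fast, fast, "spect_counts")
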