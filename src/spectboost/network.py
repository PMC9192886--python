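"""Nested-U generator for fast-SPECT enhancement.

The generator is a U²-Net: an outer U of six encoder and five decoder stages
whose stages are themselves small U-shaped sub-networks, the residual
U-blocks (RSU).  An RSU of height L runs an input 3x3 convolution, a
symmetric encoder/decoder of L-1 levels over the resulting feature map, and
adds the multi-scale output back onto the input-convolution branch.  At the
lowest outer resolutions pooling would destroy context, so those stages use
the dilated variant ("RS-L"): the same topology with pooling/upsampling
replaced by progressively dilated convolutions, keeping the spatial size.

Six side outputs (one per decoder stage plus the deepest encoder) are mapped
to single-channel images, upsampled to the input size, concatenated and
fused by a 1x1 convolution; a long skip connection adds the fast-SPECT input
channel to the fused image to give the final synthesized slice.  All outputs
are linear — intensities are unbounded mean-normalized counts, so no
saturating output nonlinearity is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .exceptions import ContractError, ShapeError
from .nn import Tensor

#: outer downsampling factor implied by five pooling steps
OUTER_DIVISOR = 32


@dataclass
class RSUConfig:
    """One residual U-block: height, channel widths, dilated or not."""

    height_L: int
    in_channels: int
    mid_channels: int
    out_channels: int
    dilated: bool = False

    def __post_init__(self):
        if self.height_L < 2:
            raise ContractError(f"RSU height must be >= 2, got {self.height_L}")
        for name in ("in_channels", "mid_channels", "out_channels"):
            if getattr(self, name) < 1:
                raise ContractError(f"{name} must be positive")

    @property
    def required_divisor(self) -> int:
        """Spatial sides must divide by this for pooling to invert exactly."""
        return 1 if self.dilated else 2 ** (self.height_L - 2)


class RSU(nn.Module):
    """Residual U-block: out = innerU(conv_in(x)) + conv_in(x)."""

    def __init__(self, cfg: RSUConfig, rng: np.random.Generator, dtype=np.float32):
        self.cfg = cfg
        L, mid = cfg.height_L, cfg.mid_channels
        self.conv_in = nn.ConvBNReLU(cfg.in_channels, cfg.out_channels, rng=rng, dtype=dtype)
        if cfg.dilated:
            enc_d = [2 ** i for i in range(L - 1)]           # 1, 2, 4, ...
            bottom_d = 2 ** (L - 1)
            dec_d = enc_d[::-1][:-1] + [1]
        else:
            enc_d = [1] * (L - 1)
            bottom_d = 2
            dec_d = [1] * (L - 1)
        self.enc = nn.ModuleList(
            [nn.ConvBNReLU(cfg.out_channels, mid, dilation=enc_d[0], rng=rng, dtype=dtype)]
            + [nn.ConvBNReLU(mid, mid, dilation=d, rng=rng, dtype=dtype) for d in enc_d[1:]])
        self.bottom = nn.ConvBNReLU(mid, mid, dilation=bottom_d, rng=rng, dtype=dtype)
        self.dec = nn.ModuleList(
            [nn.ConvBNReLU(2 * mid, mid, dilation=d, rng=rng, dtype=dtype) for d in dec_d[:-1]]
            + [nn.ConvBNReLU(2 * mid, cfg.out_channels, dilation=dec_d[-1], rng=rng, dtype=dtype)])

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        H, W = x.shape[-2:]
        div = cfg.required_divisor
        if H % div or W % div:
            raise ShapeError(
                f"RSU-{cfg.height_L} needs spatial sides divisible by {div}, got {H}x{W}")
        xin = self.conv_in(x)
        if cfg.dilated:
            feats = [self.enc[0](xin)]
            for conv in self.enc[1:]:
                feats.append(conv(feats[-1]))
            h = self.bottom(feats[-1])
            for conv, skip in zip(self.dec, feats[::-1]):
                h = conv(nn.concat([h, skip], axis=1))
            return h + xin
        feats = [self.enc[0](xin)]
        for conv in self.enc[1:]:
            feats.append(conv(nn.maxpool2(feats[-1])))
        h = self.bottom(feats[-1])
        h = self.dec[0](nn.concat([h, feats[-1]], axis=1))
        for conv, skip in zip(self.dec[1:], feats[-2::-1]):
            h = conv(nn.concat([nn.upsample_bilinear(h, skip.shape[-2:]), skip], axis=1))
        return h + xin


def _default_stages(base: int, in_channels: int) -> Tuple[List[RSUConfig], List[RSUConfig]]:
    b = base
    # narrow desk-scale models keep a floor on the inner-U widths: a one- or
    # two-channel inner U cannot carry multi-scale content
    half = max(b // 2, 4)
    quarter = max(b // 4, 4)
    encoders = [
        RSUConfig(7, in_channels, half, b),
        RSUConfig(6, b, half, 2 * b),
        RSUConfig(5, 2 * b, b, 4 * b),
        RSUConfig(4, 4 * b, 2 * b, 8 * b),
        RSUConfig(4, 8 * b, 4 * b, 8 * b, dilated=True),
        RSUConfig(4, 8 * b, 4 * b, 8 * b, dilated=True),
    ]
    decoders = [
        RSUConfig(4, 16 * b, 4 * b, 8 * b, dilated=True),
        RSUConfig(4, 16 * b, 2 * b, 4 * b),
        RSUConfig(5, 8 * b, b, 2 * b),
        RSUConfig(6, 4 * b, half, b),
        RSUConfig(7, 2 * b, quarter, b),
    ]
    return encoders, decoders


@dataclass
class U2NetConfig:
    """Architecture hyperparameters of the generator.

    ``base_channels`` scales every stage width; 64 is the published full-size
    network, 8 or 4 gives a desk-scale model with identical topology.
    ``fast_channel`` names the input channel carrying the fast SPECT slice,
    which feeds the long skip connection.
    """

    in_channels: int = 2
    base_channels: int = 64
    n_side_outputs: int = 6
    fast_channel: int = 0
    seed: int = 0
    dtype: str = "float32"
    encoder_blocks: Optional[List[RSUConfig]] = None
    decoder_blocks: Optional[List[RSUConfig]] = None

    def __post_init__(self):
        if self.encoder_blocks is None or self.decoder_blocks is None:
            enc, dec = _default_stages(self.base_channels, self.in_channels)
            self.encoder_blocks = self.encoder_blocks or enc
            self.decoder_blocks = self.decoder_blocks or dec
        if len(self.encoder_blocks) != 6 or len(self.decoder_blocks) != 5:
            raise ContractError("expected 6 encoder and 5 decoder stages")
        n_dil = sum(c.dilated for c in self.encoder_blocks + self.decoder_blocks)
        if n_dil != 3:
            raise ContractError(f"expected exactly 3 dilated stages, found {n_dil}")
        if self.n_side_outputs != 6:
            raise ContractError("the architecture produces exactly 6 side outputs")
        if not 0 <= self.fast_channel < self.in_channels:
            raise ContractError("fast_channel outside input channel range")


class U2Net(nn.Module):
    """Six-stage nested-U encoder/decoder with deep-supervision side outputs."""

    def __init__(self, cfg: U2NetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        dtype = np.dtype(cfg.dtype)
        self.encoders = nn.ModuleList([RSU(c, rng, dtype) for c in cfg.encoder_blocks])
        self.decoders = nn.ModuleList([RSU(c, rng, dtype) for c in cfg.decoder_blocks])
        # side taps: decoder stages De-5..De-1 plus the deepest encoder En-6
        side_srcs = ([cfg.decoder_blocks[-1 - i].out_channels for i in range(5)]
                     + [cfg.encoder_blocks[-1].out_channels])
        self.side_convs = nn.ModuleList(
            [nn.Conv2d(c, 1, 3, rng=rng, dtype=dtype) for c in side_srcs])
        for conv in self.side_convs:
            # mean-normalized targets have unit DC level; starting the side
            # heads there saves the first chunk of training
            conv.bias.data[...] = 1.0
        # the fusion head sees the six side outputs plus the fast-SPECT channel
        # of the long skip: with the skip added after the 1x1 convolution, the
        # head must be able to trade input noise against the side estimates
        # (weighting the skip channel toward -1), otherwise the additive skip
        # pins the final image to the noisy input
        self.fuse = nn.Conv2d(7, 1, 1, rng=rng, dtype=dtype)
        # identity start: with a zeroed fusion head the long skip makes the
        # network an exact pass-through of the fast-SPECT channel, so training
        # can only move away from the input where the loss says to
        self.fuse.weight.data[...] = 0

    def forward(self, x) -> Tuple[Tensor, List[Tensor]]:
        """Run one slab of slices; returns (final, [Sup1..Sup6]).

        ``x``: (N, C, H, W) with H, W divisible by 32.  Sup1 comes from the
        full-resolution decoder, Sup6 from the deepest encoder; all are
        upsampled to the input size.  final = 1x1-fusion of the six side
        outputs plus the fast-SPECT input channel (long skip).
        """
        x = nn.as_tensor(x)
        if x.data.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ShapeError(
                f"expected (N, {self.cfg.in_channels}, H, W) input, got {x.shape}")
        H, W = x.shape[-2:]
        if H % OUTER_DIVISOR or W % OUTER_DIVISOR:
            raise ShapeError(
                f"input sides must be divisible by {OUTER_DIVISOR}, got {H}x{W}")

        enc_feats = []
        h = x
        for i, enc in enumerate(self.encoders):
            h = enc(h if i == 0 else nn.maxpool2(h))
            enc_feats.append(h)

        dec_feats = []  # De-5 ... De-1
        h = enc_feats[-1]
        for dec, skip in zip(self.decoders, enc_feats[-2::-1]):
            h = dec(nn.concat([nn.upsample_bilinear(h, skip.shape[-2:]), skip], axis=1))
            dec_feats.append(h)

        taps = [dec_feats[4], dec_feats[3], dec_feats[2], dec_feats[1], dec_feats[0],
                enc_feats[5]]  # Sup1..Sup6
        sides = []
        for conv, feat in zip(self.side_convs, taps):
            s = conv(feat)
            if s.shape[-2:] != (H, W):
                s = nn.upsample_bilinear(s, (H, W))
            sides.append(s)
        fast = nn.channel_slice(x, self.cfg.fast_channel, self.cfg.fast_channel + 1)
        fused = self.fuse(nn.concat(sides + [fast], axis=1))
        final = fused + fast
        return final, sides

    @property
    def n_dilated_stages(self) -> int:
        return sum(c.dilated for c in self.cfg.encoder_blocks + self.cfg.decoder_blocks)


def build_u2net(cfg: U2NetConfig | None = None, **kwargs) -> U2Net:
    """Construct the generator; kwargs override U2NetConfig fields."""
    if cfg is None:
        cfg = U2NetConfig(**kwargs)
    elif kwargs:
        raise ContractError("pass either a config or keyword overrides, not both")
    return U2Net(cfg)


def save_checkpoint(model: U2Net, path):
    """Single-file checkpoint: parameter/buffer arrays plus a config echo."""
    import json

    cfg = model.cfg
    meta = dict(in_channels=cfg.in_channels, base_channels=cfg.base_channels,
                fast_channel=cfg.fast_channel, seed=cfg.seed, dtype=cfg.dtype)
    state = model.state_dict()
    np.savez(path, __config__=json.dumps(meta), **state)


def load_checkpoint(path) -> U2Net:
    import json

    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["__config__"]))
        state = {k: f[k] for k in f.files if k != "__config__"}
    model = U2Net(U2NetConfig(**meta))
    model.load_state_dict(state)
    return model
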