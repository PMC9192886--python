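"""Layer/module system on top of the tensor engine.

Modules discover parameters and sub-modules by attribute scan (lists of
modules are supported via ``ModuleList``), mirroring the familiar
torch.nn idiom at a fraction of the surface.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Tuple

import numpy as np

from .tensor import Tensor, batchnorm2d_train, conv2d, relu


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    training: bool = True

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{full}.")

    def modules(self) -> Iterator["Module"]:
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- checkpointing -----------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, val in self._named_buffers():
            state[name] = val.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        bufs = dict(self._named_buffers())
        for key, arr in state.items():
            if key in own:
                own[key].data = np.asarray(arr).astype(own[key].dtype, copy=True)
            elif key in bufs:
                bufs[key][...] = arr
            else:
                raise KeyError(f"unexpected checkpoint entry {key!r}")
        missing = (set(own) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing entries: {sorted(missing)}")

    def _named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Module):
                yield from val._named_buffers(f"{full}.")
            elif isinstance(val, np.ndarray) and name.startswith("running_"):
                yield full, val

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods: List[Module]):
        self._mods = list(mods)

    def __iter__(self):
        return iter(self._mods)

    def __getitem__(self, i):
        return self._mods[i]

    def __len__(self):
        return len(self._mods)

    def named_parameters(self, prefix: str = ""):
        for i, m in enumerate(self._mods):
            yield from m.named_parameters(f"{prefix}{i}.")

    def modules(self):
        yield self
        for m in self._mods:
            yield from m.modules()

    def _named_buffers(self, prefix: str = ""):
        for i, m in enumerate(self._mods):
            yield from m._named_buffers(f"{prefix}{i}.")


class Conv2d(Module):
    """Stride-1 convolution; Kaiming fan-in init from the supplied rng."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, dilation: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.weight = Parameter(
            rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)).astype(dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None
        self.dilation = dilation

    def forward(self, x, padding: str = "same"):
        return conv2d(x, self.weight, self.bias, dilation=self.dilation, padding=padding)


class BatchNorm2d(Module):
    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        self.gamma = Parameter(np.ones(n_ch, dtype=dtype))
        self.beta = Parameter(np.zeros(n_ch, dtype=dtype))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(n_ch, dtype=np.float64)
        self.running_var = np.ones(n_ch, dtype=np.float64)

    def forward(self, x):
        if self.training:
            out, mu, var = batchnorm2d_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mu
            self.running_var[...] = (1 - m) * self.running_var + m * var
            return out
        scale = (self.gamma.data / np.sqrt(self.running_var + self.eps)).astype(x.dtype)
        shift = (self.beta.data - self.running_mean * scale).astype(x.dtype)
        return x * Tensor(scale.reshape(1, -1, 1, 1)) + Tensor(shift.reshape(1, -1, 1, 1))


class ConvBNReLU(Module):
    """conv3x3 (optionally dilated) -> batch norm -> ReLU, the RSU unit cell."""

    def __init__(self, in_ch: int, out_ch: int, dilation: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        # no conv bias: batch norm's shift makes it redundant
        self.conv = Conv2d(in_ch, out_ch, 3, dilation=dilation, bias=False,
                           rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(out_ch, dtype=dtype)

    def forward(self, x):
        return relu(self.bn(self.conv(x)))
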