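"""Layer/module abstractions over the autograd engine.

Initialisation is He-uniform (fan-in), drawn from a generator the caller
supplies so that a fixed seed yields bit-identical parameters.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: tracks parameters and training mode recursively."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for name, m in self._modules.items():
            out.extend(m.named_parameters(prefix + name + "."))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- flat state (used for checkpoints) -----------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for n, p in self.named_parameters():
            p.data = np.asarray(state[n], dtype=p.data.dtype).copy()
        for name, buf in self.named_buffers():
            buf[...] = state[name]

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = []
        for attr in ("running_mean", "running_var"):
            buf = self.__dict__.get(attr)
            if isinstance(buf, np.ndarray):
                out.append((prefix + attr, buf))
        for name, m in self._modules.items():
            out.extend(m.named_buffers(prefix + name + "."))
        return out


def he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.k = k
        self.pad = k // 2
        self.weight = Tensor(
            he_uniform(rng, (cout, cin, k, k), fan_in=cin * k * k), requires_grad=True
        )
        self.bias = (
            Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
            if bias else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, self.pad)


class ConvTranspose2d(Module):
    """Kernel-2 stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(
            he_uniform(rng, (cin, cout, 2, 2), fan_in=cin * 4), requires_grad=True
        )
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.batch_norm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class ConvBlock(Module):
    """`n_convs` x [conv -> (batchnorm) -> ReLU], the UNet building block."""

    def __init__(self, cin: int, cout: int, k: int, n_convs: int,
                 batchnorm: bool, rng: np.random.Generator):
        super().__init__()
        self.n_convs = n_convs
        self.batchnorm = batchnorm
        for j in range(n_convs):
            conv = Conv2d(cin if j == 0 else cout, cout, k, rng, bias=not batchnorm)
            setattr(self, f"conv{j}", conv)
            if batchnorm:
                setattr(self, f"bn{j}", BatchNorm2d(cout))

    def __call__(self, x: Tensor) -> Tensor:
        for j in range(self.n_convs):
            x = getattr(self, f"conv{j}")(x)
            if self.batchnorm:
                x = getattr(self, f"bn{j}")(x)
            x = ag.relu(x)
        return x
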