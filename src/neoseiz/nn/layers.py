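"""Neural-network building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import (
    Tensor,
    adaptive_avg_pool2d,
    concatenate,
    conv2d,
    dropout,
    max_pool2d,
    stack,
)

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "BatchNorm2d",
    "MaxPool2d",
    "AdaptiveAvgPool2d",
    "ReLU",
    "Dropout",
    "Sequential",
    "BiLSTM",
]


class Module:
    """Base class with parameter discovery, train/eval mode and state I/O."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def _children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        yield v

    def named_parameters(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield from v.named_parameters(prefix=f"{key}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and not value.requires_grad:
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_buffers(prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield from v.named_buffers(prefix=f"{key}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({k: v.data.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        own.update(dict(self.named_buffers()))
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)}")
        for key, tensor in own.items():
            arr = np.asarray(state[key])
            if arr.shape != tensor.data.shape:
                raise ValueError(f"shape mismatch for {key}: {arr.shape} vs {tensor.data.shape}")
            tensor.data = arr.astype(tensor.data.dtype, copy=True)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        bound = 1.0 / np.sqrt(in_dim)
        self.weight = Tensor(rng.uniform(-bound, bound, (out_dim, in_dim)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, out_dim).astype(np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = False):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(_kaiming(rng, (out_ch, in_ch, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Tensor(np.ones(num_features, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features, dtype=np.float32), requires_grad=True)
        self.running_mean = Tensor(np.zeros(num_features, dtype=np.float32))
        self.running_var = Tensor(np.ones(num_features, dtype=np.float32))
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean.data = (1 - m) * self.running_mean.data + m * mean.data.ravel()
            self.running_var.data = (1 - m) * self.running_var.data + m * var.data.ravel()
            xhat = (x - mean) / ((var + self.eps) ** 0.5)
        else:
            mean = Tensor(self.running_mean.data.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.data.reshape(1, -1, 1, 1))
            xhat = (x - mean) / ((var + self.eps) ** 0.5)
        w = self.weight.reshape(1, -1, 1, 1)
        b = self.bias.reshape(1, -1, 1, 1)
        return xhat * w + b


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel, self.stride, self.padding)


class AdaptiveAvgPool2d(Module):
    def __init__(self, out_hw: tuple[int, int]):
        super().__init__()
        self.out_hw = out_hw

    def forward(self, x: Tensor) -> Tensor:
        return adaptive_avg_pool2d(x, self.out_hw)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return dropout(x, self.p, self.rng, self.training)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x


class _LSTMCellParams(Module):
    """One direction's weights: gates ordered (input, forget, cell, output)."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(hidden)
        self.w_ih = Tensor(rng.uniform(-bound, bound, (4 * hidden, input_dim)).astype(np.float32),
                           requires_grad=True)
        self.w_hh = Tensor(rng.uniform(-bound, bound, (4 * hidden, hidden)).astype(np.float32),
                           requires_grad=True)
        self.bias = Tensor(np.zeros(4 * hidden, dtype=np.float32), requires_grad=True)
        self.hidden = hidden

    def step(self, x_t: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        hd = self.hidden
        gates = x_t @ self.w_ih.transpose(1, 0) + h @ self.w_hh.transpose(1, 0) + self.bias
        i = gates[:, 0 * hd:1 * hd].sigmoid()
        f = gates[:, 1 * hd:2 * hd].sigmoid()
        g = gates[:, 2 * hd:3 * hd].tanh()
        o = gates[:, 3 * hd:4 * hd].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new


class BiLSTM(Module):
    """Bidirectional LSTM over axis 1; outputs concatenated fwd/bwd hidden states."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = _LSTMCellParams(input_dim, hidden, rng)
        self.bwd = _LSTMCellParams(input_dim, hidden, rng)
        self.hidden = hidden

    def _run(self, cell: _LSTMCellParams, x: Tensor, reverse: bool) -> list[Tensor]:
        n, steps, _ = x.shape
        h = Tensor(np.zeros((n, cell.hidden), dtype=np.float32))
        c = Tensor(np.zeros((n, cell.hidden), dtype=np.float32))
        order = range(steps - 1, -1, -1) if reverse else range(steps)
        outs: dict[int, Tensor] = {}
        for t in order:
            h, c = cell.step(x[:, t, :], h, c)
            outs[t] = h
        return [outs[t] for t in range(steps)]

    def forward(self, x: Tensor) -> Tensor:
        f_out = self._run(self.fwd, x, reverse=False)
        b_out = self._run(self.bwd, x, reverse=True)
        per_step = [concatenate([f, b], axis=1) for f, b in zip(f_out, b_out)]
        return stack(per_step, axis=1)  # (N, steps, 2*hidden)
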