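"""Network building blocks on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

__all__ = ["Module", "Linear", "Conv2d", "ResidualBlock", "Adam"]


class Module:
    """Base class: parameter registry plus train/eval no-ops."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"expected {len(params)} weight arrays, got {len(arrays)}"
            )
        for p, a in zip(params, arrays):
            a = np.asarray(a, dtype=np.float32)
            if a.shape != p.data.shape:
                raise ValueError(f"shape mismatch: {a.shape} vs {p.data.shape}")
            p.data = a.copy()


class Linear(Module):
    """Affine layer with He-scaled initialisation."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, (d_in, d_out)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int | None = None,
    ):
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, (c_out, c_in, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class ResidualBlock(Module):
    """Two 3x3 convolutions with an identity skip (channel-preserving)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = Conv2d(channels, channels, 3, rng)
        self.conv2 = Conv2d(channels, channels, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv1(x).relu()
        h = self.conv2(h)
        return (h + x).relu()


class Adam:
    """Adaptive-moment gradient optimiser with decoupled weight decay."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            update = mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and p.data.ndim > 1:  # decay weights, not biases
                update = update + self.weight_decay * p.data
            p.data = p.data - self.lr * update
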