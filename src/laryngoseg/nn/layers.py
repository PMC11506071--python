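"""Neural-network building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

__all__ = ["Module", "Conv2d", "Linear", "InstanceNorm", "ResidualUnit"]


class Module:
    """Minimal parameter container with recursive named-parameter access."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        found: list[tuple[str, Tensor]] = []
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                found.append((key, value))
            elif isinstance(value, Module):
                found.extend(value.named_parameters(prefix=f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        found.extend(item.named_parameters(prefix=f"{key}.{i}."))
        return found

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, t in own.items():
            if t.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            t.data = state[name].astype(np.float32).copy()

    def zero_grad(self) -> None:
        for t in self.parameters():
            t.zero_grad()


class Conv2d(Module):
    """3×3/1×1 convolution with He-normal init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 padding: int | None = None, rng: np.random.Generator | None = None,
                 bias: bool = True):
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        scale = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.weight = Tensor(rng.normal(0.0, scale, size=(out_ch, in_ch, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    """Affine map; used for all encoder heads (deliberately no activation)."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(1.0 / in_features)
        self.weight = Tensor(rng.normal(0.0, scale, size=(in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class InstanceNorm(Module):
    """Per-sample, per-channel normalization over the spatial axes.

    Deterministic at train and inference time (no running statistics),
    which keeps seeded runs exactly reproducible.  Renormalizing after
    every downsampling convolution is what keeps feature scales alive when
    the critic's weights are clipped to a small range.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=(2, 3), keepdims=True)
        inv = (var + self.eps).pow(-0.5)
        return centered * inv * self.gamma + self.beta


class ResidualUnit(Module):
    """The basic detour unit F(x) + x with two 3×3 convolutions.

    With all weights zeroed it is exactly the identity map, which the skip
    connections rely on at initialization time (second conv is zero-init so
    every unit starts as the identity).
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.conv1 = Conv2d(channels, channels, 3, rng=rng)
        self.conv2 = Conv2d(channels, channels, 3, rng=rng)
        self.conv2.weight.data[:] = 0.0

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv2(self.conv1(x).relu()) + x
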