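"""Layer objects over the autodiff primitives: parameters, conv, batchnorm."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, batch_norm, conv2d, relu

__all__ = ["Module", "Conv2d", "BatchNorm2d", "ConvBlock"]


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def modules(self) -> list["Module"]:
        out: list[Module] = [self]
        for value in self.__dict__.values():
            if isinstance(value, Module):
                out.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name → array mapping of parameters and buffers (stable order)."""
        out: dict[str, np.ndarray] = {}

        def walk(obj: "Module", prefix: str) -> None:
            for name, value in obj.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(value, Tensor) and value.requires_grad:
                    out[key] = value.data
                elif isinstance(value, np.ndarray):
                    out[key] = value
                elif isinstance(value, Module):
                    walk(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state mismatch, differing keys: {sorted(missing)[:5]}")
        for key, arr in own.items():
            arr[...] = state[key]


class Conv2d(Module):
    """Stride-1 convolution with He-normal weights and zero bias.

    Weights are (k, k, in_channels, out_channels) to match the NHWC engine.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, (kernel_size, kernel_size, in_channels, out_channels))
            .astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, dtype=np.float32) -> None:
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def __call__(self, x: Tensor) -> Tensor:
        return batch_norm(x, self.gamma, self.beta, self.running_mean,
                          self.running_var, training=self.training)


class ConvBlock(Module):
    """Two 3×3 convolutions, each followed by batch norm and ReLU."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.conv1 = Conv2d(in_channels, out_channels, 3, rng, dtype)
        self.bn1 = BatchNorm2d(out_channels, dtype)
        self.conv2 = Conv2d(out_channels, out_channels, 3, rng, dtype)
        self.bn2 = BatchNorm2d(out_channels, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        x = relu(self.bn1(self.conv1(x)))
        return relu(self.bn2(self.conv2(x)))
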