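"""Minimal define-by-layer neural-network engine on numpy.

Every layer is a :class:`Module` with an explicit ``forward`` that
caches what its ``backward`` needs; ``backward`` consumes the upstream
gradient, accumulates parameter gradients in place and returns the
gradient with respect to its input. Containers discover child modules
and parameters by attribute scan, so composite blocks read like plain
dataclasses. All arrays are float32; all initialization randomness
comes from an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

__all__ = ["Parameter", "Module", "Sequential", "he_normal"]


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """Kaiming-normal initialization for ReLU networks."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Module:
    training: bool = True

    # -- introspection -------------------------------------------------
    def children(self) -> Iterator["Module"]:
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list[Parameter], seen: set[int]) -> None:
        for value in self.__dict__.values():
            items = value if isinstance(value, (list, tuple)) else [value]
            for item in items:
                if isinstance(item, Parameter) and id(item) not in seen:
                    seen.add(id(item))
                    params.append(item)
                elif isinstance(item, Module):
                    item._collect(params, seen)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self, flag: bool = True) -> "Module":
        self.training = flag
        for child in self.children():
            child.train(flag)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- compute -------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    # -- (de)serialization --------------------------------------------
    buffer_names: tuple[str, ...] = ()  # non-trainable state (e.g. BN running stats)

    def _all_modules(self) -> Iterator["Module"]:
        yield self
        for child in self.children():
            yield from child._all_modules()

    def _buffers(self) -> list[np.ndarray]:
        out = []
        for mod in self._all_modules():
            for name in mod.buffer_names:
                out.append((mod, name))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        for i, (mod, name) in enumerate(self._buffers()):
            state[f"b{i}"] = getattr(mod, name)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        buffers = self._buffers()
        if len(state) != len(params) + len(buffers):
            raise ValueError(
                f"state has {len(state)} arrays, model expects {len(params) + len(buffers)}"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch at parameter {i}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
        for i, (mod, name) in enumerate(buffers):
            setattr(mod, name, np.asarray(state[f"b{i}"], dtype=np.float32).copy())


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout
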