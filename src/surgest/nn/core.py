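"""Minimal layer/parameter machinery for the CPU training engine.

Every layer implements ``forward`` (caching what its gradient needs) and
``backward`` (consuming the cache, accumulating parameter gradients and
returning the gradient w.r.t. its input).  Backward must directly follow the
matching forward, which is all the training loops in this package require.
All parameters are float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Parameter", "Module", "Sequential", "set_trainable"]


class Parameter:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray, trainable: bool = True):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable

    @property
    def shape(self):
        return self.value.shape


class Module:
    """Base class; children discovered by attribute walk (sorted for determinism)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)

    # -- parameter / buffer traversal ------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, child in sorted(vars(self).items()):
            full = f"{prefix}{name}"
            if isinstance(child, Parameter):
                yield full, child
            elif isinstance(child, Module):
                yield from child.named_parameters(full + ".")
            elif isinstance(child, (list, tuple)):
                for i, item in enumerate(child):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- buffers (non-trainable state such as batch-norm running stats) --
    def named_buffers(self, prefix: str = ""):
        for name in sorted(getattr(self, "_buffers", ())):
            yield f"{prefix}{name}", getattr(self, name)
        for name, child in sorted(vars(self).items()):
            full = f"{prefix}{name}"
            if isinstance(child, Module):
                yield from child.named_buffers(full + ".")
            elif isinstance(child, (list, tuple)):
                for i, item in enumerate(child):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")

    # -- (de)serialisation -----------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.value for name, p in self.named_parameters()}
        state.update({f"buffer:{name}": b for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            if name not in state:
                raise KeyError(f"missing parameter {name!r} in state dict")
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.value.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: expected {p.value.shape}, got {arr.shape}"
                )
            p.value[...] = arr
        for name, buf in self.named_buffers():
            key = f"buffer:{name}"
            if key in state:
                buf[...] = np.asarray(state[key], dtype=buf.dtype)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def set_trainable(module: Module, flag: bool) -> None:
    for p in module.parameters():
        p.trainable = flag
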