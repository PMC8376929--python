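"""Module/Parameter containers for the numpy network layers."""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable tensor with an accumulated gradient of the same shape."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover
        return f"Parameter({self.name or 'unnamed'}, shape={self.data.shape})"


class Module:
    """Base class: tracks sub-modules and parameters via attribute assignment.

    Subclasses implement ``forward(x)`` and ``backward(grad_out)``; ``backward``
    must accumulate parameter gradients and return the gradient with respect to
    the module input.
    """

    def __init__(self):
        self.training = True

    # -- parameter / module discovery -------------------------------------
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for obj in self.__dict__.values():
            for p in _collect(obj):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for obj in self.__dict__.values():
            mods.extend(_collect_modules(obj))
        return mods

    # -- mode switches ------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- state (de)serialization -------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data[...] = arr

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


def _collect(obj) -> list[Parameter]:
    if isinstance(obj, Parameter):
        return [obj]
    if isinstance(obj, Module):
        return obj.parameters()
    if isinstance(obj, (list, tuple)):
        out = []
        for o in obj:
            out.extend(_collect(o))
        return out
    return []


def _collect_modules(obj) -> list["Module"]:
    if isinstance(obj, Module):
        return obj.modules()
    if isinstance(obj, (list, tuple)):
        out = []
        for o in obj:
            out.extend(_collect_modules(o))
        return out
    return []


class Sequential(Module):
    """Chain of layers; backward runs the chain in reverse."""

    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
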