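"""Minimal trainable-layer framework on numpy arrays.

Layers cache what their backward pass needs during ``forward`` and release it
after ``backward``; a module is therefore not reentrant within one step.
All parameters are float32. Gradients accumulate into ``Parameter.grad``
until ``zero_grad``.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    @property
    def shape(self):
        return self.data.shape


class Module:
    """Base class: tracks parameters and sub-modules by attribute name."""

    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- parameter bookkeeping -------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def modules(self):
        """This module and every sub-module, depth first."""
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._modules.items():
            for k, v in m.extra_state().items():
                state[f"{name}.{k}"] = v.copy()
        state.update(self.extra_state())
        return state

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        extra = self._extra_state_slots()
        for key, value in state.items():
            if key in own:
                if own[key].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {key}: "
                        f"{own[key].data.shape} vs {value.shape}"
                    )
                own[key].data[...] = value
            elif key in extra:
                extra[key][...] = value
            else:
                raise KeyError(f"unexpected state entry {key!r}")

    def extra_state(self) -> dict:
        """Non-trainable buffers (e.g. batch-norm running stats)."""
        return {}

    def _extra_state_slots(self, prefix: str = "") -> dict:
        slots = {prefix + k: v for k, v in self.extra_state().items()}
        for name, m in self._modules.items():
            slots.update(m._extra_state_slots(prefix + name + "."))
        return slots

    # -- computation ------------------------------------------------------
    def forward(self, x, train: bool = True):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x, train: bool = True):
        return self.forward(x, train=train)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x, train: bool = True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """Kaiming-normal initialization for ReLU networks."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)
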