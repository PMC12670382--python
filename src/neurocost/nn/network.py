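"""Sequential network container with residual branches and seeded init."""

from __future__ import annotations

import hashlib
from typing import Iterable, Iterator

import numpy as np

from .layers import Layer


class Residual(Layer):
    """Identity-skip container: y = F(x) + x, F a list of layers.

    The inner path must preserve shape (projection shortcuts are expressed by
    putting the projection inside an outer Sequential stage instead).
    """

    name = "residual"

    def __init__(self, inner: list[Layer]):
        self.inner = list(inner)

    def initialize(self, rng: np.random.Generator) -> None:
        for layer in self.inner:
            layer.initialize(rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x
        for layer in self.inner:
            out = layer.forward(out)
        return out + x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad
        for layer in reversed(self.inner):
            g = layer.backward(g)
        return g + grad

    def params_and_grads(self):
        out = []
        for layer in self.inner:
            out.extend(layer.params_and_grads())
        return out


class Network:
    """An ordered stack of layers, identified by name, with seeded init.

    ``forward`` optionally records the output tensor of every atomic layer in
    execution order (descending into :class:`Residual`, plus one event for the
    skip-addition), which is what block-wise activation capture consumes.
    """

    def __init__(self, layers: list[Layer], name: str = "net"):
        self.layers = list(layers)
        self.name = name
        seen: set[int] = set()
        for layer in self.iter_atomic():
            if layer.has_params:
                if id(layer) in seen:
                    raise ValueError(
                        f"weight sharing detected: layer {layer.name!r} appears twice")
                seen.add(id(layer))

    # -- structure ---------------------------------------------------------

    def iter_atomic(self) -> Iterator[Layer]:
        """Yield non-container layers in execution order."""
        for layer in self.layers:
            if isinstance(layer, Residual):
                yield from layer.inner
            else:
                yield layer

    @property
    def parameterized_layers(self) -> list[Layer]:
        return [l for l in self.iter_atomic() if l.has_params]

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.parameterized_layers)

    # -- parameters --------------------------------------------------------

    def initialize(self, seed: int) -> "Network":
        """(Re-)draw all parameters from the seeded default initializer."""
        rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.initialize(rng)
        return self

    @property
    def initialized(self) -> bool:
        return all(l.initialized for l in self.parameterized_layers)

    def weight_checksum(self) -> str:
        """SHA-256 over all parameter bytes, in layer order."""
        h = hashlib.sha256()
        for layer in self.parameterized_layers:
            h.update(np.ascontiguousarray(layer.weight).tobytes())
            h.update(np.ascontiguousarray(layer.bias).tobytes())
        return h.hexdigest()

    def params_and_grads(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params_and_grads())
        return out

    # -- execution ---------------------------------------------------------

    def forward(self, x: np.ndarray, record: bool = False):
        """Run the network. With ``record=True`` also return the list of
        (layer-or-tag, output) events in execution order."""
        events: list[tuple[object, np.ndarray]] = []
        out = x
        for layer in self.layers:
            if isinstance(layer, Residual) and record:
                inner = out
                for sub in layer.inner:
                    inner = sub.forward(inner)
                    events.append((sub, inner))
                out = inner + out
                events.append(("residual_add", out))
            else:
                out = layer.forward(out)
                if record:
                    events.append((layer, out))
        return (out, events) if record else out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def sgd_step(self, lr: float, momentum: float = 0.0) -> None:
        for owner, pname, gname in self.params_and_grads():
            grad = getattr(owner, gname)
            if grad is None:
                continue
            if momentum:
                vname = "_vel_" + pname
                vel = getattr(owner, vname, None)
                vel = momentum * vel - lr * grad if vel is not None else -lr * grad
                setattr(owner, vname, vel)
                getattr(owner, pname)[...] += vel
            else:
                getattr(owner, pname)[...] -= lr * grad


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(probs[np.arange(n), labels] + 1e-12).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n
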