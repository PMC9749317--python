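"""Model containers, softmax cross-entropy loss and Adam."""

from __future__ import annotations

import copy

import numpy as np


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray) -> tuple:
    """Mean cross-entropy over the batch and the gradient w.r.t. logits.

    ``labels`` are integer class indices.
    """
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class _Base:
    def parameters(self) -> list:
        raise NotImplementedError

    def gradients(self) -> list:
        raise NotImplementedError

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def get_weights(self) -> list:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list) -> None:
        for p, w in zip(self.parameters(), weights):
            p[...] = w

    def get_state(self) -> dict:
        """Weights plus batch-norm running statistics."""
        return {
            "weights": self.get_weights(),
            "bn": copy.deepcopy([(l.running_mean, l.running_var)
                                 for l in self._bn_layers()]),
        }

    def set_state(self, state: dict) -> None:
        self.set_weights(state["weights"])
        for l, (m, v) in zip(self._bn_layers(), state["bn"]):
            l.running_mean = m.copy()
            l.running_var = v.copy()

    def _bn_layers(self):
        raise NotImplementedError

    def predict_proba(self, x, batch_size: int = 64) -> np.ndarray:
        """Softmax class probabilities in inference mode."""
        outs = []
        n = x[0].shape[0] if isinstance(x, list) else x.shape[0]
        for i in range(0, n, batch_size):
            xb = ([xi[i:i + batch_size] for xi in x]
                  if isinstance(x, list) else x[i:i + batch_size])
            outs.append(softmax(self.forward(xb, train=False)))
        return np.concatenate(outs, axis=0)


def _iter_bn(layers):
    from .layers import BatchNorm, ResidualConv1D
    for l in layers:
        if isinstance(l, BatchNorm):
            yield l
        elif isinstance(l, ResidualConv1D):
            yield l.bn


class Sequential(_Base):
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x, train: bool = False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g

    def parameters(self):
        return [p for l in self.layers for p in l.params]

    def gradients(self):
        return [g for l in self.layers for g in l.grads]

    def _bn_layers(self):
        return list(_iter_bn(self.layers))


class MultiInputModel(_Base):
    """Parallel branches over per-channel inputs, features concatenated
    into a shared head.  Branch weights are independent objects."""

    def __init__(self, branches: list, head: Sequential):
        self.branches = branches
        self.head = head

    @property
    def n_inputs(self) -> int:
        return len(self.branches)

    def forward(self, xs: list, train: bool = False):
        if len(xs) != len(self.branches):
            raise ValueError(f"expected {len(self.branches)} inputs, got {len(xs)}")
        feats = [b.forward(x, train=train) for b, x in zip(self.branches, xs)]
        self._widths = [f.shape[1] for f in feats]
        return self.head.forward(np.concatenate(feats, axis=1), train=train)

    def backward(self, g):
        g = self.head.backward(g)
        outs = []
        start = 0
        for b, w in zip(self.branches, self._widths):
            outs.append(b.backward(g[:, start:start + w]))
            start += w
        return outs

    def parameters(self):
        ps = [p for b in self.branches for p in b.parameters()]
        return ps + self.head.parameters()

    def gradients(self):
        gs = [g for b in self.branches for g in b.gradients()]
        return gs + self.head.gradients()

    def _bn_layers(self):
        out = []
        for b in self.branches:
            out.extend(b._bn_layers())
        out.extend(self.head._bn_layers())
        return out


class Adam:
    """Adam with Keras-style defaults (eps 1e-7)."""

    def __init__(self, params: list, grads: list, lr: float = 0.0011,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
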