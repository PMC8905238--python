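"""SGD-with-momentum and Adam optimizers over (layer, name) parameter lists."""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, parameters, lr: float):
        self.parameters = list(parameters)
        self.lr = float(lr)

    def step(self):  # pragma: no cover - abstract
        raise NotImplementedError

    def zero_grad(self):
        for layer, name in self.parameters:
            layer.grads.pop(name, None)


class SGD(Optimizer):
    def __init__(self, parameters, lr: float, momentum: float = 0.9):
        super().__init__(parameters, lr)
        self.momentum = momentum
        self._velocity = [np.zeros_like(layer.params[name])
                          for layer, name in self.parameters]

    def step(self):
        for v, (layer, name) in zip(self._velocity, self.parameters):
            g = layer.grads[name]
            v *= self.momentum
            v -= self.lr * g
            layer.params[name] += v


class Adam(Optimizer):
    def __init__(self, parameters, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        super().__init__(parameters, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(layer.params[name]) for layer, name in self.parameters]
        self._v = [np.zeros_like(layer.params[name]) for layer, name in self.parameters]
        self._t = 0

    def step(self):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self._t
        bias2 = 1.0 - b2 ** self._t
        for m, v, (layer, name) in zip(self._m, self._v, self.parameters):
            g = layer.grads[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            layer.params[name] -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
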