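"""Adam and a reduce-on-plateau learning-rate scheduler."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class Adam:
    """Adam with bias correction; betas default to the conventional (0.9, 0.999)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * np.square(p.grad)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class ReduceLROnPlateau:
    """Cut the learning rate by ``factor`` after ``patience`` consecutive
    epochs without sufficient relative improvement of the monitored loss.

    An epoch *improves* iff its loss is below ``best * (1 - threshold)``
    where ``best`` is the minimum loss seen so far (so sub-threshold drift
    never counts as improvement).  The rate is reduced on the
    (patience+1)-th consecutive non-improving epoch and the counter resets.
    """

    def __init__(self, optimizer: Adam, factor: float = 0.3, patience: int = 8,
                 threshold: float = 0.01):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.threshold = threshold
        self.best = np.inf
        self.num_bad_epochs = 0

    def is_better(self, value: float) -> bool:
        return value < self.best * (1.0 - self.threshold)

    def step(self, value: float) -> float:
        """Register one epoch's monitored loss; returns the (possibly new) lr."""
        if self.is_better(value):
            self.num_bad_epochs = 0
        else:
            self.num_bad_epochs += 1
            if self.num_bad_epochs > self.patience:
                self.optimizer.lr *= self.factor
                self.num_bad_epochs = 0
        self.best = min(self.best, value)
        return self.optimizer.lr
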