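"""Adam optimizer (Kingma & Ba) for the NumPy autograd engine."""

from __future__ import annotations

import numpy as np

from plantsr.nn.tensor import DTYPE, Tensor


class Adam:
    """Adam with bias-corrected first/second moment estimates.

    Defaults: β₁ = 0.9, β₂ = 0.999, ε = 1e-8. A learning rate of 0 leaves
    parameters exactly unchanged.
    """

    def __init__(
        self,
        params,
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params: list[Tensor] = list(params)
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        if self.lr == 0:
            return
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= np.asarray(
                self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps), dtype=DTYPE
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
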