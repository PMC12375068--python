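"""First-order optimizers over lists of parameters.

Update rules follow the common framework defaults (decay rates, epsilons)
so a named optimizer behaves the way practitioners expect.  Every optimizer
holds its slot variables per parameter and is deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["make_optimizer", "OPTIMIZERS"]


class _Optimizer:
    def __init__(self, params, lr):
        self.params = list(params)
        self.lr = lr
        self.t = 0

    def step(self):
        self.t += 1
        for p in self.params:
            if p.grad is not None:
                self._update(p, p.grad)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class SGD(_Optimizer):
    def _update(self, p, g):
        p.data -= self.lr * g


class Adam(_Optimizer):
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(params, lr)
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class Nadam(Adam):
    def step(self):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = self.b1 * m / bc1 + (1 - self.b1) * g / bc1
            p.data -= self.lr * mhat / (np.sqrt(v / bc2) + self.eps)


class RMSProp(_Optimizer):
    def __init__(self, params, lr, rho=0.9, eps=1e-7):
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self.acc = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for p, a in zip(self.params, self.acc):
            if p.grad is None:
                continue
            g = p.grad
            a += (1 - self.rho) * (g * g - a)
            p.data -= self.lr * g / (np.sqrt(a) + self.eps)


class Adamax(_Optimizer):
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(params, lr)
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.u = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        for p, m, u in zip(self.params, self.m, self.u):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - self.b1) * (g - m)
            np.maximum(self.b2 * u, np.abs(g), out=u)
            p.data -= self.lr * (m / bc1) / (u + self.eps)


class Adadelta(_Optimizer):
    def __init__(self, params, lr, rho=0.95, eps=1e-7):
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self.acc_g = [np.zeros_like(p.data) for p in self.params]
        self.acc_d = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for p, ag, ad in zip(self.params, self.acc_g, self.acc_d):
            if p.grad is None:
                continue
            g = p.grad
            ag += (1 - self.rho) * (g * g - ag)
            d = np.sqrt(ad + self.eps) / np.sqrt(ag + self.eps) * g
            ad += (1 - self.rho) * (d * d - ad)
            p.data -= self.lr * d


class Ftrl(_Optimizer):
    """Follow-the-regularized-leader with learning-rate power -1/2."""

    def __init__(self, params, lr, beta=0.0, l1=0.0, l2=0.0):
        super().__init__(params, lr)
        self.beta, self.l1, self.l2 = beta, l1, l2
        self.z = [np.zeros_like(p.data) for p in self.params]
        self.n = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for p, z, n in zip(self.params, self.z, self.n):
            if p.grad is None:
                continue
            g = p.grad
            n_new = n + g * g
            sigma = (np.sqrt(n_new) - np.sqrt(n)) / self.lr
            z += g - sigma * p.data
            n[...] = n_new
            quad = (self.beta + np.sqrt(n)) / self.lr + 2 * self.l2
            prox = np.clip(z, -self.l1, self.l1)
            # active iff |z| exceeds the l1 threshold and curvature has
            # accumulated (g*g may underflow to 0 in float32 while z != 0)
            upd = np.zeros_like(z)
            active = (np.abs(z) > self.l1) & (quad > 0)
            upd[active] = -(z[active] - prox[active]) / quad[active]
            p.data[...] = upd


OPTIMIZERS = {
    "sgd": SGD, "adam": Adam, "rmsprop": RMSProp, "adamax": Adamax,
    "adadelta": Adadelta, "nadam": Nadam, "ftrl": Ftrl,
}


def make_optimizer(name: str, params, lr: float):
    try:
        cls = OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}")
    return cls(params, lr)
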