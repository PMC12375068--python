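"""Trainable layers: parameter containers and the standard building layers.

Parameter-count convention
--------------------------
``Module.param_count()`` counts *every* per-layer array, i.e. weights, biases
and — for batch normalization — the scale, offset and the two running
statistics (4 values per channel).  This is the convention common framework
summaries print as the per-layer "Param #" column, and it is the convention
under which the architecture's published layer table is exactly reproducible.
Gradient-carrying parameters are the subset returned by ``parameters()``.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


# ---------------------------------------------------------------------------
# initializers
# ---------------------------------------------------------------------------

def fan_out_normal(rng: np.random.Generator, shape, fan_out: int) -> np.ndarray:
    """He-style normal init scaled by the fan-out of the layer (for convolutions)."""
    std = np.sqrt(2.0 / max(fan_out, 1))
    return rng.normal(0.0, std, size=shape).astype(np.float32)


def truncated_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) with rejection of draws beyond two standard deviations."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2.0 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2.0 * std
    return x.astype(np.float32)


class Module:
    """Base class with automatic parameter/buffer/submodule registration."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, array):
        self._buffers[name] = array
        object.__setattr__(self, name, array)

    def parameters(self):
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def state(self, prefix: str = ""):
        """Ordered dict of every named array (parameters then buffers)."""
        out = {}
        for k, v in self._params.items():
            out[prefix + k] = v.data
        for k, v in self._buffers.items():
            out[prefix + k] = v
        for name, m in self._modules.items():
            out.update(m.state(prefix + name + "."))
        return out

    def param_count(self) -> int:
        """Brute-force enumeration: total number of scalars across all arrays."""
        return int(sum(a.size for a in self.state().values()))

    def load_state(self, arrays: dict, prefix: str = ""):
        for k, v in self._params.items():
            v.data[...] = arrays[prefix + k]
        for k in self._buffers:
            self._buffers[k][...] = arrays[prefix + k]
        for name, m in self._modules.items():
            m.load_state(arrays, prefix + name + ".")

    def __call__(self, x, training: bool = False):
        return self.forward(x, training)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self.mods = list(mods)

    def forward(self, x, training=False):
        for m in self.mods:
            x = m(x, training)
        return x


def _act(x, name):
    if name == "relu":
        return ag.relu(x)
    if name == "swish":
        return ag.swish(x)
    if name is None or name == "linear":
        return x
    raise ValueError(f"unknown activation {name!r}")


class Conv2D(Module):
    """Standard convolution, same padding, optional bias and activation."""

    def __init__(self, cin, cout, kernel, rng, stride=1, bias=True, activation=None):
        super().__init__()
        self.stride, self.activation = stride, activation
        self.w = Tensor(fan_out_normal(rng, (kernel, kernel, cin, cout),
                                       kernel * kernel * cout), requires_grad=True)
        self.b = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x, training=False):
        return _act(ag.conv2d(x, self.w, self.b, self.stride), self.activation)


class DepthwiseConv2D(Module):
    def __init__(self, cin, kernel, rng, stride=1, depth_multiplier=1):
        super().__init__()
        self.stride = stride
        self.w = Tensor(fan_out_normal(rng, (kernel, kernel, cin, depth_multiplier),
                                       kernel * kernel * depth_multiplier),
                        requires_grad=True)

    def forward(self, x, training=False):
        return ag.depthwise_conv2d(x, self.w, self.stride)


class BatchNorm2D(Module):
    def __init__(self, channels, momentum=0.9, eps=1e-3):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(channels, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, np.float32), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(channels, np.float32))
        self.register_buffer("running_var", np.ones(channels, np.float32))

    def forward(self, x, training=False):
        return ag.batch_norm(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, training, self.momentum, self.eps)


class ConvBN(Module):
    """Convolution without bias followed by batch normalization (+ activation)."""

    def __init__(self, cin, cout, kernel, rng, stride=1, activation=None):
        super().__init__()
        self.conv = Conv2D(cin, cout, kernel, rng, stride, bias=False)
        self.bn = BatchNorm2D(cout)
        self.activation = activation

    def forward(self, x, training=False):
        return _act(self.bn(self.conv(x, training), training), self.activation)


class SeparableConvBN(Module):
    """Depthwise then pointwise convolution, batch-normalized output.

    Parameter layout mirrors a framework separable convolution with the bias
    replaced by batch normalization: K*K*C*alpha depthwise weights,
    C*alpha*N pointwise weights, 4N normalization values.
    """

    def __init__(self, cin, cout, kernel, rng, stride=1, depth_multiplier=1,
                 activation=None):
        super().__init__()
        self.dw = DepthwiseConv2D(cin, kernel, rng, stride, depth_multiplier)
        self.pw = Conv2D(cin * depth_multiplier, cout, 1, rng, 1, bias=False)
        self.bn = BatchNorm2D(cout)
        self.activation = activation

    def forward(self, x, training=False):
        return _act(self.bn(self.pw(self.dw(x, training), training), training),
                    self.activation)


class Dense(Module):
    def __init__(self, cin, cout, rng, bias=True, activation=None, init_std=0.02):
        super().__init__()
        self.activation = activation
        self.w = Tensor(truncated_normal(rng, (cin, cout), init_std), requires_grad=True)
        self.b = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x, training=False):
        y = ag.matmul(x, self.w)
        if self.b is not None:
            y = ag.add(y, self.b)
        return _act(y, self.activation)


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-6):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, np.float32), requires_grad=True)

    def forward(self, x, training=False):
        return ag.layer_norm(x, self.gamma, self.beta, self.eps)


class MaxPool2D(Module):
    def __init__(self, k=3, stride=1):
        super().__init__()
        self.k, self.stride = k, stride

    def forward(self, x, training=False):
        return ag.max_pool2d(x, self.k, self.stride)


class AvgPool2D(Module):
    def __init__(self, k=3, stride=1):
        super().__init__()
        self.k, self.stride = k, stride

    def forward(self, x, training=False):
        return ag.avg_pool2d(x, self.k, self.stride)
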