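"""Layers with explicit forward/backward passes.

Convolutions are evaluated offset-by-offset: for each of the k*k kernel
offsets the strided input slice is contracted with the corresponding weight
plane through a single BLAS matmul.  This keeps peak memory at one input-sized
temporary (no full im2col buffer), which is what lets the 6078-channel presets
run on a laptop-class CPU.

Gradients accumulate into ``Parameter.grad`` (they are not overwritten), so
gradient accumulation over micro-batches falls out of the design; the
optimizer's ``zero_grad`` resets them.
"""

from __future__ import annotations

import numpy as np

from ..errors import ShapeError


class Parameter:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base class: parameters, state (incl. non-learnable buffers), fwd/bwd."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state(self) -> dict[str, np.ndarray]:
        return {p.name: p.value for p in self.parameters()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value = np.array(state[p.name], dtype=p.value.dtype)
            p.grad = np.zeros_like(p.value)

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Module):
    """3x3-by-default strided convolution, NCHW layout, optional zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 2,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float64,
    ):
        if kernel < 1 or stride < 1 or padding < 0:
            raise ShapeError("kernel and stride must be >= 1, padding >= 0")
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel * kernel
        self.weight = Parameter(
            "weight", _he_init(rng, (out_channels, in_channels, kernel, kernel), fan_in, dtype)
        )
        self.bias = Parameter("bias", np.zeros(out_channels, dtype=dtype)) if bias else None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    @staticmethod
    def out_side(n: int, kernel: int, stride: int, padding: int) -> int:
        if n + 2 * padding < kernel:
            raise ShapeError(
                f"input side {n} with padding {padding} is smaller than kernel {kernel}"
            )
        return (n + 2 * padding - kernel) // stride + 1

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ShapeError(
                f"expected (B, {self.in_channels}, H, W), got {x.shape}"
            )
        if self.padding:
            p = self.padding
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._x = x
        B, C, H, W = x.shape
        k, s = self.kernel, self.stride
        Ho = self.out_side(H, k, s, 0)
        Wo = self.out_side(W, k, s, 0)
        self._out_shape = (Ho, Wo)
        out = np.zeros((B, self.out_channels, Ho, Wo), dtype=x.dtype)
        Wv = self.weight.value
        for ki in range(k):
            for kj in range(k):
                xs = x[:, :, ki : ki + s * Ho : s, kj : kj + s * Wo : s]
                # (O,C) x (B,C,Ho,Wo) -> (B,O,Ho,Wo), one BLAS call per offset
                out += np.einsum("oc,bchw->bohw", Wv[:, :, ki, kj], xs, optimize=True)
        if self.bias is not None:
            out += self.bias.value[None, :, None, None]
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x = self._x
        k, s = self.kernel, self.stride
        Ho, Wo = self._out_shape
        gx = np.zeros_like(x)
        Wv = self.weight.value
        for ki in range(k):
            for kj in range(k):
                xs = x[:, :, ki : ki + s * Ho : s, kj : kj + s * Wo : s]
                self.weight.grad[:, :, ki, kj] += np.einsum(
                    "bohw,bchw->oc", grad_out, xs, optimize=True
                )
                gx[:, :, ki : ki + s * Ho : s, kj : kj + s * Wo : s] += np.einsum(
                    "oc,bohw->bchw", Wv[:, :, ki, kj], grad_out, optimize=True
                )
        if self.bias is not None:
            self.bias.grad += grad_out.sum(axis=(0, 2, 3))
        if self.padding:
            p = self.padding
            gx = gx[:, :, p:-p, p:-p]
        return gx


class ConvTranspose2d(Module):
    """Strided transposed convolution with output padding (mirror of Conv2d)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 2,
        padding: int = 0,
        output_padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float64,
    ):
        if output_padding >= stride:
            raise ShapeError("output_padding must be < stride")
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self.output_padding = output_padding
        fan_in = in_channels * kernel * kernel
        self.weight = Parameter(
            "weight", _he_init(rng, (in_channels, out_channels, kernel, kernel), fan_in, dtype)
        )
        self.bias = Parameter("bias", np.zeros(out_channels, dtype=dtype)) if bias else None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    @staticmethod
    def out_side(n: int, kernel: int, stride: int, padding: int, output_padding: int) -> int:
        return (n - 1) * stride - 2 * padding + kernel + output_padding

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ShapeError(f"expected (B, {self.in_channels}, H, W), got {x.shape}")
        self._x = x
        B, C, H, W = x.shape
        k, s, p, op = self.kernel, self.stride, self.padding, self.output_padding
        Hf = (H - 1) * s + k
        Wf = (W - 1) * s + k
        y = np.zeros((B, self.out_channels, Hf, Wf), dtype=x.dtype)
        Wv = self.weight.value
        for ki in range(k):
            for kj in range(k):
                y[:, :, ki : ki + s * H : s, kj : kj + s * W : s] += np.einsum(
                    "io,bihw->bohw", Wv[:, :, ki, kj], x, optimize=True
                )
        if p:
            y = y[:, :, p : Hf - p, p : Wf - p]
        if op:
            y = np.pad(y, ((0, 0), (0, 0), (0, op), (0, op)))
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x = self._x
        B, C, H, W = x.shape
        k, s, p, op = self.kernel, self.stride, self.padding, self.output_padding
        if self.bias is not None:
            self.bias.grad += grad_out.sum(axis=(0, 2, 3))
        g = grad_out
        if op:
            g = g[:, :, : g.shape[2] - op, : g.shape[3] - op]
        if p:
            g = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p)))
        gx = np.zeros_like(x)
        Wv = self.weight.value
        for ki in range(k):
            for kj in range(k):
                gs = g[:, :, ki : ki + s * H : s, kj : kj + s * W : s]
                gx += np.einsum("io,bohw->bihw", Wv[:, :, ki, kj], gs, optimize=True)
                self.weight.grad[:, :, ki, kj] += np.einsum(
                    "bihw,bohw->io", x, gs, optimize=True
                )
        return gx


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics for eval mode."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float64):
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter("gamma", np.ones(num_features, dtype=dtype))
        self.beta = Parameter("beta", np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def state(self) -> dict[str, np.ndarray]:
        s = super().state()
        s["running_mean"] = self.running_mean
        s["running_var"] = self.running_var
        return s

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        super().load_state(state)
        self.running_mean = np.array(state["running_mean"], dtype=self.running_mean.dtype)
        self.running_var = np.array(state["running_var"], dtype=self.running_var.dtype)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._training = training
        if training:
            n = x.shape[0] * x.shape[2] * x.shape[3]
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))  # biased, used for normalization
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            unbiased = var * n / max(n - 1, 1)
            self.running_var = (1 - m) * self.running_var + m * unbiased
            self._n = n
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._xhat, self._std = xhat, std
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, std = self._xhat, self._std
        self.gamma.grad += (grad_out * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad_out.sum(axis=(0, 2, 3))
        gscaled = grad_out * self.gamma.value[None, :, None, None]
        if not self._training:
            return gscaled / std[None, :, None, None]
        n = self._n
        mean_g = gscaled.mean(axis=(0, 2, 3), keepdims=True)
        mean_gx = (gscaled * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (gscaled - mean_g - xhat * mean_gx) / std[None, :, None, None]


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.01):
        self.negative_slope = negative_slope

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._neg = x < 0
        return np.where(self._neg, self.negative_slope * x, x)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return np.where(self._neg, self.negative_slope * grad_out, grad_out)


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  p >= 1 zeroes everything."""

    def __init__(self, p: float = 0.5, seed: int = 0):
        if not 0.0 <= p <= 1.0:
            raise ShapeError("dropout probability must be in [0, 1]")
        self.p = p
        self.rng = np.random.default_rng(seed)

    def reseed(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if self.p >= 1.0:
            self._mask = np.zeros_like(x)
            return self._mask.copy()
        keep = (self.rng.random(x.shape) >= self.p).astype(x.dtype)
        self._mask = keep / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad_out
        return grad_out * self._mask


class Flatten(Module):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(self._shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter("weight", _he_init(rng, (out_features, in_features), in_features, dtype))
        self.bias = Parameter("bias", np.zeros(out_features, dtype=dtype)) if bias else None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_features:
            raise ShapeError(f"expected {self.in_features} features, got {x.shape[1]}")
        self._x = x
        y = x @ self.weight.value.T
        if self.bias is not None:
            y += self.bias.value
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.weight.grad += grad_out.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad_out.sum(axis=0)
        return grad_out @ self.weight.value


class Sequential(Module):
    """Ordered container; backward runs layers in reverse."""

    def __init__(self, layers: list[Module]):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def forward_with_shapes(self, x: np.ndarray, training: bool = False):
        """Forward pass that also records each layer's output shape."""
        shapes = []
        for layer in self.layers:
            x = layer.forward(x, training=training)
            shapes.append(x.shape)
        return x, shapes

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def state(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.state().items():
                out[f"{i}.{k}"] = v
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            prefix = f"{i}."
            sub = {k[len(prefix):]: v for k, v in state.items() if k.startswith(prefix)}
            if sub:
                layer.load_state(sub)

    def dropout_layers(self) -> list[Dropout]:
        return [l for l in self.layers if isinstance(l, Dropout)]
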