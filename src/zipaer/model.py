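"""Compressive convolutional autoencoders built from a declarative spec.

Unlike image autoencoders that trade spatial extent for channel depth, these
models shrink *both* axes: a schedule like 6078 -> 512 -> 512 halves the
spatial side at each 3x3 stride-2 convolution while collapsing thousands of
gene channels into a few hundred latent channels.  The decoder mirrors the
encoder with transposed convolutions whose output paddings are chosen
automatically so the reconstruction lands exactly on the input shape.

Closed-form oracles (`conv_out_side`, `latent_shape`, `count_parameters`)
predict every instantiated shape and the exact learnable-parameter count;
the test suite holds the instantiated networks to them.

Presets:

``zipaer2``  6078-channel, 300-px input, schedule (512, 512);
             latent 512 x 74 x 74, ~61M parameters.
``zipaer3``  schedule (512, 512, 256); latent 256 x 36 x 36, ~63M parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .errors import ShapeError, SpecError

KERNEL = 3
STRIDE = 2


@dataclass(frozen=True)
class ConvLayerSpec:
    in_channels: int
    out_channels: int
    kernel: int = KERNEL
    stride: int = STRIDE
    padding: int = 0
    with_bias: bool = True
    followed_by_batchnorm: bool = False
    activation: str = "leaky_relu"


@dataclass(frozen=True)
class TransposedConvLayerSpec(ConvLayerSpec):
    output_padding: int = 0

    def __post_init__(self):
        if self.output_padding >= self.stride:
            raise SpecError("output_padding must be < stride")


@dataclass(frozen=True)
class LatentShape:
    channels: int
    side: int

    @property
    def n_elements(self) -> int:
        return self.channels * self.side * self.side


@dataclass(frozen=True)
class ModelSpec:
    """Encoder channel schedule; the decoder is mirrored automatically."""

    input_channels: int
    input_side: int
    channel_schedule: tuple[int, ...]
    name: str = "custom"

    def __post_init__(self):
        object.__setattr__(self, "channel_schedule", tuple(self.channel_schedule))
        if not self.channel_schedule:
            raise SpecError("channel schedule must be non-empty")
        if self.input_channels < 1 or self.input_side < 1:
            raise SpecError("input channels and side must be >= 1")
        if any(c < 1 for c in self.channel_schedule):
            raise SpecError("channel counts must be >= 1")

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(
            {
                "name": self.name,
                "input_channels": self.input_channels,
                "input_side": self.input_side,
                "schedule": list(self.channel_schedule),
            },
            sort_keys=False,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ModelSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = yaml.safe_load(text)
        return cls(
            input_channels=int(d["input_channels"]),
            input_side=int(d["input_side"]),
            channel_schedule=tuple(int(c) for c in d["schedule"]),
            name=str(d.get("name", "custom")),
        )


PRESETS = {
    "zipaer2": ModelSpec(6078, 300, (512, 512), name="zipaer2"),
    "zipaer3": ModelSpec(6078, 300, (512, 512, 256), name="zipaer3"),
}


def get_preset(name: str) -> ModelSpec:
    try:
        return PRESETS[name.lower()]
    except KeyError:
        raise SpecError(f"unknown preset {name!r}; known: {sorted(PRESETS)}") from None


def conv_out_side(n: int, kernel: int = KERNEL, stride: int = STRIDE, padding: int = 0) -> int:
    """floor((n + 2p - k)/s) + 1, the strided-convolution output side."""
    if n + 2 * padding < kernel:
        raise ShapeError(f"side {n} too small for kernel {kernel} with padding {padding}")
    return (n + 2 * padding - kernel) // stride + 1


def tconv_out_side(n: int, kernel: int = KERNEL, stride: int = STRIDE,
                   padding: int = 0, output_padding: int = 0) -> int:
    """(n - 1)s - 2p + k + op, the transposed-convolution output side."""
    if n < 1:
        raise ShapeError("input side must be >= 1")
    return (n - 1) * stride - 2 * padding + kernel + output_padding


def choose_output_padding(target_side: int, n: int, kernel: int = KERNEL,
                          stride: int = STRIDE, padding: int = 0) -> int:
    """The unique output padding in {0, 1} that mirrors a stride-2 conv."""
    for op in (0, 1):
        if tconv_out_side(n, kernel, stride, padding, op) == target_side:
            return op
    raise SpecError(
        f"no output padding in {{0, 1}} maps side {n} back to {target_side}"
    )


def encoder_sides(spec: ModelSpec) -> list[int]:
    """Spatial side after the input and after each encoder convolution."""
    sides = [spec.input_side]
    for _ in spec.channel_schedule:
        try:
            sides.append(conv_out_side(sides[-1]))
        except ShapeError as e:
            raise SpecError(f"encoder side collapses below the kernel: {e}") from e
    if sides[-1] < 1:
        raise SpecError("latent side would reach 0")
    return sides


def latent_shape(spec: ModelSpec) -> LatentShape:
    return LatentShape(channels=spec.channel_schedule[-1], side=encoder_sides(spec)[-1])


def encoder_layer_specs(spec: ModelSpec) -> list[ConvLayerSpec]:
    """Convs per schedule; batch norm after the final encoder conv only."""
    chans = [spec.input_channels, *spec.channel_schedule]
    n = len(spec.channel_schedule)
    return [
        ConvLayerSpec(
            in_channels=chans[i],
            out_channels=chans[i + 1],
            followed_by_batchnorm=(i == n - 1),
        )
        for i in range(n)
    ]


def decoder_layer_specs(spec: ModelSpec) -> list[TransposedConvLayerSpec]:
    """Mirrored transposed convs; batch norm after every layer except the last."""
    sides = encoder_sides(spec)
    chans = [*reversed(spec.channel_schedule), spec.input_channels]
    n = len(spec.channel_schedule)
    out = []
    for j in range(n):
        cur = sides[n - j]
        target = sides[n - j - 1]
        out.append(
            TransposedConvLayerSpec(
                in_channels=chans[j],
                out_channels=chans[j + 1],
                output_padding=choose_output_padding(target, cur),
                followed_by_batchnorm=(j < n - 1),
            )
        )
    return out


def count_parameters(spec: ModelSpec) -> int:
    """Closed-form learnable-parameter count (weights + biases + 2 per BN
    channel), exactly matching the instantiated network."""
    total = 0
    for ls in [*encoder_layer_specs(spec), *decoder_layer_specs(spec)]:
        total += ls.in_channels * ls.out_channels * ls.kernel ** 2
        if ls.with_bias:
            total += ls.out_channels
        if ls.followed_by_batchnorm:
            total += 2 * ls.out_channels
    return total


class Autoencoder:
    """Instantiated encoder/decoder pair for one :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, seed: int = 0, dtype=np.float64,
                 leaky_slope: float = 0.01, batch_norm: bool = True):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        enc_layers: list[nn.Module] = []
        for ls in encoder_layer_specs(spec):
            enc_layers.append(
                nn.Conv2d(ls.in_channels, ls.out_channels, ls.kernel, ls.stride,
                          ls.padding, bias=ls.with_bias, rng=rng, dtype=dtype)
            )
            if batch_norm and ls.followed_by_batchnorm:
                enc_layers.append(nn.BatchNorm2d(ls.out_channels, dtype=dtype))
            enc_layers.append(nn.LeakyReLU(leaky_slope))
        dec_layers: list[nn.Module] = []
        for ls in decoder_layer_specs(spec):
            dec_layers.append(
                nn.ConvTranspose2d(ls.in_channels, ls.out_channels, ls.kernel,
                                   ls.stride, ls.padding, ls.output_padding,
                                   bias=ls.with_bias, rng=rng, dtype=dtype)
            )
            if batch_norm and ls.followed_by_batchnorm:
                dec_layers.append(nn.BatchNorm2d(ls.out_channels, dtype=dtype))
            dec_layers.append(nn.LeakyReLU(leaky_slope))
        self.encoder = nn.Sequential(enc_layers)
        self.decoder = nn.Sequential(dec_layers)

    def _check_input(self, x: np.ndarray) -> None:
        expected = (self.spec.input_channels, self.spec.input_side, self.spec.input_side)
        if x.ndim != 4 or x.shape[1:] != expected:
            raise ShapeError(f"expected (B, {expected[0]}, {expected[1]}, {expected[2]}), "
                             f"got {tuple(x.shape)}")

    def encode(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._check_input(np.asarray(x))
        return self.encoder.forward(np.asarray(x, dtype=self.dtype), training=training)

    def decode(self, z: np.ndarray, training: bool = False) -> np.ndarray:
        return self.decoder.forward(np.asarray(z, dtype=self.dtype), training=training)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.decode(self.encode(x, training=training), training=training)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return self.encoder.backward(self.decoder.backward(grad_out))

    def parameters(self) -> list[nn.Parameter]:
        return self.encoder.parameters() + self.decoder.parameters()

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    @property
    def latent_shape(self) -> LatentShape:
        return latent_shape(self.spec)

    def state(self) -> dict[str, np.ndarray]:
        out = {f"encoder.{k}": v for k, v in self.encoder.state().items()}
        out.update({f"decoder.{k}": v for k, v in self.decoder.state().items()})
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.encoder.load_state(
            {k[len("encoder."):]: v for k, v in state.items() if k.startswith("encoder.")}
        )
        self.decoder.load_state(
            {k[len("decoder."):]: v for k, v in state.items() if k.startswith("decoder.")}
        )


def build_autoencoder(spec: ModelSpec, seed: int = 0, dtype=np.float64,
                      leaky_slope: float = 0.01, batch_norm: bool = True) -> Autoencoder:
    """Instantiate the autoencoder for ``spec`` with a seeded initialization.

    ``batch_norm=False`` builds a batch-norm-free variant (useful when exact
    gradient-accumulation equivalence matters); the parameter-count oracle
    applies to the default batch-norm configuration.
    """
    return Autoencoder(spec, seed=seed, dtype=dtype, leaky_slope=leaky_slope,
                       batch_norm=batch_norm)
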