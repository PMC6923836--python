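"""The SigUNet architecture family.

A 1D U-Net over 96-residue windows: an encoder of ``depth`` levels (two
length-preserving convolutions + ReLU, then a size-2 pooling per level), a
bottleneck, and a decoder that mirrors the encoder with kernel-2 stride-2
transposed convolutions and plain concatenation of the same-resolution
encoder output (no cropping — all convolutions preserve length).  A final
1x1 convolution maps to 3 channels with a per-position softmax, so the
output is a 96x3 probability matrix: for each residue, the probability of
being signal peptide (S), transmembrane (T) or neither (N).

Channel schedules:

* ``linear`` — the channel count starts at ``m`` and grows by ``n`` per
  pooling level (the SigUNet schedule; ``m`` and ``n`` are hyper-parameters).
* ``doubling`` — 64, 128, 256, ... (the classical U-Net schedule, used by
  the ``unet1d`` ablation variant together with max pooling).

Average pooling is the default: each residue is assumed to carry signal,
and max pooling can discard a residue's contribution when a neighbour
dominates the pooled pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path

import numpy as np

from .nn import (
    Adam,
    AvgPool2,
    Conv1d,
    ConvTranspose1d,
    MaxPool2,
    ReLU,
    softmax,
)

INPUT_LENGTH = 96
N_INPUT_CHANNELS = 20
N_CLASSES = 3


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters for the SigUNet family."""

    m: int = 24
    n: int = 24
    depth: int = 3
    kernel_size: int = 3
    convs_per_level: int = 2
    pooling: str = "average"  # average | max
    schedule: str = "linear"  # linear | doubling
    variant: str = "sigunet"  # sigunet | sigunet_light | unet1d

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 0:
            raise ValueError("m must be positive and n non-negative")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if INPUT_LENGTH % (2**self.depth) != 0:
            raise ValueError(f"{INPUT_LENGTH} must be divisible by 2^depth")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and positive")
        if self.convs_per_level < 1:
            raise ValueError("convs_per_level must be positive")
        if self.pooling not in ("average", "max"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.schedule not in ("linear", "doubling"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.variant not in ("sigunet", "sigunet_light", "unet1d"):
            raise ValueError(f"unknown variant {self.variant!r}")


#: repository defaults; weight counts land inside the published size ranges
SIGUNET_DEFAULT = NetworkConfig(m=24, n=24, depth=3, variant="sigunet")
SIGUNET_LIGHT_DEFAULT = NetworkConfig(m=20, n=20, depth=3, variant="sigunet_light")
UNET1D_DEFAULT = NetworkConfig(
    m=64, n=0, depth=3, schedule="doubling", pooling="max", variant="unet1d"
)


def default_config(variant: str) -> NetworkConfig:
    try:
        return {
            "sigunet": SIGUNET_DEFAULT,
            "sigunet_light": SIGUNET_LIGHT_DEFAULT,
            "unet1d": UNET1D_DEFAULT,
        }[variant]
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}") from None


def channel_schedule(config: NetworkConfig, level: int) -> int:
    """Channel count at a resolution level (0 = full resolution)."""
    if level < 0 or level > config.depth:
        raise ValueError(f"level {level} outside [0, depth={config.depth}]")
    if config.schedule == "linear":
        return config.m + level * config.n
    return 64 * 2**level


def _layer_plan(config: NetworkConfig) -> list[tuple[str, int, int]]:
    """Sequence of (kind, c_in, c_out) for every weighted layer, in build order."""
    k = config.kernel_size
    plan: list[tuple[str, int, int]] = []
    c_prev = N_INPUT_CHANNELS
    for level in range(config.depth + 1):  # last level is the bottleneck
        c = channel_schedule(config, level)
        for i in range(config.convs_per_level):
            plan.append(("conv", c_prev if i == 0 else c, c))
        c_prev = c
    for level in reversed(range(config.depth)):
        c = channel_schedule(config, level)
        plan.append(("upconv", c_prev, c))
        for i in range(config.convs_per_level):
            plan.append(("conv", 2 * c if i == 0 else c, c))
        c_prev = c
    plan.append(("final", c_prev, N_CLASSES))
    return plan


def count_parameters(config: NetworkConfig) -> int:
    """Closed-form trainable-weight count of ``build_network(config)``.

    Convolutions contribute ``kernel*c_in*c_out + c_out``, transposed
    convolutions ``2*c_in*c_out + c_out`` and the final 1x1 layer
    ``c_in*3 + 3``.  Must agree exactly with enumeration of the built
    model's parameter arrays.
    """
    k = config.kernel_size
    total = 0
    for kind, c_in, c_out in _layer_plan(config):
        width = {"conv": k, "upconv": 2, "final": 1}[kind]
        total += width * c_in * c_out + c_out
    return total


class Model:
    """A built (trainable) SigUNet: maps a 96x20 matrix to 96x3 probabilities."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        pool_cls = AvgPool2 if config.pooling == "average" else MaxPool2

        self.enc_convs: list[list[Conv1d]] = []
        self.enc_relus: list[list[ReLU]] = []
        self.pools: list = []
        c_prev = N_INPUT_CHANNELS
        for level in range(config.depth):
            c = channel_schedule(config, level)
            convs = [
                Conv1d(c_prev if i == 0 else c, c, config.kernel_size, rng)
                for i in range(config.convs_per_level)
            ]
            self.enc_convs.append(convs)
            self.enc_relus.append([ReLU() for _ in convs])
            self.pools.append(pool_cls())
            c_prev = c

        c = channel_schedule(config, config.depth)
        self.mid_convs = [
            Conv1d(c_prev if i == 0 else c, c, config.kernel_size, rng)
            for i in range(config.convs_per_level)
        ]
        self.mid_relus = [ReLU() for _ in self.mid_convs]
        c_prev = c

        self.upconvs: list[ConvTranspose1d] = []
        self.up_relus: list[ReLU] = []
        self.dec_convs: list[list[Conv1d]] = []
        self.dec_relus: list[list[ReLU]] = []
        for level in reversed(range(config.depth)):
            c = channel_schedule(config, level)
            self.upconvs.append(ConvTranspose1d(c_prev, c, rng))
            self.up_relus.append(ReLU())
            convs = [
                Conv1d(2 * c if i == 0 else c, c, config.kernel_size, rng)
                for i in range(config.convs_per_level)
            ]
            self.dec_convs.append(convs)
            self.dec_relus.append([ReLU() for _ in convs])
            c_prev = c

        self.final = Conv1d(c_prev, N_CLASSES, 1, rng)

        self._layers = []
        for convs in self.enc_convs:
            self._layers.extend(convs)
        self._layers.extend(self.mid_convs)
        for up, convs in zip(self.upconvs, self.dec_convs):
            self._layers.append(up)
            self._layers.extend(convs)
        self._layers.append(self.final)

    # -- forward / backward -------------------------------------------------

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """Pre-softmax activations; ``x`` has shape (batch, 96, 20)."""
        h = x
        self._skips = []
        for level in range(self.config.depth):
            for conv, relu in zip(self.enc_convs[level], self.enc_relus[level]):
                h = relu.forward(conv.forward(h))
            self._skips.append(h)
            h = self.pools[level].forward(h)
        for conv, relu in zip(self.mid_convs, self.mid_relus):
            h = relu.forward(conv.forward(h))
        self._skip_channels = []
        for i, level in enumerate(reversed(range(self.config.depth))):
            h = self.up_relus[i].forward(self.upconvs[i].forward(h))
            skip = self._skips[level]
            self._skip_channels.append(skip.shape[2])
            h = np.concatenate([skip, h], axis=2)
            for conv, relu in zip(self.dec_convs[i], self.dec_relus[i]):
                h = relu.forward(conv.forward(h))
        return self.final.forward(h)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Per-position class probabilities, shape (batch, 96, 3)."""
        return softmax(self.forward_logits(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Probabilities for a single 96x20 matrix or a batch."""
        single = x.ndim == 2
        if single:
            x = x[None]
        p = self.forward(x)
        return p[0] if single else p

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the final logits into all weights."""
        d = self.final.backward(dlogits)
        dskips: dict[int, np.ndarray] = {}
        # decoder stages in reverse build order: i = depth-1 (level 0) first
        for i in reversed(range(self.config.depth)):
            level = self.config.depth - 1 - i
            for conv, relu in zip(
                reversed(self.dec_convs[i]), reversed(self.dec_relus[i])
            ):
                d = conv.backward(relu.backward(d))
            c_skip = self._skip_channels[i]
            dskips[level] = d[:, :, :c_skip]
            d = self.upconvs[i].backward(self.up_relus[i].backward(d[:, :, c_skip:]))
        for conv, relu in zip(reversed(self.mid_convs), reversed(self.mid_relus)):
            d = conv.backward(relu.backward(d))
        for level in reversed(range(self.config.depth)):
            d = self.pools[level].backward(d)
            d = d + dskips[level]
            for conv, relu in zip(
                reversed(self.enc_convs[level]), reversed(self.enc_relus[level])
            ):
                d = conv.backward(relu.backward(d))

    # -- parameter access ---------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers:
            out.extend(layer.params())
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers:
            out.extend(layer.grads())
        return out

    def num_parameters(self) -> int:
        """Trainable-weight total by exhaustive enumeration of the arrays."""
        return sum(p.size for p in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(weights):
            raise ValueError("weight list does not match architecture")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch {p.shape} vs {w.shape}")
            p[...] = w

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Save weights as .npz with a JSON sidecar recording the config."""
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        np.savez(path, **arrays)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(asdict(self.config), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        path = Path(path)
        sidecar = path.with_suffix(".json")
        config = NetworkConfig(**json.loads(sidecar.read_text()))
        model = cls(config)
        with np.load(path if path.suffix else path.with_suffix(".npz")) as data:
            model.set_weights([data[f"p{i}"] for i in range(len(data.files))])
        return model


def build_network(config: NetworkConfig, seed: int = 0) -> Model:
    """Construct a (randomly initialised, He-uniform) model for a config."""
    return Model(config, seed=seed)
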