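"""The 1D U-Net that maps window features to per-point moving probabilities.

Architecture (depth 2, the default): each encoder level applies a
length-preserving convolution + ReLU, stores the activation as a skip
connection, then halves the length with max pooling (stride 2).  A
bottleneck convolution sits at the coarsest resolution (length W / 2²).
Each decoder level doubles the length with a learned transposed convolution
("up-conv"), concatenates the matching skip activation along channels, and
applies a convolution + ReLU.  A final 1×1 convolution with a sigmoid yields
one P(moving) value per window position; P(not_moving) is its complement,
so a single sigmoid channel carries the two-class output.

Channel widths start at ``base_channels`` and double per level
(16 → 32, bottleneck 64 by default); the widths and the kernel size are
package choices kept small for CPU training on 8-point windows.  No batch
normalisation or dropout is used.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .exceptions import ConfigurationError, TrajsegError
from .nn import Conv1d, ConvTranspose1d, MaxPool1d, ReLU, Sigmoid

__all__ = ["UNetConfig", "UNet1D", "ModelArtifact", "save_model", "load_model"]

_CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters of the segmentation network.

    in_channels: feature channels per window position (2: r,θ or x,y).
    depth: number of down-/up-sampling levels (window length must be
    divisible by ``2**depth``).
    base_channels: width of the first encoder level; doubles per level.
    kernel_size: odd convolution width with 'same' padding.
    seed: weight-initialisation seed (makes builds reproducible).
    """

    in_channels: int = 2
    depth: int = 2
    base_channels: int = 16
    kernel_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.depth < 1 or self.base_channels < 1:
            raise ConfigurationError(f"invalid UNetConfig: {self}")
        if self.kernel_size % 2 != 1:
            raise ConfigurationError(
                f"kernel_size must be odd, got {self.kernel_size}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "UNetConfig":
        return cls(**d)


class UNet1D:
    """Encoder–decoder over window positions; see module docstring.

    Weight initialisation is drawn from a generator seeded with
    ``config.seed``, so two builds with the same config produce identical
    forward outputs.
    """

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        k = config.kernel_size

        self.enc_convs: list[Conv1d] = []
        self.enc_relus: list[ReLU] = []
        self.pools: list[MaxPool1d] = []
        c_in = config.in_channels
        widths = []
        for _ in range(config.depth):
            self.enc_convs.append(Conv1d(c_in, c, k, rng))
            self.enc_relus.append(ReLU())
            self.pools.append(MaxPool1d())
            widths.append(c)
            c_in, c = c, c * 2

        self.bottleneck = Conv1d(c_in, c, k, rng)
        self.bottleneck_relu = ReLU()

        self.upconvs: list[ConvTranspose1d] = []
        self.dec_convs: list[Conv1d] = []
        self.dec_relus: list[ReLU] = []
        for skip_c in reversed(widths):
            self.upconvs.append(ConvTranspose1d(c, skip_c, rng))
            self.dec_convs.append(Conv1d(2 * skip_c, skip_c, k, rng))
            self.dec_relus.append(ReLU())
            c = skip_c

        self.head = Conv1d(c, 1, 1, rng)
        self.head_sigmoid = Sigmoid()

    # -- forward / backward -------------------------------------------------

    def forward(self, batch: np.ndarray) -> np.ndarray:
        """Map a ``(n, in_channels, W)`` batch to ``(n, W)`` probabilities."""
        x = np.asarray(batch, dtype=np.float64)
        if x.ndim != 3 or x.shape[1] != self.config.in_channels:
            raise TrajsegError(
                f"expected batch of shape (n, {self.config.in_channels}, W), "
                f"got {x.shape}"
            )
        W = x.shape[2]
        if W % (2 ** self.config.depth) != 0:
            raise ConfigurationError(
                f"window length {W} not divisible by 2**depth = "
                f"{2 ** self.config.depth}"
            )
        if not np.all(np.isfinite(x)):
            raise TrajsegError("non-finite values in input batch")

        skips = []
        for conv, relu, pool in zip(self.enc_convs, self.enc_relus, self.pools):
            a = relu.forward(conv.forward(x))
            skips.append(a)
            x = pool.forward(a)
        x = self.bottleneck_relu.forward(self.bottleneck.forward(x))
        for up, conv, relu, skip in zip(
            self.upconvs, self.dec_convs, self.dec_relus, reversed(skips)
        ):
            u = up.forward(x)
            x = relu.forward(conv.forward(np.concatenate([u, skip], axis=1)))
        self._n_skips = len(skips)
        p = self.head_sigmoid.forward(self.head.forward(x))
        return p[:, 0, :]

    def backward(self, dprob: np.ndarray) -> None:
        """Back-propagate d(loss)/d(probabilities); accumulates gradients."""
        dy = self.head_sigmoid.backward(dprob[:, None, :])
        dx = self.head.backward(dy)
        skip_grads = []
        for up, conv, relu in zip(
            reversed(self.upconvs), reversed(self.dec_convs), reversed(self.dec_relus)
        ):
            dcat = conv.backward(relu.backward(dx))
            half = dcat.shape[1] // 2
            skip_grads.append(dcat[:, half:, :])
            dx = up.backward(dcat[:, :half, :])
        dx = self.bottleneck.backward(self.bottleneck_relu.backward(dx))
        # skip_grads accumulates shallowest-first; encoder backward runs
        # deepest-first, so pair with the reversed list
        for conv, relu, pool, dskip in zip(
            reversed(self.enc_convs),
            reversed(self.enc_relus),
            reversed(self.pools),
            reversed(skip_grads),
        ):
            da = pool.backward(dx) + dskip
            dx = conv.backward(relu.backward(da))

    # -- parameter plumbing -------------------------------------------------

    def _layers(self):
        return (
            self.enc_convs
            + [self.bottleneck]
            + self.upconvs
            + self.dec_convs
            + [self.head]
        )

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for p in layer.parameters()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self._layers() for g in layer.gradients()]

    def zero_grad(self) -> None:
        for g in self.gradients():
            g[...] = 0.0

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))


@dataclass
class ModelArtifact:
    """A trained model plus the metadata inference needs to reproduce its
    preprocessing: coordinate system, window geometry, loss history, seed."""

    model: UNet1D
    training_meta: dict

    @property
    def config(self) -> UNetConfig:
        return self.model.config

    def forward(self, batch: np.ndarray) -> np.ndarray:
        return self.model.forward(batch)


def save_model(artifact: ModelArtifact, path) -> None:
    """Serialise config + weights + training metadata to a single ``.npz``.

    Weights are stored as float64, so a load reproduces forward outputs
    bit-identically.
    """
    meta = {
        "version": _CHECKPOINT_VERSION,
        "config": artifact.model.config.to_dict(),
        "training_meta": artifact.training_meta,
    }
    arrays = {
        f"param_{i}": p for i, p in enumerate(artifact.model.parameters())
    }
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path) -> ModelArtifact:
    """Load a checkpoint written by :func:`save_model`."""
    try:
        data = np.load(path)
    except FileNotFoundError:
        raise
    meta = json.loads(bytes(data["meta"]).decode())
    if meta.get("version") != _CHECKPOINT_VERSION:
        raise TrajsegError(
            f"checkpoint version {meta.get('version')} not supported "
            f"(expected {_CHECKPOINT_VERSION})"
        )
    model = UNet1D(UNetConfig.from_dict(meta["config"]))
    params = model.parameters()
    for i, p in enumerate(params):
        stored = data[f"param_{i}"]
        if stored.shape != p.shape:
            raise TrajsegError(
                f"checkpoint parameter {i} has shape {stored.shape}, "
                f"model expects {p.shape}"
            )
        p[...] = stored
    return ModelArtifact(model=model, training_meta=meta["training_meta"])
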