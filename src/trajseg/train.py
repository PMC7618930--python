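"""Training: window dataset assembly, binary cross-entropy, Adam loop.

The model is trained per window: every enumerated window of every labelled
trajectory becomes one sample, with padded tail positions labelled
``not_moving`` (the repeated-point padding is a stalled segment by
construction).  The loss is the binary cross-entropy averaged over counted
points — all W positions by default, or only unpadded positions when
``include_padded_points_in_loss`` is off (an ablation switch).

Optimisation uses Adam with learning rate 1e-4.  Epoch count, batch size
and shuffling are exposed in :class:`TrainConfig`; defaults are sized for
CPU-minutes training.  Everything downstream of the seed (weight init and
batch shuffling) is deterministic.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import ConfigurationError, TrainingError, ValidationError
from .io import Trajectory
from .nn import Adam
from .unet import ModelArtifact, UNet1D, UNetConfig
from .windows import WindowSpec, build_features

__all__ = ["TrainConfig", "build_training_set", "bce_loss", "train"]

_CLAMP = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings.

    learning_rate: Adam step size (default 1e-4).
    epochs: full passes over the window set (default 200).
    batch_size: windows per optimisation step (default 32).
    coord_system: feature representation, 'polar' (default) or 'cartesian'.
    seed: controls weight initialisation and shuffling.
    include_padded_points_in_loss: count padded positions (as not_moving)
    in the loss; on by default, off for ablation.
    """

    learning_rate: float = 1e-4
    epochs: int = 200
    batch_size: int = 32
    coord_system: str = "polar"
    seed: int = 0
    include_padded_points_in_loss: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigurationError(
                f"learning_rate must be > 0, got {self.learning_rate}"
            )
        if self.epochs < 1:
            raise ConfigurationError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ConfigurationError(
                f"batch_size must be >= 1, got {self.batch_size}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


def build_training_set(
    trajs: Sequence[Trajectory],
    spec: WindowSpec,
    coord_system: str = "polar",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Turn labelled trajectories into (features, labels, valid_masks).

    Returns arrays of shape (n, 2, W), (n, W) and (n, W) where n is the
    total window count across all trajectories (one sample per enumerated
    window of each padded track).
    """
    feats, labels, masks = [], [], []
    for traj in trajs:
        if traj.labels is None:
            raise ValidationError(
                f"track {traj.track_id!r} has no labels; training requires "
                "fully labelled trajectories"
            )
        for w in build_features(traj, spec, coord_system):
            feats.append(w.features)
            labels.append(w.labels)
            masks.append(w.valid_mask)
    if not feats:
        raise ValidationError("no trajectories provided")
    return (
        np.stack(feats).astype(np.float64),
        np.stack(labels).astype(np.float64),
        np.stack(masks),
    )


def bce_loss(
    pred: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Masked binary cross-entropy, mean over counted points.

    Returns ``(loss, dloss/dpred)``.  Predictions are clamped away from 0
    and 1 so the value is always finite.  ``mask`` selects counted points;
    ``None`` counts everything.
    """
    p = np.clip(pred, _CLAMP, 1.0 - _CLAMP)
    y = labels
    if mask is None:
        mask = np.ones_like(p, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        return 0.0, np.zeros_like(p)
    ll = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    loss = float((ll * mask).sum() / n)
    grad = np.where(mask, (p - y) / (p * (1.0 - p)) / n, 0.0)
    return loss, grad


def train(
    features: np.ndarray,
    labels: np.ndarray,
    valid_masks: np.ndarray,
    config: TrainConfig,
    unet_config: UNetConfig | None = None,
    window_spec: WindowSpec | None = None,
    callback: Callable[[int, float], None] | None = None,
) -> tuple[ModelArtifact, list[float]]:
    """Train a fresh U-Net on a window set.

    Returns the trained :class:`ModelArtifact` (embedding the coordinate
    system and window geometry used, so inference can reproduce them) and
    the per-epoch mean loss history.  Raises :class:`TrainingError` if the
    loss goes non-finite.
    """
    n, c, W = features.shape
    if labels.shape != (n, W) or valid_masks.shape != (n, W):
        raise ConfigurationError(
            f"inconsistent shapes: features {features.shape}, "
            f"labels {labels.shape}, masks {valid_masks.shape}"
        )
    if unet_config is None:
        unet_config = UNetConfig(in_channels=c, seed=config.seed)
    window_spec = window_spec or WindowSpec(W=W)

    model = UNet1D(unet_config)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    loss_mask = None if config.include_padded_points_in_loss else valid_masks

    history: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            pred = model.forward(features[idx])
            loss, grad = bce_loss(
                pred, labels[idx], None if loss_mask is None else loss_mask[idx]
            )
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}: check the learning "
                    "rate and input data for pathologies"
                )
            model.zero_grad()
            model.backward(grad)
            opt.step(model.gradients())
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / n_batches)
        if callback is not None:
            callback(epoch, history[-1])

    artifact = ModelArtifact(
        model=model,
        training_meta={
            "coord_system": config.coord_system,
            "window_spec": window_spec.to_dict(),
            "train_config": config.to_dict(),
            "loss_history": history,
            "n_samples": int(n),
            "seed": config.seed,
        },
    )
    return artifact, history
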