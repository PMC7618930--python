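"""High-level Model/Results interface.

:class:`TrajectorySegmenter` bundles the windowing, feature and network
configuration with a labelled training set; its :meth:`fit` runs the Adam
loop and returns a :class:`SegmenterResults` carrying the trained weights,
the loss history and evaluation/plotting helpers — the same shape of API as
statsmodels' ``Model.fit() -> Results``.

Typical use::

    from trajseg import TrajectorySegmenter, simulate

    cfg = simulate.separable_preset(n_tracks=250)
    train_trajs, test_trajs = simulate.simulate_dataset(cfg, n_test=50)

    model = TrajectorySegmenter(train_trajs, coord_system="polar")
    res = model.fit(epochs=200, seed=0)
    print(res.summary())
    report = res.evaluate(test_trajs)
    print(report.summary())
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluate import EvalReport, point_accuracy
from .infer import SegmentationResult, segment_all, segment_trajectory
from .io import Trajectory, read_trajectories
from .train import TrainConfig, build_training_set, train
from .unet import ModelArtifact, UNetConfig, load_model, save_model
from .windows import WindowSpec

__all__ = ["TrajectorySegmenter", "SegmenterResults"]


class TrajectorySegmenter:
    """Sliding-window 1D U-Net segmenter of particle trajectories.

    Parameters
    ----------
    trajectories : sequence of Trajectory
        Fully labelled training tracks.
    window_spec : WindowSpec, optional
        Sliding-window geometry (default: W=8, stride 2, centre half).
    coord_system : {'polar', 'cartesian'}
        Feature representation of the normalised windows.
    unet_config : UNetConfig, optional
        Network architecture (default: depth 2, 16 base channels).
    """

    def __init__(
        self,
        trajectories: Sequence[Trajectory],
        window_spec: WindowSpec | None = None,
        coord_system: str = "polar",
        unet_config: UNetConfig | None = None,
    ):
        self.trajectories = list(trajectories)
        self.window_spec = window_spec or WindowSpec()
        self.coord_system = coord_system
        self.unet_config = unet_config
        self.features, self.labels, self.valid_masks = build_training_set(
            self.trajectories, self.window_spec, coord_system
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, column_map=None, **kwargs
    ) -> "TrajectorySegmenter":
        """Build from a long-format DataFrame (track_id, frame, x, y, label)."""
        import io as _io

        buf = _io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        return cls(read_trajectories(buf, column_map=column_map), **kwargs)

    @classmethod
    def from_csv(cls, path, column_map=None, **kwargs) -> "TrajectorySegmenter":
        """Build from a trajectory CSV file."""
        return cls(read_trajectories(path, column_map=column_map), **kwargs)

    @property
    def n_windows(self) -> int:
        """Total number of training samples (windows across all tracks)."""
        return self.features.shape[0]

    def fit(
        self,
        learning_rate: float = 1e-4,
        epochs: int = 200,
        batch_size: int = 32,
        seed: int = 0,
        include_padded_points_in_loss: bool = True,
        callback=None,
    ) -> "SegmenterResults":
        """Train the network with Adam and binary cross-entropy."""
        cfg = TrainConfig(
            learning_rate=learning_rate,
            epochs=epochs,
            batch_size=batch_size,
            coord_system=self.coord_system,
            seed=seed,
            include_padded_points_in_loss=include_padded_points_in_loss,
        )
        seed_cfg = self.unet_config
        if seed_cfg is None:
            seed_cfg = UNetConfig(in_channels=self.features.shape[1], seed=seed)
        elif seed_cfg.seed != seed:
            seed_cfg = replace(seed_cfg, seed=seed)
        artifact, history = train(
            self.features, self.labels, self.valid_masks, cfg,
            unet_config=seed_cfg, window_spec=self.window_spec,
            callback=callback,
        )
        return SegmenterResults(self, artifact, history)


class SegmenterResults:
    """Fit results: trained weights, loss history, prediction and scoring."""

    def __init__(
        self,
        model: TrajectorySegmenter | None,
        artifact: ModelArtifact,
        loss_history: list[float],
    ):
        self.model = model
        self.artifact = artifact
        self.loss_history = list(loss_history)

    # -- prediction ---------------------------------------------------------

    def segment(self, traj: Trajectory) -> SegmentationResult:
        """Stitched per-point segmentation of one trajectory."""
        return segment_trajectory(self.artifact, traj)

    def segment_all(self, trajs: Sequence[Trajectory]) -> list[SegmentationResult]:
        return segment_all(self.artifact, trajs)

    def evaluate(self, trajs: Sequence[Trajectory]) -> EvalReport:
        """Segment labelled trajectories and score them."""
        return point_accuracy(self.segment_all(trajs), trajs)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        save_model(self.artifact, path)

    @classmethod
    def load(cls, path) -> "SegmenterResults":
        artifact = load_model(path)
        return cls(None, artifact, artifact.training_meta.get("loss_history", []))

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        meta = self.artifact.training_meta
        spec = meta["window_spec"]
        tc = meta["train_config"]
        lines = [
            "Trajectory segmentation fit",
            "=" * 46,
            f"coordinate system : {meta['coord_system']}",
            f"window            : W={spec['W']} step={spec['step']} "
            f"center={spec['center_fraction']:.0%}",
            f"network           : depth {self.artifact.config.depth}, "
            f"{self.artifact.config.base_channels} base channels, "
            f"{self.artifact.model.n_parameters()} parameters",
            f"training samples  : {meta['n_samples']} windows",
            f"optimizer         : Adam, lr={tc['learning_rate']}, "
            f"{tc['epochs']} epochs, batch {tc['batch_size']}",
            f"seed              : {meta['seed']}",
        ]
        if self.loss_history:
            lines.append(
                f"loss              : {self.loss_history[0]:.4f} (first epoch) "
                f"-> {self.loss_history[-1]:.4f} (final)"
            )
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Plot the per-epoch training loss curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, len(self.loss_history) + 1), self.loss_history)
        ax.set_xlabel("epoch")
        ax.set_ylabel("mean binary cross-entropy")
        ax.set_title("training loss")
        return ax

    def plot_segmentation(self, traj: Trajectory, ax=None):
        """Plot a trajectory coloured by predicted class (red = moving)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        res = self.segment(traj)
        xy = traj.coords
        for i in range(1, len(xy)):
            color = "red" if res.label[i] else "green"
            ax.plot(xy[i - 1 : i + 1, 0], xy[i - 1 : i + 1, 1], color=color)
        ax.set_aspect("equal")
        ax.set_title(f"track {traj.track_id} (red = moving)")
        return ax
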