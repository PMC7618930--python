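"""Inference: run the model over sliding windows and stitch per-point output.

Each window produces W probabilities; only the positions flagged in its
``weight_mask`` (centre half, extended at the trajectory ends) contribute to
the stitched result.  Where contributions overlap — inevitable with stride
2 and centre length 4 — the probabilities are averaged (unweighted) before
thresholding, so window seams do not quantise the output.  The hard label
is ``moving`` iff the stitched probability exceeds 0.5; an exact tie maps
to ``not_moving``.  Predictions on padded positions are discarded, so the
result is aligned with the original trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import TrajsegError
from .io import Trajectory, trajectories_to_dataframe
from .unet import ModelArtifact
from .windows import WindowSpec, build_features

__all__ = ["SegmentationResult", "segment_trajectory", "segment_all",
           "write_segmented_csv"]

THRESHOLD = 0.5


@dataclass
class SegmentationResult:
    """Stitched per-point output for one trajectory (padding stripped).

    ``probability[i]`` is the averaged P(moving) for point i,
    ``label[i]`` the thresholded class, and ``n_windows[i]`` the number of
    windows that contributed to point i (always >= 1).
    """

    track_id: str
    probability: np.ndarray
    label: np.ndarray
    n_windows: np.ndarray

    def __len__(self) -> int:
        return len(self.probability)


def segment_trajectory(
    artifact: ModelArtifact, traj: Trajectory
) -> SegmentationResult:
    """Segment one trajectory with a trained model.

    Features are built exactly as during training (coordinate system and
    window geometry come from the artifact's metadata).  All windows are
    evaluated in a single batch.
    """
    meta = artifact.training_meta
    spec = WindowSpec.from_dict(meta["window_spec"])
    coord_system = meta["coord_system"]

    windows = build_features(traj, spec, coord_system)
    batch = np.stack([w.features for w in windows])
    if batch.shape[1] != artifact.config.in_channels:
        raise TrajsegError(
            f"model expects {artifact.config.in_channels} feature channels, "
            f"got {batch.shape[1]}"
        )
    probs = artifact.forward(batch)  # (n_windows, W)

    padded_len = max(w.start + spec.W for w in windows)
    total = np.zeros(padded_len)
    count = np.zeros(padded_len, dtype=np.int64)
    for w, p in zip(windows, probs):
        idx = w.start + np.flatnonzero(w.weight_mask)
        total[idx] += p[w.weight_mask]
        count[idx] += 1
    if np.any(count == 0):
        raise TrajsegError("stitching left uncovered points (internal error)")
    stitched = total / count

    L = len(traj)  # drop padded tail
    prob = stitched[:L]
    return SegmentationResult(
        track_id=traj.track_id,
        probability=prob,
        label=(prob > THRESHOLD).astype(np.int64),
        n_windows=count[:L],
    )


def segment_all(
    artifact: ModelArtifact, trajs: Sequence[Trajectory]
) -> list[SegmentationResult]:
    """Segment every trajectory in a dataset."""
    return [segment_trajectory(artifact, t) for t in trajs]


def write_segmented_csv(
    trajs: Sequence[Trajectory],
    results: Sequence[SegmentationResult],
    path,
) -> None:
    """Write original points plus stitched probability and predicted label.

    The output keeps the standard trajectory columns, so it can be re-read
    by :func:`trajseg.io.read_trajectories` with the predicted labels in
    the ``label`` column (any reference labels are preserved under
    ``ref_label``).
    """
    import pandas as pd

    if not trajs:
        pd.DataFrame(
            columns=["track_id", "frame", "x", "y", "probability", "label"]
        ).to_csv(path, index=False)
        return
    extra = {
        "probability": [r.probability for r in results],
    }
    df = trajectories_to_dataframe(trajs, extra_columns=extra)
    if "label" in df.columns:
        df = df.rename(columns={"label": "ref_label"})
    df["label"] = np.concatenate([r.label for r in results])
    df.to_csv(path, index=False, float_format="%.17g")
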