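"""Scoring segmentations and the coordinate-system comparison experiment.

The headline metric is per-point accuracy with each trajectory's *first
point excluded*: a single position carries no dynamics, so it cannot be
classified and is not scored.  Accuracy is micro-averaged over all scored
points (Σ correct / Σ (L_i − 1)).  Per-class precision/recall and the
confusion counts are reported alongside because realistic datasets are
class-imbalanced and a single accuracy figure can hide a degenerate
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ValidationError
from .infer import SegmentationResult
from .io import MOVING, NOT_MOVING, Trajectory

__all__ = ["EvalReport", "point_accuracy", "coordinate_comparison"]


@dataclass
class EvalReport:
    """Segmentation scores under the first-point-excluded protocol."""

    accuracy: float
    n_scored: int
    confusion: dict  # keys 'tp','fp','fn','tn' with moving as positive
    precision_moving: float
    recall_moving: float
    precision_not_moving: float
    recall_not_moving: float
    per_trajectory_accuracy: dict

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "n_scored": self.n_scored,
            "confusion": self.confusion,
            "precision_moving": self.precision_moving,
            "recall_moving": self.recall_moving,
            "precision_not_moving": self.precision_not_moving,
            "recall_not_moving": self.recall_not_moving,
        }

    def summary(self) -> str:
        c = self.confusion
        lines = [
            "Segmentation evaluation (first point of each track excluded)",
            f"  scored points : {self.n_scored}",
            f"  accuracy      : {self.accuracy:.4f}",
            f"  moving        : precision {self.precision_moving:.4f}  "
            f"recall {self.recall_moving:.4f}",
            f"  not_moving    : precision {self.precision_not_moving:.4f}  "
            f"recall {self.recall_not_moving:.4f}",
            f"  confusion     : tp={c['tp']} fp={c['fp']} fn={c['fn']} tn={c['tn']}",
        ]
        return "\n".join(lines)


def _safe_div(a: float, b: float) -> float:
    return float(a / b) if b else float("nan")


def point_accuracy(
    preds: Sequence[SegmentationResult], refs: Sequence[Trajectory]
) -> EvalReport:
    """Score predictions against reference labels.

    ``preds`` and ``refs`` are matched by track id; lengths must agree.
    Index 0 of every track is excluded, so ``n_scored == Σ (L_i − 1)``.
    """
    ref_by_id = {t.track_id: t for t in refs}
    if len(ref_by_id) != len(refs):
        raise ValidationError("duplicate track ids in reference set")

    tp = fp = fn = tn = 0
    per_track: dict[str, float] = {}
    for pred in preds:
        ref = ref_by_id.get(pred.track_id)
        if ref is None:
            raise ValidationError(f"no reference for track {pred.track_id!r}")
        if ref.labels is None:
            raise ValidationError(f"track {pred.track_id!r} has no reference labels")
        if len(pred) != len(ref):
            raise ValidationError(
                f"track {pred.track_id!r}: prediction length {len(pred)} != "
                f"reference length {len(ref)}"
            )
        p = pred.label[1:]
        y = ref.labels[1:]
        tp += int(np.sum((p == MOVING) & (y == MOVING)))
        fp += int(np.sum((p == MOVING) & (y == NOT_MOVING)))
        fn += int(np.sum((p == NOT_MOVING) & (y == MOVING)))
        tn += int(np.sum((p == NOT_MOVING) & (y == NOT_MOVING)))
        per_track[pred.track_id] = (
            float(np.mean(p == y)) if len(p) else float("nan")
        )

    n_scored = tp + fp + fn + tn
    return EvalReport(
        accuracy=_safe_div(tp + tn, n_scored),
        n_scored=n_scored,
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        precision_moving=_safe_div(tp, tp + fp),
        recall_moving=_safe_div(tp, tp + fn),
        precision_not_moving=_safe_div(tn, tn + fn),
        recall_not_moving=_safe_div(tn, tn + fp),
        per_trajectory_accuracy=per_track,
    )


def coordinate_comparison(
    train_trajs: Sequence[Trajectory],
    test_trajs: Sequence[Trajectory],
    base_config=None,
    window_spec=None,
    unet_config=None,
) -> dict:
    """Train twin models differing only in coordinate system and score both.

    Returns ``{"cartesian": EvalReport, "polar": EvalReport}``.  Both runs
    share the same seed, data and hyperparameters, isolating the effect of
    the feature representation.  No ordering between the two accuracies is
    asserted anywhere: which representation wins is dataset-dependent and
    the margin is typically small.
    """
    from dataclasses import replace

    from .infer import segment_all
    from .train import TrainConfig, build_training_set, train
    from .windows import WindowSpec

    base_config = base_config or TrainConfig()
    window_spec = window_spec or WindowSpec()

    out = {}
    for coord_system in ("cartesian", "polar"):
        cfg = replace(base_config, coord_system=coord_system)
        feats, labels, masks = build_training_set(
            train_trajs, window_spec, coord_system
        )
        artifact, _ = train(
            feats, labels, masks, cfg,
            unet_config=unet_config, window_spec=window_spec,
        )
        preds = segment_all(artifact, test_trajs)
        out[coord_system] = point_accuracy(preds, test_trajs)
    return out
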