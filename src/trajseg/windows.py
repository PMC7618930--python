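"""Sliding-window preprocessing: padding, window placement and features.

A trajectory is cut into fixed-length windows of ``W`` points that slide
with a stride of 25 % of the window length.  Each window is normalised to
its *own* first position, so every window starts at the origin and only the
displacements within the window matter (translation invariance).  Features
are either the normalised Cartesian displacements (x, y) or their polar form
(r, θ); the radius channel expresses the displacement magnitude in a single
value, which is the motivation for the polar representation.

When stitching per-window predictions back onto the trajectory, only the
centre 50 % of each window contributes, except that the first window also
contributes its leading quarter and the last window its trailing quarter, so
every point of the (padded) trajectory receives at least one prediction.

Trajectories shorter than ``W`` are padded by repeating the last observed
point; the repeated tail is a zero-displacement segment and is labelled
``not_moving`` (stalled behaviour).  Padded positions are flagged in
``valid_mask`` and removed again after stitching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, ValidationError
from .io import NOT_MOVING, Trajectory

__all__ = [
    "WindowSpec",
    "Window",
    "pad_trajectory",
    "enumerate_windows",
    "normalize_window",
    "to_polar",
    "build_features",
    "COORD_SYSTEMS",
]

COORD_SYSTEMS = ("cartesian", "polar")


@dataclass(frozen=True)
class WindowSpec:
    """Geometry of the sliding window.

    Parameters
    ----------
    W : int
        Window length in points (default 8).  Must be at least 4 and
        divisible by ``2**depth`` of the network so the encoder can pool.
    step : int
        Stride between window starts; default ``round(0.25 * W)`` (= 2 for
        W = 8), minimum 1.
    center_fraction : float
        Fraction of each window that contributes to stitching (default 0.5,
        i.e. the centre half).
    """

    W: int = 8
    step: int = field(default=-1)
    center_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.step == -1:
            object.__setattr__(self, "step", max(1, round(0.25 * self.W)))
        if self.W < 4:
            raise ConfigurationError(f"window length W={self.W} must be >= 4")
        if not (1 <= self.step <= self.W):
            raise ConfigurationError(
                f"step={self.step} must be in [1, W={self.W}]"
            )
        if not (0.0 < self.center_fraction <= 1.0):
            raise ConfigurationError(
                f"center_fraction={self.center_fraction} must be in (0, 1]"
            )
        if self.center_len < self.step:
            raise ConfigurationError(
                f"centre length {self.center_len} < step {self.step}: "
                "stitching would leave uncovered points"
            )

    @property
    def center_len(self) -> int:
        return round(self.center_fraction * self.W)

    @property
    def center_start(self) -> int:
        # centre block placed symmetrically; W=8 -> indices 2..5
        return (self.W - self.center_len) // 2

    def to_dict(self) -> dict:
        return {
            "W": self.W,
            "step": self.step,
            "center_fraction": self.center_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WindowSpec":
        return cls(**d)


@dataclass
class Window:
    """One sliding-window slice of a (padded) trajectory.

    ``features`` has shape (channels, W): rows are (x, y) displacements or
    (r, θ).  ``valid_mask`` is False on padded positions, ``weight_mask``
    marks the positions this window contributes to stitching, and ``start``
    locates the window within the padded trajectory.
    """

    start: int
    features: np.ndarray
    valid_mask: np.ndarray
    weight_mask: np.ndarray
    labels: np.ndarray | None = None


def pad_trajectory(coords: np.ndarray, W: int, labels: np.ndarray | None = None):
    """Pad a trajectory shorter than ``W`` by repeating its last point.

    Returns ``(padded_coords, valid_mask, padded_labels)``.  Trajectories of
    length >= W pass through unchanged with an all-True mask.  Appended
    positions are marked invalid and labelled ``not_moving``.
    """
    if W < 1:
        raise ConfigurationError(f"window length W={W} must be >= 1")
    coords = np.asarray(coords, dtype=np.float64)
    L = len(coords)
    if L < 1:
        raise ValidationError("cannot pad an empty trajectory")
    if L >= W:
        mask = np.ones(L, dtype=bool)
        return coords, mask, labels
    n_pad = W - L
    padded = np.concatenate([coords, np.repeat(coords[-1:], n_pad, axis=0)])
    mask = np.concatenate([np.ones(L, dtype=bool), np.zeros(n_pad, dtype=bool)])
    padded_labels = None
    if labels is not None:
        padded_labels = np.concatenate(
            [np.asarray(labels, dtype=np.int64), np.full(n_pad, NOT_MOVING)]
        )
    return padded, mask, padded_labels


def enumerate_windows(L: int, spec: WindowSpec) -> list[tuple[int, np.ndarray]]:
    """Place windows over a padded trajectory of length ``L``.

    Starts advance by ``spec.step`` from 0; the final start is snapped to
    ``L - W`` so the tail is always covered.  Each returned ``weight_mask``
    (length W, boolean) marks the positions that window contributes to the
    stitched result: the centre block for interior windows, extended to the
    window edge for the first and last windows.
    """
    W = spec.W
    if L < W:
        raise ValidationError(f"padded length {L} < window length {W}; pad first")
    starts = list(range(0, L - W + 1, spec.step))
    if starts[-1] != L - W:
        starts.append(L - W)

    c0, c1 = spec.center_start, spec.center_start + spec.center_len
    out = []
    for i, s in enumerate(starts):
        mask = np.zeros(W, dtype=bool)
        mask[c0:c1] = True
        if i == 0:
            mask[:c0] = True
        if i == len(starts) - 1:
            mask[c1:] = True
        out.append((s, mask))
    return out


def normalize_window(coords: np.ndarray) -> np.ndarray:
    """Translate window coordinates so its first point is the origin.

    ``out[i] = coords[i] - coords[0]``; the result is invariant under any
    constant shift of the whole window.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if not np.all(np.isfinite(coords)):
        raise ValidationError("non-finite coordinates in window")
    return coords - coords[0]


def to_polar(displacements: np.ndarray) -> np.ndarray:
    """Convert origin-normalised displacements to (r, θ).

    r = sqrt(x² + y²), θ = atan2(y, x) ∈ (−π, π], with θ defined as 0 at the
    origin (numpy's atan2(0, 0) convention).  ``r cos θ, r sin θ`` recovers
    the input to floating-point precision.
    """
    d = np.asarray(displacements, dtype=np.float64)
    r = np.hypot(d[:, 0], d[:, 1])
    theta = np.arctan2(d[:, 1], d[:, 0])
    # atan2 returns -pi for negative-zero y; fold onto the (-pi, pi] contract
    theta = np.where(theta == -np.pi, np.pi, theta)
    theta = np.where(r == 0.0, 0.0, theta)
    return np.column_stack([r, theta])


def build_features(
    traj: Trajectory, spec: WindowSpec, coord_system: str = "polar"
) -> list[Window]:
    """Build the full window feature set for one trajectory.

    Pipeline: pad to >= W -> enumerate windows -> per-window origin
    normalisation (each window uses *its own* first point) -> optional polar
    conversion.  Features are returned channels-first, shape (2, W).
    """
    if coord_system not in COORD_SYSTEMS:
        raise ConfigurationError(
            f"coord_system must be one of {COORD_SYSTEMS}, got {coord_system!r}"
        )
    padded, valid, padded_labels = pad_trajectory(traj.coords, spec.W, traj.labels)
    windows = []
    for start, weight_mask in enumerate_windows(len(padded), spec):
        sl = slice(start, start + spec.W)
        disp = normalize_window(padded[sl])
        feats = to_polar(disp) if coord_system == "polar" else disp
        windows.append(
            Window(
                start=start,
                features=feats.T.copy(),
                valid_mask=valid[sl].copy(),
                weight_mask=weight_mask,
                labels=None if padded_labels is None else padded_labels[sl].copy(),
            )
        )
    return windows
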