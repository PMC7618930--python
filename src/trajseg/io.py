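"""Reading and writing particle trajectories as delimited text.

The on-disk dialect is a comma-separated file with a header row and the
default columns ``track_id, frame, x, y`` plus an optional ``label`` column.
Column names are remappable via ``column_map`` so exports from common
tracking tools can be ingested without editing the file.  Coordinates are
kept in whatever unit the tracker produced (pixels or µm); the downstream
feature transform is scale-covariant, so no unit conversion is performed and
the unit is carried as metadata only.

Per-point labels use the package-wide integer encoding

    ``moving`` (directed motion)  -> 1
    ``not_moving`` (stalled, Brownian or confined) -> 0

which is stable across save/load round-trips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, TrajectoryParseError, ValidationError

__all__ = [
    "MOVING",
    "NOT_MOVING",
    "LABEL_NAMES",
    "Trajectory",
    "DEFAULT_COLUMNS",
    "read_trajectories",
    "write_trajectories",
    "trajectories_to_dataframe",
]

#: Integer code for the directed-motion class.
MOVING = 1
#: Integer code for the stalled/Brownian/confined class.
NOT_MOVING = 0
#: Human-readable names, index-aligned with the integer codes.
LABEL_NAMES = {NOT_MOVING: "not_moving", MOVING: "moving"}

DEFAULT_COLUMNS: dict[str, str] = {
    "track_id": "track_id",
    "frame": "frame",
    "x": "x",
    "y": "y",
    "label": "label",
}


@dataclass
class Trajectory:
    """An ordered sequence of 2D particle positions over consecutive frames.

    Parameters
    ----------
    track_id : str
        Identifier of the track, unique within a dataset.
    frames : ndarray of int, shape (L,)
        Strictly increasing frame indices.
    coords : ndarray of float, shape (L, 2)
        (x, y) positions, finite, in a single consistent unit.
    labels : ndarray of int, shape (L,), optional
        Per-point motion class (``MOVING``/``NOT_MOVING``).
    unit : str, optional
        Free-text unit of the coordinates (e.g. ``"pixel"``, ``"um"``);
        metadata only, never used in computation.
    """

    track_id: str
    frames: np.ndarray
    coords: np.ndarray
    labels: np.ndarray | None = None
    unit: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
        self.validate()

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def has_labels(self) -> bool:
        return self.labels is not None

    def validate(self) -> None:
        """Raise :class:`ValidationError` if any structural invariant fails."""
        if len(self.frames) < 1:
            raise ValidationError(f"track {self.track_id!r}: empty trajectory")
        if self.coords.shape != (len(self.frames), 2):
            raise ValidationError(
                f"track {self.track_id!r}: coords shape {self.coords.shape} "
                f"does not match {len(self.frames)} frames"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"track {self.track_id!r}: non-finite coordinates")
        d = np.diff(self.frames)
        if np.any(d <= 0):
            raise ValidationError(
                f"track {self.track_id!r}: frame indices not strictly increasing"
            )
        if self.labels is not None:
            if len(self.labels) != len(self.frames):
                raise ValidationError(
                    f"track {self.track_id!r}: {len(self.labels)} labels for "
                    f"{len(self.frames)} points"
                )
            bad = set(np.unique(self.labels)) - {MOVING, NOT_MOVING}
            if bad:
                raise ValidationError(
                    f"track {self.track_id!r}: labels outside {{0, 1}}: {sorted(bad)}"
                )
        if np.any(d > 1):
            warnings.warn(
                f"track {self.track_id!r} has frame gaps; points are treated "
                "as consecutive by the segmentation pipeline",
                stacklevel=2,
            )

    def translated(self, offset) -> "Trajectory":
        """Return a copy shifted by a constant (x, y) offset."""
        return Trajectory(
            track_id=self.track_id,
            frames=self.frames.copy(),
            coords=self.coords + np.asarray(offset, dtype=np.float64),
            labels=None if self.labels is None else self.labels.copy(),
            unit=self.unit,
        )


def _parse_label_value(value, row: int) -> int:
    if isinstance(value, str):
        s = value.strip().lower()
        for code, name in LABEL_NAMES.items():
            if s == name:
                return code
        try:
            value = float(s)
        except ValueError:
            raise TrajectoryParseError(
                f"row {row}: unrecognised label {value!r} "
                f"(expected 0/1 or {sorted(LABEL_NAMES.values())})"
            ) from None
    v = float(value)
    if v not in (0.0, 1.0):
        raise TrajectoryParseError(
            f"row {row}: label value {value!r} outside the two-class domain {{0, 1}}"
        )
    return int(v)


def read_trajectories(
    path,
    column_map: Mapping[str, str] | None = None,
    unit: str | None = None,
) -> list[Trajectory]:
    """Read trajectories from a delimited-text file.

    Parameters
    ----------
    path : path-like
        CSV file with a header row.
    column_map : mapping, optional
        Maps the canonical names ``track_id, frame, x, y, label`` to the
        column names actually present in the file.  Unmapped names fall back
        to the canonical defaults.  The label column is optional.
    unit : str, optional
        Coordinate unit recorded on every returned trajectory.

    Returns
    -------
    list of Trajectory
        One per distinct track id, points sorted by frame, in order of first
        appearance in the file.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ConfigurationError(
                f"column_map contains unknown keys: {sorted(unknown)}"
            )
        cols.update(column_map)

    df = pd.read_csv(path, dtype={cols["track_id"]: str},
                     float_precision="round_trip")
    for key in ("track_id", "frame", "x", "y"):
        if cols[key] not in df.columns:
            raise ConfigurationError(
                f"required column {cols[key]!r} (for {key!r}) not found in "
                f"{path}; available: {list(df.columns)}"
            )
    has_labels = cols["label"] in df.columns

    for key in ("frame", "x", "y"):
        col = cols[key]
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
            raise TrajectoryParseError(
                f"row {row}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r}"
            )
        if numeric.isna().any():
            row = int(numeric.isna().idxmax()) + 2
            raise TrajectoryParseError(f"row {row}: missing value in column {col!r}")
        df[col] = numeric

    trajectories: list[Trajectory] = []
    for track_id, group in df.groupby(cols["track_id"], sort=False):
        group = group.sort_values(cols["frame"], kind="stable")
        frames = group[cols["frame"]].to_numpy(dtype=np.int64)
        if len(np.unique(frames)) != len(frames):
            raise ValidationError(
                f"track {track_id!r}: duplicate frame index in file {path}"
            )
        labels = None
        if has_labels:
            labels = np.array(
                [
                    _parse_label_value(v, row=int(i) + 2)
                    for i, v in zip(group.index, group[cols["label"]])
                ],
                dtype=np.int64,
            )
        trajectories.append(
            Trajectory(
                track_id=str(track_id),
                frames=frames,
                coords=group[[cols["x"], cols["y"]]].to_numpy(dtype=np.float64),
                labels=labels,
                unit=unit,
            )
        )
    return trajectories


def trajectories_to_dataframe(
    trajs: Sequence[Trajectory],
    extra_columns: Mapping[str, Sequence[np.ndarray]] | None = None,
) -> pd.DataFrame:
    """Flatten trajectories into one long-format DataFrame.

    ``extra_columns`` maps a column name to a list of per-trajectory arrays
    (same order and lengths as ``trajs``), used e.g. to attach predicted
    probabilities next to the raw points.
    """
    any_labels = any(t.labels is not None for t in trajs)
    rows = {
        "track_id": np.concatenate([[t.track_id] * len(t) for t in trajs])
        if trajs
        else np.array([], dtype=str),
        "frame": np.concatenate([t.frames for t in trajs])
        if trajs
        else np.array([], dtype=np.int64),
        "x": np.concatenate([t.coords[:, 0] for t in trajs])
        if trajs
        else np.array([]),
        "y": np.concatenate([t.coords[:, 1] for t in trajs])
        if trajs
        else np.array([]),
    }
    if any_labels:
        for t in trajs:
            if t.labels is None:
                raise ValidationError(
                    f"track {t.track_id!r} has no labels but other tracks do"
                )
        rows["label"] = np.concatenate([t.labels for t in trajs])
    if extra_columns:
        for name, arrays in extra_columns.items():
            rows[name] = (
                np.concatenate(list(arrays)) if trajs else np.array([])
            )
    return pd.DataFrame(rows)


def write_trajectories(trajs: Sequence[Trajectory], path) -> None:
    """Write trajectories to CSV so that a subsequent read round-trips.

    Coordinates are written with 17 significant digits, which reproduces
    float64 values exactly on re-read and keeps seeded runs byte-identical.
    An empty list produces a header-only file.
    """
    df = trajectories_to_dataframe(trajs)
    if not trajs:
        df = pd.DataFrame(columns=["track_id", "frame", "x", "y"])
    df.to_csv(path, index=False, float_format="%.17g")
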