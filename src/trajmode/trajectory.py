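"""The trajectory container and its plain-text (CSV) serialization.

A trajectory is a time-ordered sequence of 2-D positions recorded at a
uniform frame interval: columns ``frame`` (0-based integer), ``t`` (s),
``x`` and ``y`` (um), plus an optional ``label`` column carrying per-frame
ground-truth modes (``free``, ``spring2``, ``quartic4``) for simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "read_trajectory", "write_trajectory"]

#: relative tolerance on frame-interval uniformity
_DT_RTOL = 1e-9

_VALID_LABELS = frozenset({"free", "spring2", "quartic4"})


@dataclass
class Trajectory:
    """Time-ordered 2-D positions with a uniform acquisition interval."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.t.size
        if n < 2:
            raise ValueError(f"a trajectory needs >= 2 frames, got {n}")
        if self.x.size != n or self.y.size != n:
            raise ValueError(
                f"length mismatch: t has {n}, x has {self.x.size}, y has {self.y.size}"
            )
        for name, arr in (("t", self.t), ("x", self.x), ("y", self.y)):
            if not np.all(np.isfinite(arr)):
                row = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise ValueError(f"non-finite value in column '{name}' at row {row}")
        dts = np.diff(self.t)
        if np.any(dts <= 0):
            row = int(np.flatnonzero(dts <= 0)[0]) + 1
            raise ValueError(f"time not strictly increasing at row {row}")
        dt0 = dts[0]
        bad = np.abs(dts - dt0) > _DT_RTOL * max(abs(dt0), 1.0)
        if np.any(bad):
            row = int(np.flatnonzero(bad)[0]) + 1
            raise ValueError(
                f"non-uniform frame interval at row {row}: "
                f"dt={dts[row - 1]!r} vs dt0={dt0!r}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.size != n:
                raise ValueError("labels length does not match trajectory length")

    @property
    def n_frames(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of positions."""
        return np.column_stack([self.x, self.y])

    @property
    def displacements(self) -> np.ndarray:
        """(N-1, 2) array of frame-to-frame displacements."""
        return np.column_stack([np.diff(self.x), np.diff(self.y)])

    def window(self, start: int, stop: int) -> "Trajectory":
        """Sub-trajectory over frames [start, stop) (0-based, half-open)."""
        labels = None if self.labels is None else self.labels[start:stop]
        return Trajectory(self.t[start:stop], self.x[start:stop], self.y[start:stop], labels)

    def translated(self, dx: float, dy: float) -> "Trajectory":
        return Trajectory(self.t.copy(), self.x + dx, self.y + dy, self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trajectory):
            return NotImplemented
        same = (
            np.array_equal(self.t, other.t)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
        )
        if not same:
            return False
        if (self.labels is None) != (other.labels is None):
            return False
        return self.labels is None or bool(np.array_equal(self.labels, other.labels))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as CSV with header ``frame,t,x,y[,label]``.

    Numbers are written with 12 significant digits so a read/write round trip
    reproduces coordinates to better than 1e-9 relative and a second write is
    byte-identical.
    """
    df = pd.DataFrame(
        {
            "frame": np.arange(traj.n_frames, dtype=int),
            "t": traj.t,
            "x": traj.x,
            "y": traj.y,
        }
    )
    if traj.labels is not None:
        df["label"] = traj.labels
    df.to_csv(path, index=False, float_format="%.12g")


def read_trajectory(path) -> Trajectory:
    """Read a trajectory CSV (see :func:`write_trajectory` for the layout).

    Raises ``ValueError`` naming the offending row for missing columns, NaN
    coordinates, or a non-uniform frame interval.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty trajectory file: {path}") from exc
    missing = [c for c in ("frame", "t", "x", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    for name in ("t", "x", "y"):
        col = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(col)):
            row = int(np.flatnonzero(~np.isfinite(col))[0])
            raise ValueError(f"{path}: invalid value in column '{name}' at row {row}")
    labels = None
    if "label" in df.columns:
        labels = df["label"].to_numpy(dtype=object)
        bad = [str(v) for v in np.unique(labels) if str(v) not in _VALID_LABELS]
        if bad:
            raise ValueError(f"{path}: unknown label value(s) {bad}")
    return Trajectory(
        df["t"].to_numpy(dtype=float),
        df["x"].to_numpy(dtype=float),
        df["y"].to_numpy(dtype=float),
        labels,
    )
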