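"""Kinematic primitives: step distances, per-second speed, histogram.

Distance between consecutive frames is the straight-line Euclidean
distance between their coordinates ("triangulation" of the camera
coordinates).  Instantaneous velocity is defined per second as the sum
of the ``fps`` inter-frame distances inside non-overlapping windows
aligned to the first frame; a trailing partial window is discarded.
Windows overlapping excluded (missing) frames are reported as missing
and every summary carries the effective observed time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import Trajectory


class KinematicsError(ValueError):
    pass


@dataclass(frozen=True)
class SpeedSeries:
    """Ordered per-second speeds (cm/s); NaN marks an excluded window."""

    fish_id: str
    values: np.ndarray
    window_s: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        ok = self.values[~np.isnan(self.values)]
        if (ok < 0).any():
            raise KinematicsError("speeds must be non-negative")

    @property
    def effective_time_s(self) -> float:
        return float((~np.isnan(self.values)).sum() * self.window_s)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SpeedHistogram:
    """Cumulated seconds per 1 cm/s speed bin, plus one overflow bin.

    ``seconds[i]`` is the time spent in ``[i, i+1)`` cm/s for
    ``i < ceiling`` and at ``>= ceiling`` cm/s for the last entry.
    """

    fish_id: str
    seconds: np.ndarray
    bin_width_cm_s: float = 1.0
    ceiling_cm_s: float = 21.0

    @property
    def bin_edges(self) -> list[tuple[float, float]]:
        edges = [(float(i), float(i + 1)) for i in range(int(self.ceiling_cm_s))]
        edges.append((float(self.ceiling_cm_s), float("inf")))
        return edges

    def to_frame(self) -> pd.DataFrame:
        lo, hi = zip(*self.bin_edges)
        return pd.DataFrame({"bin_lo": lo, "bin_hi": hi, "seconds": self.seconds})


def step_distances(traj: Trajectory) -> np.ndarray:
    """Euclidean distance (cm) between consecutive frames; NaN across gaps."""
    if len(traj) < 2:
        raise KinematicsError("need at least 2 frames to compute step distances")
    dx = np.diff(traj.x_cm)
    dy = np.diff(traj.y_cm)
    return np.hypot(dx, dy)


def total_distance(traj: Trajectory) -> float:
    """Total distance swum (cm) over all observed steps."""
    return float(np.nansum(step_distances(traj)))


def instantaneous_velocity(traj: Trajectory) -> SpeedSeries:
    """Per-second speeds: sums of ``fps`` inter-frame distances (cm/s).

    Requires an integer frame rate and contiguous frame numbering (gaps
    in tracking are NaN coordinates, not absent rows).
    """
    fps = int(round(traj.fps))
    if abs(traj.fps - fps) > 1e-9 or fps <= 0:
        raise KinematicsError("windowed velocity requires an integer fps")
    if len(traj) >= 2 and not np.array_equal(
        np.diff(traj.frame_index), np.ones(len(traj) - 1, dtype=np.int64)
    ):
        raise KinematicsError("instantaneous_velocity requires contiguous frame indices")
    steps = step_distances(traj)
    n_windows = len(steps) // fps
    if n_windows == 0:
        raise KinematicsError("recording shorter than one 1 s window")
    windows = steps[: n_windows * fps].reshape(n_windows, fps)
    values = windows.sum(axis=1)
    values[np.isnan(windows).any(axis=1)] = np.nan
    return SpeedSeries(fish_id=traj.fish_id, values=values)


def max_speed(series: SpeedSeries) -> float:
    """Maximum per-second instantaneous speed (cm/s)."""
    valid = series.values[~np.isnan(series.values)]
    if len(valid) == 0:
        raise KinematicsError("no valid windows")
    return float(valid.max())


def speed_histogram(series: SpeedSeries, ceiling_cm_s: float = 21.0) -> SpeedHistogram:
    """Cumulated time per 1 cm/s increment (overflow bin above ceiling)."""
    ceiling = int(ceiling_cm_s)
    valid = series.values[~np.isnan(series.values)]
    idx = np.minimum(np.floor(valid).astype(int), ceiling)
    seconds = np.bincount(idx, minlength=ceiling + 1).astype(float) * series.window_s
    return SpeedHistogram(
        fish_id=series.fish_id,
        seconds=seconds,
        ceiling_cm_s=float(ceiling),
    )


def kinematics_summary(traj: Trajectory) -> dict:
    """Per-fish kinematics row: total distance, max speed, effective time."""
    series = instantaneous_velocity(traj)
    return {
        "fish_id": traj.fish_id,
        "total_distance_cm": total_distance(traj),
        "max_speed_cm_s": max_speed(series),
        "effective_time_s": series.effective_time_s,
    }
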