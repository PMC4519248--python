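"""Speed-activity-profile classification and tank-zone occupancy.

The three speed activity profiles (SAP) partition per-second swimming
speed by body length (bl): rest below 0.5 bl/s, moderate from 0.5 to
3 bl/s, fast at and above 3 bl/s — i.e. 1/6 cm/s thresholds for a 2 cm
fish, 2/12 cm/s for a 4 cm fish.  Bands are half-open ``[0, 0.5)``,
``[0.5, 3)``, ``[3, inf)`` so every speed belongs to exactly one class.

Spatial occupancy is per frame: the upper quarter of the water column
for surface-respiration behavior, and a concentric rectangle covering
exactly half the tank footprint for center avoidance (centrophobia).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kinematics import SpeedSeries
from .trajectory import Trajectory

SAP_CLASSES = ("rest", "moderate", "fast")


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class SAPProfile:
    """Cumulated time per speed-activity class for one fish."""

    fish_id: str
    thresholds_cm_s: tuple[float, float]  # (rest upper, fast lower)
    seconds: tuple[float, float, float]  # rest, moderate, fast
    fractions_pct: tuple[float, float, float]

    @property
    def effective_time_s(self) -> float:
        return float(sum(self.seconds))


@dataclass(frozen=True)
class ZoneOccupancy:
    """Time spent inside a tank zone, with the observed denominator."""

    fish_id: str
    zone: str  # "upper_quarter" | "center_50pct"
    seconds_in_zone: float
    total_observed_s: float

    @property
    def fraction(self) -> float:
        if self.total_observed_s == 0:
            return float("nan")
        return self.seconds_in_zone / self.total_observed_s


def resolve_sap_thresholds(body_length_cm: float) -> tuple[float, float]:
    """(rest upper, fast lower) thresholds in cm/s: 0.5 bl/s and 3 bl/s."""
    if not body_length_cm > 0:
        raise ProfileError("body_length_cm must be positive")
    return 0.5 * body_length_cm, 3.0 * body_length_cm


def classify_sap(series: SpeedSeries, body_length_cm: float) -> SAPProfile:
    """Assign each valid 1 s window to rest/moderate/fast by body length."""
    rest_upper, fast_lower = resolve_sap_thresholds(body_length_cm)
    v = series.values[~np.isnan(series.values)]
    rest = float((v < rest_upper).sum() * series.window_s)
    fast = float((v >= fast_lower).sum() * series.window_s)
    moderate = float(len(v) * series.window_s - rest - fast)
    total = rest + moderate + fast
    if total > 0:
        fracs = (100.0 * rest / total, 100.0 * moderate / total, 100.0 * fast / total)
    else:
        fracs = (float("nan"),) * 3
    return SAPProfile(
        fish_id=series.fish_id,
        thresholds_cm_s=(rest_upper, fast_lower),
        seconds=(rest, moderate, fast),
        fractions_pct=fracs,
    )


def upper_quarter_time(traj: Trajectory, upper_fraction: float = 0.25) -> ZoneOccupancy:
    """Time spent in the top ``upper_fraction`` of the water column.

    Vertical-plane recordings only: ``y`` is depth measured upward from
    the tank floor and ``tank_height_cm`` is the water-column height.
    Each observed frame contributes ``1/fps`` seconds.
    """
    if not 0 < upper_fraction < 1:
        raise ProfileError("upper_fraction must be in (0, 1)")
    valid = ~traj.missing_mask
    threshold = (1.0 - upper_fraction) * traj.tank_height_cm
    in_zone = valid & (traj.y_cm >= threshold)
    return ZoneOccupancy(
        fish_id=traj.fish_id,
        zone="upper_quarter",
        seconds_in_zone=float(in_zone.sum() / traj.fps),
        total_observed_s=float(valid.sum() / traj.fps),
    )


def center_zone_bounds(
    tank_width_cm: float, tank_height_cm: float, area_fraction: float = 0.5
) -> tuple[float, float, float, float]:
    """(x_lo, x_hi, y_lo, y_hi) of the concentric homothetic center zone.

    The zone shares the tank's center and aspect ratio; each side is
    scaled by ``sqrt(area_fraction)`` so the area fraction is exact.
    """
    if not 0 < area_fraction <= 1:
        raise ProfileError("area_fraction must be in (0, 1]")
    s = math.sqrt(area_fraction)
    hw = 0.5 * s * tank_width_cm
    hh = 0.5 * s * tank_height_cm
    cx, cy = 0.5 * tank_width_cm, 0.5 * tank_height_cm
    return cx - hw, cx + hw, cy - hh, cy + hh


def center_zone_time(traj: Trajectory, area_fraction: float = 0.5) -> ZoneOccupancy:
    """Time spent in the central homothetic zone (boundary counts inside).

    Horizontal-plane recordings: both coordinates are the tank footprint.
    """
    x_lo, x_hi, y_lo, y_hi = center_zone_bounds(
        traj.tank_width_cm, traj.tank_height_cm, area_fraction
    )
    valid = ~traj.missing_mask
    in_zone = (
        valid
        & (traj.x_cm >= x_lo)
        & (traj.x_cm <= x_hi)
        & (traj.y_cm >= y_lo)
        & (traj.y_cm <= y_hi)
    )
    return ZoneOccupancy(
        fish_id=traj.fish_id,
        zone="center_50pct",
        seconds_in_zone=float(in_zone.sum() / traj.fps),
        total_observed_s=float(valid.sum() / traj.fps),
    )


def subsample_positions(traj: Trajectory, stride_frames: int = 150) -> np.ndarray:
    """Every ``stride_frames``-th position for trajectory diagrams.

    Default stride of 150 frames is one point every 6 s at 25 fps.
    Returns an array of rows ``(frame_index, x_cm, y_cm)``.
    """
    if stride_frames < 1:
        raise ProfileError("stride_frames must be >= 1")
    sl = slice(None, None, stride_frames)
    return np.column_stack([traj.frame_index[sl], traj.x_cm[sl], traj.y_cm[sl]])
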