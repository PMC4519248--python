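"""Trajectory containers, validation, file I/O and gap handling.

A recording is a single fish filmed in one plane of a rectangular tank:
the horizontal plane for locomotion/centrophobia assays, the vertical
plane for water-column occupancy.  Coordinates are centimetres with the
origin at the bottom-left corner of the filmed cross-section; for
vertical recordings ``y`` increases toward the water surface, so the
"upper quarter" is ``y >= 0.75 * tank_height_cm``.

Missing coordinates (tracking loss) are kept as explicit NaNs and never
silently dropped: every downstream statistic reports the effective
observed time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

GENOTYPES = ("WT", "HT", "HM")

#: absolute slack (cm) allowed when checking coordinates against tank walls
COORD_TOLERANCE_CM = 1e-6


class TrajectoryError(ValueError):
    """Raised for malformed or invariant-violating trajectory data."""


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed 2-D positions of one fish plus recording metadata.

    Parameters
    ----------
    frame_index
        Strictly increasing, non-negative integer frame numbers.
    x_cm, y_cm
        Coordinates in cm; NaN marks a missing (untracked) frame.
    fps
        Camera frame rate (frames per second).
    body_length_cm
        Fish standard length, used to normalise speed thresholds.
    tank_width_cm, tank_height_cm
        Extent of the filmed cross-section.  For vertical-plane
        recordings ``tank_height_cm`` is the water-column height.
    """

    fish_id: str
    genotype: str
    age_group: str
    fps: float
    body_length_cm: float
    tank_width_cm: float
    tank_height_cm: float
    frame_index: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "frame_index", np.asarray(self.frame_index, dtype=np.int64))
        object.__setattr__(self, "x_cm", np.asarray(self.x_cm, dtype=float))
        object.__setattr__(self, "y_cm", np.asarray(self.y_cm, dtype=float))
        if self.genotype not in GENOTYPES:
            raise TrajectoryError(f"unknown genotype {self.genotype!r}; expected one of {GENOTYPES}")
        for name in ("fps", "body_length_cm", "tank_width_cm", "tank_height_cm"):
            if not getattr(self, name) > 0:
                raise TrajectoryError(f"{name} must be positive, got {getattr(self, name)!r}")
        n = len(self.frame_index)
        if len(self.x_cm) != n or len(self.y_cm) != n:
            raise TrajectoryError("frame_index, x_cm and y_cm must have equal length")
        if n and (np.diff(self.frame_index) <= 0).any():
            raise TrajectoryError("frame_index must be strictly increasing")
        if n and self.frame_index[0] < 0:
            raise TrajectoryError("frame_index must be non-negative")
        self._check_bounds("x_cm", self.x_cm, self.tank_width_cm)
        self._check_bounds("y_cm", self.y_cm, self.tank_height_cm)

    def _check_bounds(self, name: str, values: np.ndarray, extent: float) -> None:
        bad = (values < -COORD_TOLERANCE_CM) | (values > extent + COORD_TOLERANCE_CM)
        bad &= ~np.isnan(values)
        if bad.any():
            i = int(np.argmax(bad))
            raise TrajectoryError(
                f"{name}[frame {int(self.frame_index[i])}] = {values[i]:g} cm outside "
                f"[0, {extent:g}] for fish {self.fish_id!r}"
            )

    def __len__(self) -> int:
        return len(self.frame_index)

    @property
    def missing_mask(self) -> np.ndarray:
        """True where a frame has no usable position (either coordinate NaN)."""
        return np.isnan(self.x_cm) | np.isnan(self.y_cm)

    @property
    def n_valid_frames(self) -> int:
        return int((~self.missing_mask).sum())

    @property
    def duration_s(self) -> float:
        """Nominal recording span in seconds (first to last frame)."""
        if len(self) < 2:
            return 0.0
        return float(self.frame_index[-1] - self.frame_index[0]) / self.fps


@dataclass(frozen=True)
class RespirationRecord:
    """Opercular/oral movements counted for one fish over one minute."""

    fish_id: str
    genotype: str
    counts_per_minute: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise TrajectoryError(f"unknown genotype {self.genotype!r}")
        if self.counts_per_minute < 0 or int(self.counts_per_minute) != self.counts_per_minute:
            raise TrajectoryError("counts_per_minute must be a non-negative integer")


@dataclass(frozen=True)
class CohortMetadata:
    """Recording metadata shared by a trajectory file.

    Documented keys of the YAML metadata file: ``fps``, ``tank_width_cm``,
    ``tank_height_cm``, ``body_length_cm``, ``genotype``, ``age_group``.
    """

    fps: float = 25.0
    tank_width_cm: float = 18.0
    tank_height_cm: float = 24.0
    body_length_cm: float = 4.0
    genotype: str = "WT"
    age_group: str = "9mpf"


def read_metadata(path) -> CohortMetadata:
    """Read a flat key-value YAML metadata file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(CohortMetadata.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise TrajectoryError(f"unknown metadata keys {sorted(unknown)}; expected {sorted(known)}")
    return CohortMetadata(**raw)


def write_metadata(meta: CohortMetadata, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {k: getattr(meta, k) for k in CohortMetadata.__dataclass_fields__},
            fh,
            sort_keys=False,
        )


def read_trajectory(path, metadata: CohortMetadata, fish_id: str | None = None) -> Trajectory:
    """Read a ``frame,x,y`` CSV into a validated :class:`Trajectory`.

    Empty ``x``/``y`` fields are missing coordinates.  A malformed row
    raises :class:`TrajectoryError` naming the offending line.
    """
    frames: list[int] = []
    xs: list[float] = []
    ys: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:3]] != ["frame", "x", "y"]:
            raise TrajectoryError(f"{path}: expected header 'frame,x,y', got {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise TrajectoryError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            try:
                frames.append(int(row[0]))
                xs.append(float(row[1]) if row[1].strip() else np.nan)
                ys.append(float(row[2]) if row[2].strip() else np.nan)
            except ValueError as exc:
                raise TrajectoryError(f"{path}:{lineno}: malformed row {row!r} ({exc})") from None
    return Trajectory(
        fish_id=fish_id if fish_id is not None else _stem(path),
        genotype=metadata.genotype,
        age_group=metadata.age_group,
        fps=metadata.fps,
        body_length_cm=metadata.body_length_cm,
        tank_width_cm=metadata.tank_width_cm,
        tank_height_cm=metadata.tank_height_cm,
        frame_index=np.array(frames, dtype=np.int64),
        x_cm=np.array(xs),
        y_cm=np.array(ys),
    )


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def write_trajectory(traj: Trajectory, path) -> None:
    """Write the ``frame,x,y`` CSV contract (empty field = missing)."""
    df = pd.DataFrame({"frame": traj.frame_index, "x": traj.x_cm, "y": traj.y_cm})
    # repr-precision floats so that read(write(T)) round-trips exactly
    df.to_csv(path, index=False, float_format="%.17g", na_rep="")


@dataclass(frozen=True)
class GapSpan:
    """A maximal run of consecutive missing frames."""

    start_frame: int
    end_frame: int
    n_frames: int
    action: str  # "interpolated" | "excluded"


@dataclass(frozen=True)
class GapReport:
    spans: tuple[GapSpan, ...] = field(default_factory=tuple)

    @property
    def n_interpolated_frames(self) -> int:
        return sum(s.n_frames for s in self.spans if s.action == "interpolated")

    @property
    def n_excluded_frames(self) -> int:
        return sum(s.n_frames for s in self.spans if s.action == "excluded")


def fill_gaps(traj: Trajectory, max_gap_frames: int = 5) -> tuple[Trajectory, GapReport]:
    """Linearly interpolate short tracking gaps.

    Runs of at most ``max_gap_frames`` consecutive missing frames that are
    flanked by observed positions are filled by linear interpolation
    against the frame index; longer runs (and runs at either end of the
    recording, which have only one anchor) stay missing and are flagged
    ``excluded``.  Non-missing coordinates are never altered.
    """
    if max_gap_frames < 0:
        raise TrajectoryError("max_gap_frames must be >= 0")
    missing = traj.missing_mask
    if not missing.any():
        return traj, GapReport()
    x = traj.x_cm.copy()
    y = traj.y_cm.copy()
    idx = traj.frame_index
    spans: list[GapSpan] = []
    n = len(traj)
    i = 0
    while i < n:
        if not missing[i]:
            i += 1
            continue
        j = i
        while j < n and missing[j]:
            j += 1
        run = j - i  # rows in the run; frame-index span for interior runs
        interior = i > 0 and j < n
        if interior and run <= max_gap_frames:
            t0, t1 = idx[i - 1], idx[j]
            frac = (idx[i:j] - t0) / (t1 - t0)
            x[i:j] = x[i - 1] + frac * (x[j] - x[i - 1])
            y[i:j] = y[i - 1] + frac * (y[j] - y[i - 1])
            action = "interpolated"
        else:
            action = "excluded"
        spans.append(GapSpan(int(idx[i]), int(idx[j - 1]), run, action))
        i = j
    filled = replace(traj, x_cm=x, y_cm=y)
    return filled, GapReport(tuple(spans))


def read_respiration(path) -> list[RespirationRecord]:
    """Read a ``fish_id,genotype,counts_per_minute`` CSV."""
    df = pd.read_csv(path)
    return [
        RespirationRecord(str(r.fish_id), str(r.genotype), int(r.counts_per_minute))
        for r in df.itertuples()
    ]


def write_respiration(records: Sequence[RespirationRecord], path) -> None:
    pd.DataFrame(
        {
            "fish_id": [r.fish_id for r in records],
            "genotype": [r.genotype for r in records],
            "counts_per_minute": [r.counts_per_minute for r in records],
        }
    ).to_csv(path, index=False)
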