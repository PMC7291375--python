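"""Tracking-table I/O, arena/session/profile configuration and input validation.

The on-disk dialect is a plain CSV with columns
``t_s, nose_x, nose_y, center_x, center_y, tail_x, tail_y[, area_change_pct]``,
coordinates in cm in a corner-origin, y-up Cartesian frame. Pixel-to-cm
calibration is assumed to have happened upstream in the tracker.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

REQUIRED_COLUMNS = [
    "t_s",
    "nose_x",
    "nose_y",
    "center_x",
    "center_y",
    "tail_x",
    "tail_y",
]
AREA_COLUMN = "area_change_pct"

#: longest dropout (in samples) bridged by linear interpolation; longer gaps
#: split the session into independent segments for all state machines.
MAX_INTERP_GAP = 5

#: relative tolerance on the uniformity of the time step.
TIME_STEP_RTOL = 0.01

#: how far (cm) a coordinate may sit outside the arena before it is an error;
#: trackers routinely report the nose a little beyond the wall.
ARENA_TOLERANCE_CM = 2.0


class TrackingInputError(ValueError):
    """Raised when a tracking table fails validation."""


@dataclass(frozen=True)
class ArenaSpec:
    """Open-field floor geometry (cm), corner origin, y-up."""

    width: float = 80.0
    height: float = 80.0
    origin_convention: str = "corner_y_up"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("arena dimensions must be positive")


@dataclass(frozen=True)
class SessionInfo:
    """One animal-session: identity, group, lesion side and timing.

    ``day`` is the post-operative day; the pre-operative reference session is
    encoded as day -1 so days sort as plain integers. ``lesion_side`` is kept
    for sham animals too, purely for direction bookkeeping (ipsi/contra
    relabelling of CW/CCW counts).
    """

    animal_id: str
    group: str = "sham"
    lesion_side: str = "left"
    day: int = -1
    duration: float = 600.0
    sample_rate: float = 25.0

    def __post_init__(self) -> None:
        if self.group not in ("sham", "uvn"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.lesion_side not in ("left", "right"):
            raise ValueError(f"unknown lesion_side {self.lesion_side!r}")
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")


@dataclass(frozen=True)
class AnalysisProfile:
    """All thresholds of the 19-variable battery.

    Defaults are the tracker settings used throughout: hysteresis start/stop
    velocities for the movement state, silhouette area-change bands for the
    mobility states, the high-acceleration band with its minimum event
    duration, the nose-speed threshold defining a bobbing (cephalic
    nystagmus) event, and the two rotation-counter thresholds.
    """

    mdm_threshold: float = 0.7          # cm
    smoothing_window: int = 3           # samples, odd
    start_velocity: float = 2.00        # cm/s
    stop_velocity: float = 1.75         # cm/s
    mobility_high: float = 5.0          # % area change
    mobility_low: float = 1.0           # % area change
    accel_high: float = 50.0            # cm/s^2
    accel_min_duration: float = 0.20    # s
    bobbing_velocity: float = 100.0     # cm/s
    body_axis_rotation_threshold: float = 30.0   # deg
    arena_rotation_threshold: float = 50.0       # deg
    arena_rotation_min_distance: float = 2.0     # cm
    segment_mode: str = "all_data"      # {all_data, when_moving}
    filter_mode: str = "none"           # {none, mdm}
    #: apply the minimum-duration exclusion to low-acceleration events too
    #: (keeps counts off the sampling-noise floor); set False to exclude only
    #: high events.
    min_duration_on_low: bool = True

    def __post_init__(self) -> None:
        if self.start_velocity <= self.stop_velocity:
            raise ValueError("start_velocity must exceed stop_velocity")
        if not (self.mobility_high > self.mobility_low > 0):
            raise ValueError("require mobility_high > mobility_low > 0")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        for name in (
            "mdm_threshold",
            "accel_high",
            "accel_min_duration",
            "bobbing_velocity",
            "body_axis_rotation_threshold",
            "arena_rotation_threshold",
            "arena_rotation_min_distance",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.segment_mode not in ("all_data", "when_moving"):
            raise ValueError(f"unknown segment_mode {self.segment_mode!r}")
        if self.filter_mode not in ("none", "mdm"):
            raise ValueError(f"unknown filter_mode {self.filter_mode!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisProfile":
        """Load a profile from a YAML (or plain ``key: value``) config file.

        Keys mirror the field names; missing keys keep their defaults.
        """
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise TrackingInputError(
                f"unknown profile keys: {sorted(unknown)}"
            )
        return cls(**data)

    def replace(self, **kw) -> "AnalysisProfile":
        return dataclasses.replace(self, **kw)


@dataclass
class Trajectory:
    """Uniformly sampled three-point track plus silhouette area-change signal.

    ``mask`` is True where the sample is defined (tracked or bridged by
    short-gap interpolation). Long dropouts stay masked and split the session
    into independent segments; iterate them with :meth:`segments`.
    ``area_change`` is the percent change of the detected body silhouette
    between consecutive frames; NaN where unavailable (always at sample 0).
    """

    t: np.ndarray
    nose_xy: np.ndarray
    center_xy: np.ndarray
    tail_xy: np.ndarray
    area_change: np.ndarray | None
    mask: np.ndarray
    sample_rate: float
    #: samples that were missing in the source and bridged by interpolation
    interpolated: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        for arr, nm in (
            (self.nose_xy, "nose_xy"),
            (self.center_xy, "center_xy"),
            (self.tail_xy, "tail_xy"),
            (self.mask, "mask"),
        ):
            if len(arr) != n:
                raise ValueError(f"{nm} length {len(arr)} != t length {n}")
        if self.area_change is not None and len(self.area_change) != n:
            raise ValueError("area_change length mismatch")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        """Defined session duration in seconds (one dt per defined sample)."""
        return float(self.mask.sum()) * self.dt

    def segments(self) -> Iterator[slice]:
        """Yield slices of maximal contiguous runs of defined samples."""
        m = np.asarray(self.mask, dtype=bool)
        if not m.any():
            return
        idx = np.flatnonzero(m)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(idx) - 1]))
        for s, e in zip(starts, ends):
            yield slice(int(idx[s]), int(idx[e]) + 1)


def _infer_sample_rate(t: np.ndarray, rtol: float = TIME_STEP_RTOL) -> float:
    steps = np.diff(t)
    if len(steps) == 0:
        raise TrackingInputError("need at least two samples")
    med = float(np.median(steps))
    if med <= 0:
        raise TrackingInputError("time column must be strictly increasing")
    bad = np.flatnonzero(np.abs(steps - med) > rtol * med)
    if bad.size:
        i = int(bad[0])
        raise TrackingInputError(
            f"non-uniform sampling: step t[{i}]->t[{i + 1}] is "
            f"{steps[i]:.6g}s, expected {med:.6g}s (±{100 * rtol:.0f}%)"
        )
    return 1.0 / med


def _interpolate_short_gaps(
    xy: np.ndarray, missing: np.ndarray, max_gap: int
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly bridge missing runs of length <= max_gap between defined ends.

    Returns the filled coordinates and the mask of samples still missing.
    """
    xy = xy.copy()
    still = missing.copy()
    n = len(xy)
    i = 0
    while i < n:
        if not missing[i]:
            i += 1
            continue
        j = i
        while j < n and missing[j]:
            j += 1
        gap = j - i
        if gap <= max_gap and i > 0 and j < n:
            w = (np.arange(1, gap + 1) / (gap + 1))[:, None]
            xy[i:j] = (1 - w) * xy[i - 1] + w * xy[j]
            still[i:j] = False
        i = j
    return xy, still


def read_trajectory(
    path: str | Path,
    session: SessionInfo | None = None,
    arena: ArenaSpec | None = None,
    *,
    arena_tolerance: float = ARENA_TOLERANCE_CM,
) -> Trajectory:
    """Read and validate a tracking CSV into a :class:`Trajectory`.

    Time is re-based to start at 0 and the sample rate inferred from the time
    column (uniform within 1%). Rows with any missing coordinate are masked;
    gaps of at most ``MAX_INTERP_GAP`` samples are bridged linearly, longer
    gaps split the session.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TrackingInputError(
            f"missing required column(s): {', '.join(missing_cols)}"
        )
    t = df["t_s"].to_numpy(dtype=float)
    if np.isnan(t).any():
        raise TrackingInputError("time column contains missing values")
    sample_rate = _infer_sample_rate(t)
    t = t - t[0]

    pts = {}
    missing = np.zeros(len(df), dtype=bool)
    for name in ("nose", "center", "tail"):
        xy = df[[f"{name}_x", f"{name}_y"]].to_numpy(dtype=float)
        missing |= np.isnan(xy).any(axis=1)
        pts[name] = xy

    if arena is not None:
        lo = -arena_tolerance
        hi = np.array([arena.width, arena.height]) + arena_tolerance
        bad_rows: set[int] = set()
        for xy in pts.values():
            with np.errstate(invalid="ignore"):
                out = (xy < lo) | (xy > hi)
            bad_rows.update(np.flatnonzero(out.any(axis=1)).tolist())
        if bad_rows:
            rows = sorted(bad_rows)
            shown = ", ".join(map(str, rows[:10]))
            more = "" if len(rows) <= 10 else f" (+{len(rows) - 10} more)"
            raise TrackingInputError(
                f"coordinates outside arena (+{arena_tolerance} cm tolerance) "
                f"at rows: {shown}{more}"
            )

    for name in pts:
        pts[name], still = _interpolate_short_gaps(
            pts[name], missing & np.isnan(pts[name]).any(axis=1), MAX_INTERP_GAP
        )
    # a sample is defined only if every point is defined after bridging
    still_missing = np.zeros(len(df), dtype=bool)
    for name in pts:
        still_missing |= np.isnan(pts[name]).any(axis=1)
    mask = ~still_missing

    area = None
    if AREA_COLUMN in df.columns:
        area = df[AREA_COLUMN].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(area) < 0:
                raise TrackingInputError("area_change_pct must be >= 0")

    if session is not None:
        if abs(sample_rate - session.sample_rate) > TIME_STEP_RTOL * session.sample_rate:
            warnings.warn(
                f"inferred sample rate {sample_rate:.3f} Hz differs from "
                f"session metadata {session.sample_rate:.3f} Hz; using inferred",
                stacklevel=2,
            )

    return Trajectory(
        t=t,
        nose_xy=pts["nose"],
        center_xy=pts["center"],
        tail_xy=pts["tail"],
        area_change=area,
        mask=mask,
        sample_rate=sample_rate,
        interpolated=missing & mask,
    )


#: float format used for all CSV output; 12 significant digits round-trips
#: every quantity the battery produces to well below any threshold in use.
CSV_FLOAT_FORMAT = "%.12g"


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory in the tracking-CSV dialect (deterministic bytes)."""
    cols = {
        "t_s": traj.t,
        "nose_x": traj.nose_xy[:, 0],
        "nose_y": traj.nose_xy[:, 1],
        "center_x": traj.center_xy[:, 0],
        "center_y": traj.center_xy[:, 1],
        "tail_x": traj.tail_xy[:, 0],
        "tail_y": traj.tail_xy[:, 1],
    }
    if traj.area_change is not None:
        cols[AREA_COLUMN] = traj.area_change
    pd.DataFrame(cols).to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def write_metrics(rows, path: str | Path) -> None:
    """Write session metrics as a tidy one-row-per-session CSV.

    ``rows`` is a non-empty list of (SessionInfo, SessionMetrics) pairs or of
    SessionMetrics objects exposing ``to_row()``.
    """
    if not rows:
        raise ValueError("rows must be non-empty")
    records = []
    for item in rows:
        if isinstance(item, tuple):
            session, m = item
            rec = {
                "animal_id": session.animal_id,
                "group": session.group,
                "lesion_side": session.lesion_side,
                "day": session.day,
            }
        else:
            m, rec = item, {}
        rec.update(m.to_row())
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def read_metrics(path: str | Path) -> pd.DataFrame:
    """Read a metrics CSV written by :func:`write_metrics`."""
    return pd.read_csv(path)
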