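"""Rotation counting, ipsi/contralesional mapping, meander and body torsion.

Two rotation kinds are distinguished: body-axis rotation (the animal spins
around its own axis; heading of the center-to-nose vector, 30 deg tolerance)
and arena rotation (the animal travels in circles; heading of the
center-point path gated at 2 cm displacements, 50 deg tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .kinematics import FilteredTrack, ScalarSeries, turn_angles
from .states import IntervalSet


@dataclass(frozen=True)
class RotationCount:
    kind: str  # {body_axis, arena}
    cw: int = 0
    ccw: int = 0
    ipsilesional: int | None = None
    contralesional: int | None = None

    def __add__(self, other: "RotationCount") -> "RotationCount":
        if other.kind != self.kind:
            raise ValueError("cannot add rotation counts of different kinds")
        return RotationCount(self.kind, self.cw + other.cw, self.ccw + other.ccw)


@dataclass(frozen=True)
class PostureSummary:
    """Session posture statistics.

    ``mean_body_torsion`` is signed, positive toward the contralesional
    (intact) side; ``mean_absolute_meander`` is the mean |turn|/distance per
    step in deg/cm, with the aggregate ratio sum|turn|/sum(distance) kept as
    a secondary diagnostic.
    """

    mean_body_torsion: float
    mean_absolute_meander: float
    aggregate_meander: float = float("nan")


def count_rotations(h: ScalarSeries | np.ndarray, threshold: float,
                    kind: str = "arena", full_turn: float = 360.0) -> RotationCount:
    """Count full CW/CCW rotations of an unwrapped heading series.

    Accumulator semantics: signed heading increments are summed; excursions
    against the current direction are tolerated (subtracted from the
    accumulator) as long as their cumulative magnitude stays below
    ``threshold``. When an opposite excursion reaches the threshold the
    accumulator resets to that excursion, flipping direction. Each time the
    accumulated turn reaches a full circle one rotation is counted and a full
    circle is subtracted. CCW is the positive direction.
    """
    if not (0 < threshold < full_turn):
        raise ValueError("threshold must lie in (0, full_turn)")
    hv = h.v[h.mask] if isinstance(h, ScalarSeries) else np.asarray(h, float)
    hv = hv[~np.isnan(hv)]
    if len(hv) < 2:
        return RotationCount(kind)
    cw = ccw = 0
    direction = 0       # +1 CCW, -1 CW, 0 unresolved
    acc = 0.0           # signed accumulated turn since last reset/rotation
    peak = 0.0          # extremal progress in `direction` since excursion start
    for d in np.diff(hv):
        if d == 0:
            continue
        if direction == 0:
            direction = 1 if d > 0 else -1
            acc = d
            peak = direction * acc
        else:
            acc += d
            prog = direction * acc
            if prog > peak:
                peak = prog
            elif peak - prog >= threshold:
                # opposite excursion reached the tolerance: flip direction and
                # seed the accumulator with the excursion itself
                excursion = peak - prog
                direction = -direction
                acc = direction * excursion
                peak = excursion
        while direction != 0 and direction * acc >= full_turn:
            if direction > 0:
                ccw += 1
            else:
                cw += 1
            acc -= direction * full_turn
            peak -= full_turn
    return RotationCount(kind, cw=cw, ccw=ccw)


def count_rotations_in_segments(
    h: ScalarSeries, segments: IntervalSet, threshold: float, kind: str
) -> RotationCount:
    """Run the rotation counter independently on each moving segment.

    The accumulator does not carry across segment boundaries: turning done
    while the animal is stationary is not part of the "when moving" battery.
    """
    total = RotationCount(kind)
    for s, e in segments.intervals:
        sel = (h.t >= s) & (h.t < e) & h.mask
        total = total + count_rotations(h.v[sel], threshold, kind)
    return total


def map_direction(r: RotationCount, lesion_side: str) -> RotationCount:
    """Relabel CW/CCW counts as ipsi/contralesional given the lesion side.

    For a left lesion a CCW rotation is ipsilesional (and CW contralesional);
    a right lesion mirrors the mapping.
    """
    if lesion_side == "left":
        ipsi, contra = r.ccw, r.cw
    elif lesion_side == "right":
        ipsi, contra = r.cw, r.ccw
    else:
        raise ValueError(f"unknown lesion_side {lesion_side!r}")
    return replace(r, ipsilesional=ipsi, contralesional=contra)


def absolute_meander(
    track: FilteredTrack, segments: IntervalSet | None = None
) -> tuple[float, float]:
    """Absolute meander (deg/cm) of an MDM-filtered track.

    Per accepted step, meander is |turn angle at the step's start vertex|
    divided by the step's length; the primary statistic is the mean over all
    steps inside ``segments`` (or all steps when segments is None). The
    aggregate ratio sum|turn| / sum(distance) is returned alongside as a
    step-length-insensitive diagnostic. Both are NaN with fewer than three
    usable samples.
    """
    if len(track) < 3:
        return float("nan"), float("nan")
    turns = np.abs(turn_angles(track.xy))          # at vertices 1..m-2
    dists = track.step_distance[2:]                # step leaving each vertex
    if segments is not None:
        # a turn belongs to the battery if its vertex time is inside a
        # moving interval
        keep = segments.contains(track.t[1:-1])
        turns, dists = turns[keep], dists[keep]
    if len(turns) == 0:
        return float("nan"), float("nan")
    per_step = turns / dists
    agg = float(turns.sum() / dists.sum()) if dists.sum() > 0 else float("nan")
    return float(per_step.mean()), agg


def torsion_series(
    nose_xy: np.ndarray,
    center_xy: np.ndarray,
    tail_xy: np.ndarray,
    lesion_side: str,
) -> np.ndarray:
    """Signed body-bend angle per sample, positive toward the intact side.

    The geometric bend is the CCW angle from the tail-to-center vector to the
    center-to-nose vector, wrapped to (-180, 180]. With a left lesion the
    intact (contralesional) side is the animal's right, i.e. the clockwise
    side of the body axis, so the sign is flipped; a right lesion keeps the
    CCW-positive sign. Samples with a zero-length body vector are NaN.
    """
    a = np.asarray(center_xy, float) - np.asarray(tail_xy, float)
    b = np.asarray(nose_xy, float) - np.asarray(center_xy, float)
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]
    ang = np.degrees(np.arctan2(cross, dot))  # in (-180, 180]
    na = np.hypot(a[:, 0], a[:, 1])
    nb = np.hypot(b[:, 0], b[:, 1])
    ang[(na == 0) | (nb == 0)] = np.nan
    if lesion_side == "left":
        ang = -ang
    elif lesion_side != "right":
        raise ValueError(f"unknown lesion_side {lesion_side!r}")
    return ang


def body_torsion(
    nose_xy: np.ndarray,
    center_xy: np.ndarray,
    tail_xy: np.ndarray,
    lesion_side: str,
    sample_indices: np.ndarray | None = None,
) -> float:
    """Session mean body torsion (deg) over the given (e.g. MDM-accepted)
    samples; NaN if no sample has a well-defined body bend."""
    ang = torsion_series(nose_xy, center_xy, tail_xy, lesion_side)
    if sample_indices is not None:
        ang = ang[np.asarray(sample_indices, dtype=int)]
    ok = ~np.isnan(ang)
    if not ok.any():
        return float("nan")
    return float(ang[ok].mean())
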