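"""State and event detection on smoothed kinematic series.

Movement is a two-state hysteresis automaton on center-point speed; mobility
is a sample-wise three-way classification of the silhouette area-change
signal, fully independent of displacement; acceleration and bobbing events
are supra-threshold runs with (for accelerations) a minimum-duration
exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_config import AnalysisProfile
from .kinematics import ScalarSeries

UNDEFINED = 0
NOT_MOVING = 1
MOVING = 2


def _series_dt(t: np.ndarray) -> float:
    """Sample period of a series; 1.0 for a single sample (degenerate but
    keeps percentages well-defined)."""
    return float(np.median(np.diff(t))) if len(t) > 1 else 1.0


@dataclass
class IntervalSet:
    """Labeled contiguous state intervals [start_s, end_s) on the timeline."""

    label: str
    intervals: np.ndarray  # (n, 2) start/end seconds
    total_duration_s: float
    percent_of_session: float
    count: int

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float).reshape(-1, 2)

    def contains(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask of which of ``times`` fall inside any interval."""
        times = np.asarray(times, dtype=float)
        out = np.zeros(len(times), dtype=bool)
        for s, e in self.intervals:
            out |= (times >= s) & (times < e)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.label,
                "start_s": self.intervals[:, 0],
                "end_s": self.intervals[:, 1],
            }
        )


def intervals_from_labels(
    labels: np.ndarray,
    t: np.ndarray,
    dt: float,
    target: int | bool,
    name: str,
    session_duration: float,
) -> IntervalSet:
    """Collapse a per-sample label array into an IntervalSet for ``target``.

    Each sample owns [t_i, t_i + dt); adjacent samples with the target label
    merge into one interval.
    """
    labels = np.asarray(labels)
    hits = labels == target
    iv = []
    total = 0.0
    i = 0
    n = len(labels)
    while i < n:
        if not hits[i]:
            i += 1
            continue
        j = i
        while j < n and hits[j] and (j == i or np.isclose(t[j] - t[j - 1], dt)):
            j += 1
        iv.append((t[i], t[j - 1] + dt))
        total += (j - i) * dt
        i = j
    pct = 100.0 * total / session_duration if session_duration > 0 else np.nan
    return IntervalSet(name, np.asarray(iv).reshape(-1, 2), total, pct, len(iv))


def movement_labels(v: np.ndarray, start: float, stop: float) -> np.ndarray:
    """Per-sample movement labels from the start/stop hysteresis automaton.

    The state is undefined until the smoothed speed first exceeds ``start``
    (-> moving) or first drops below ``stop`` (-> not moving). Moving persists
    until speed < stop; not moving persists until speed > start. Undefined
    (NaN) speed samples keep the automaton undefined and force it to
    re-resolve afterwards.
    """
    if start <= stop:
        raise ValueError("start velocity must exceed stop velocity")
    v = np.asarray(v, dtype=float)
    out = np.full(len(v), UNDEFINED, dtype=np.int8)
    state = UNDEFINED
    for i, x in enumerate(v):
        if np.isnan(x):
            state = UNDEFINED
        elif state == MOVING:
            if x < stop:
                state = NOT_MOVING
        elif state == NOT_MOVING:
            if x > start:
                state = MOVING
        else:  # undefined: resolve on first crossing of either threshold
            if x > start:
                state = MOVING
            elif x < stop:
                state = NOT_MOVING
        out[i] = state
    return out


def movement_states(
    v: ScalarSeries, profile: AnalysisProfile
) -> tuple[IntervalSet, IntervalSet]:
    """Moving / not-moving interval sets from a smoothed speed series."""
    labels = movement_labels(v.v, profile.start_velocity, profile.stop_velocity)
    dt = _series_dt(v.t)
    dur = len(v) * dt
    moving = intervals_from_labels(labels, v.t, dt, MOVING, "moving", dur)
    not_moving = intervals_from_labels(
        labels, v.t, dt, NOT_MOVING, "not_moving", dur
    )
    return moving, not_moving


IMMOBILE, MOBILE, HIGHLY_MOBILE = 10, 11, 12


def mobility_labels(area: np.ndarray, low: float, high: float) -> np.ndarray:
    """Sample-wise mobility class of the (smoothed) area-change signal.

    > high -> highly mobile; in [low, high] -> mobile; < low -> immobile.
    The boundary values belong to "mobile". NaN -> undefined.
    """
    area = np.asarray(area, dtype=float)
    out = np.full(len(area), UNDEFINED, dtype=np.int8)
    ok = ~np.isnan(area)
    out[ok & (area > high)] = HIGHLY_MOBILE
    out[ok & (area >= low) & (area <= high)] = MOBILE
    out[ok & (area < low)] = IMMOBILE
    return out


def mobility_states(
    area_change: ScalarSeries, profile: AnalysisProfile
) -> tuple[IntervalSet, IntervalSet, IntervalSet, float]:
    """Immobile / mobile / highly-mobile interval sets and global mobility %.

    ``area_change`` must already be smoothed over the profile's window.
    Percentages are over defined samples, so the three classes partition
    100% exactly; global mobility is mobile% + highly_mobile%.
    """
    labels = mobility_labels(
        area_change.v, profile.mobility_low, profile.mobility_high
    )
    dt = _series_dt(area_change.t)
    dur = int((labels != UNDEFINED).sum()) * dt
    sets = [
        intervals_from_labels(labels, area_change.t, dt, code, name, dur)
        for code, name in (
            (IMMOBILE, "immobile"),
            (MOBILE, "mobile"),
            (HIGHLY_MOBILE, "highly_mobile"),
        )
    ]
    global_pct = sets[1].percent_of_session + sets[2].percent_of_session
    return sets[0], sets[1], sets[2], global_pct


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end_exclusive) index pairs."""
    mask = np.asarray(mask, dtype=bool)
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def _events_from_mask(
    mask: np.ndarray,
    t: np.ndarray,
    dt: float,
    min_duration: float,
    name: str,
    session_duration: float,
) -> IntervalSet:
    iv = []
    total = 0.0
    for i, j in _runs(mask):
        dur = (j - i) * dt
        if dur >= min_duration - 1e-12:
            iv.append((t[i], t[j - 1] + dt))
            total += dur
    pct = 100.0 * total / session_duration if session_duration > 0 else np.nan
    return IntervalSet(name, np.asarray(iv).reshape(-1, 2), total, pct, len(iv))


def acceleration_events(
    a: ScalarSeries, profile: AnalysisProfile
) -> tuple[IntervalSet, IntervalSet]:
    """High- and low-acceleration events from the signed acceleration series.

    A high event is a maximal run with a > accel_high lasting at least
    accel_min_duration; a low event is a maximal run with 0 < a <= accel_high
    (low acceleration still means speeding up; deceleration is summarized
    separately by the negative-acceleration mean). The minimum-duration
    exclusion is applied to low events too unless the profile disables it.
    """
    dt = _series_dt(a.t)
    dur = len(a) * dt
    # numerical floor: accelerations below ~1e-9 cm/s^2 are rounding dust
    # from differencing, not a low-acceleration state
    eps = 1e-9
    with np.errstate(invalid="ignore"):
        high_mask = a.v > profile.accel_high
        low_mask = (a.v > eps) & (a.v <= profile.accel_high)
    high = _events_from_mask(
        high_mask, a.t, dt, profile.accel_min_duration, "accel_high", dur
    )
    low_min = profile.accel_min_duration if profile.min_duration_on_low else 0.0
    low = _events_from_mask(low_mask, a.t, dt, low_min, "accel_low", dur)
    return high, low


def mean_signed_accel(a: ScalarSeries, sign: str) -> float:
    """Mean of the acceleration samples of one sign only (cm/s^2).

    NaN when no sample of the requested sign exists.
    """
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    vals = a.v[a.mask]
    sel = vals > 0 if sign == "positive" else vals < 0
    if not sel.any():
        return float("nan")
    return float(vals[sel].mean())


def bobbing_events(
    v_nose: ScalarSeries, profile: AnalysisProfile
) -> IntervalSet:
    """Bobbing (cephalic nystagmus) events: maximal runs of smoothed nose
    speed at or above the bobbing threshold; one event per run."""
    dt = _series_dt(v_nose.t)
    dur = len(v_nose) * dt
    with np.errstate(invalid="ignore"):
        mask = v_nose.v >= profile.bobbing_velocity
    return _events_from_mask(mask, v_nose.t, dt, 0.0, "bobbing", dur)
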