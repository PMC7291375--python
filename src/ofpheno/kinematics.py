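"""Point-track kinematics: smoothing, MDM filtering, velocity, acceleration
and heading series.

All per-step quantities (speed, acceleration, heading of a displacement) are
assigned to the later sample of the step; the first sample of a series is
undefined (NaN). Smoothing is a centered moving average so event timing
carries no phase lag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ScalarSeries:
    """A scalar signal on (a subset of) the session timeline.

    ``v`` is NaN where undefined; ``units`` is carried as metadata
    (cm, cm/s, cm/s2, deg). ``t`` may be a subset of the trajectory times for
    distance-gated headings.
    """

    t: np.ndarray
    v: np.ndarray
    units: str
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if len(self.t) != len(self.v):
            raise ValueError("t and v length mismatch")
        if self.mask is None:
            self.mask = ~np.isnan(self.v)
        self.mask = np.asarray(self.mask, dtype=bool)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def defined(self) -> np.ndarray:
        return self.v[self.mask]


@dataclass
class FilteredTrack:
    """A point track after minimal-distance-moved (MDM) filtering.

    Keeps only samples at least ``threshold`` cm from the last kept sample,
    suppressing tracker jitter. ``indices`` are positions in the source
    track; ``step_distance[j]`` is the hop onto accepted sample j (NaN at 0).
    """

    indices: np.ndarray
    t: np.ndarray
    xy: np.ndarray
    threshold: float

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def step_distance(self) -> np.ndarray:
        d = np.full(len(self.xy), np.nan)
        if len(self.xy) > 1:
            d[1:] = np.hypot(*np.diff(self.xy, axis=0).T)
        return d

    @property
    def total_distance(self) -> float:
        d = self.step_distance
        return float(np.nansum(d)) if len(d) > 1 else 0.0


def running_mean(values: np.ndarray | ScalarSeries, window: int):
    """Centered moving average over ``window`` samples.

    Edges use the available shorter window; NaN (undefined) samples are
    excluded from their windows rather than poisoning them. Window must be
    odd so the average is symmetric about the sample.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if isinstance(values, ScalarSeries):
        sm = running_mean(values.v, window)
        return ScalarSeries(values.t, sm, values.units)
    s = pd.Series(np.asarray(values, dtype=float))
    out = s.rolling(window, center=True, min_periods=1).mean().to_numpy()
    # all-NaN windows stay NaN (rolling already does this with min_periods=1)
    return out


def mdm_filter(xy: np.ndarray, t: np.ndarray, threshold: float) -> FilteredTrack:
    """Greedy minimal-distance-moved filter.

    A sample is accepted iff its Euclidean distance from the last accepted
    sample is at least ``threshold``; the first sample is always accepted.
    Threshold 0 accepts every sample.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    xy = np.asarray(xy, dtype=float)
    t = np.asarray(t, dtype=float)
    n = len(xy)
    if n == 0:
        return FilteredTrack(np.empty(0, int), t[:0], xy[:0], threshold)
    if threshold == 0:
        return FilteredTrack(np.arange(n), t, xy, threshold)
    kept = [0]
    lx, ly = xy[0]
    for i in range(1, n):
        if math.hypot(xy[i, 0] - lx, xy[i, 1] - ly) >= threshold:
            kept.append(i)
            lx, ly = xy[i]
    idx = np.asarray(kept, dtype=int)
    return FilteredTrack(idx, t[idx], xy[idx], threshold)


def velocity(
    xy: np.ndarray, t: np.ndarray, smoothing_window: int = 3
) -> ScalarSeries:
    """Scalar speed series of a point track (cm/s), smoothed.

    Per-step speed is Euclidean displacement over the step time, assigned to
    the later sample; sample 0 is undefined. The raw speeds are then averaged
    over ``smoothing_window`` samples (the tracker's "average interval").
    """
    xy = np.asarray(xy, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(xy) < 2:
        raise ValueError("need at least 2 samples")
    v = np.full(len(xy), np.nan)
    d = np.hypot(*np.diff(xy, axis=0).T)
    v[1:] = d / np.diff(t)
    sm = running_mean(v, smoothing_window)
    sm[np.isnan(v)] = np.nan  # smoothing must not invent undefined samples
    return ScalarSeries(t, sm, "cm/s")


def acceleration(v: ScalarSeries, smoothing_window: int = 3) -> ScalarSeries:
    """Signed rate of change of speed (cm/s^2), smoothed like the speed.

    The signed scalar derivative (not the vector-acceleration magnitude) is
    what splits into positive (speeding up) and negative (slowing down)
    components.
    """
    a = np.full(len(v), np.nan)
    dv = np.diff(v.v)
    dt = np.diff(v.t)
    a[1:] = dv / dt
    sm = running_mean(a, smoothing_window)
    sm[np.isnan(a)] = np.nan
    return ScalarSeries(v.t, sm, "cm/s2")


def _unwrap_deg(angles: np.ndarray) -> np.ndarray:
    return np.degrees(np.unwrap(np.radians(angles)))


def body_axis_heading(center_xy: np.ndarray, nose_xy: np.ndarray,
                      t: np.ndarray) -> ScalarSeries:
    """Heading of the body axis: direction of the center-to-nose vector.

    Degrees, CCW-positive, unwrapped so consecutive differences are the
    minimal signed turn. Samples with a degenerate (zero-length) body vector
    are undefined.
    """
    d = np.asarray(nose_xy, dtype=float) - np.asarray(center_xy, dtype=float)
    norm = np.hypot(d[:, 0], d[:, 1])
    ang = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    ok = norm > 0
    if ok.any():
        ang[ok] = _unwrap_deg(ang[ok])
    ang[~ok] = np.nan
    return ScalarSeries(np.asarray(t, dtype=float), ang, "deg", mask=ok)


def path_heading(
    xy: np.ndarray, t: np.ndarray, min_step: float = 0.0
) -> ScalarSeries:
    """Heading of the direction of travel of a point track.

    Displacements shorter than ``min_step`` produce no new heading sample:
    positions are first gated by a greedy minimum-distance rule (threshold
    ``min_step``), then each surviving displacement yields one heading sample
    at the time of its later endpoint. Unwrapped degrees, CCW-positive.
    """
    ft = mdm_filter(xy, t, min_step)
    if len(ft) < 2:
        return ScalarSeries(ft.t[:0], np.empty(0), "deg")
    steps = np.diff(ft.xy, axis=0)
    ang = np.degrees(np.arctan2(steps[:, 1], steps[:, 0]))
    return ScalarSeries(ft.t[1:], _unwrap_deg(ang), "deg")


def turn_angles(xy: np.ndarray) -> np.ndarray:
    """Signed turn (deg, CCW-positive, in (-180, 180]) at each interior vertex
    of a polyline; length len(xy) - 2."""
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 3:
        return np.empty(0)
    steps = np.diff(xy, axis=0)
    ang = np.degrees(np.arctan2(steps[:, 1], steps[:, 0]))
    d = np.diff(ang)
    return (d + 180.0) % 360.0 - 180.0
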