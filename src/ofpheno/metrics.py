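"""Assemble the 19-variable posturo-locomotor battery for one session and
aggregate cohorts into group x day summary tables.

Each variable is computed under the analysis profile its battery row
prescribes: the movement/mobility/acceleration states and the positive and
negative acceleration means run on unfiltered data; body torsion, head
velocity and bobbing run on MDM-filtered data over the whole session;
distance, body velocity, rotations and meander run on MDM-filtered data
restricted to the segments where the animal is moving.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kinematics as kin
from . import rotations_posture as rot
from . import states as st
from .io_config import AnalysisProfile, SessionInfo, Trajectory


@dataclass(frozen=True)
class ProfileSet:
    """The three analysis profiles of the battery, sharing one threshold set."""

    no_filter_all: AnalysisProfile
    mdm_all: AnalysisProfile
    mdm_moving: AnalysisProfile

    @classmethod
    def from_profile(cls, p: AnalysisProfile | None = None) -> "ProfileSet":
        p = p or AnalysisProfile()
        return cls(
            no_filter_all=p.replace(filter_mode="none", segment_mode="all_data"),
            mdm_all=p.replace(filter_mode="mdm", segment_mode="all_data"),
            mdm_moving=p.replace(filter_mode="mdm", segment_mode="when_moving"),
        )


@dataclass
class SessionMetrics:
    """One row of the battery: all 19 variables for one animal-session."""

    pct_not_moving: float = np.nan
    pct_highly_mobile: float = np.nan
    pct_mobile: float = np.nan
    pct_global_mobility: float = np.nan
    pct_immobile: float = np.nan
    freq_body_accel_high: float = np.nan
    freq_body_accel_low: float = np.nan
    freq_head_accel_high: float = np.nan
    freq_head_accel_low: float = np.nan
    mean_positive_accel: float = np.nan
    mean_negative_accel: float = np.nan
    mean_body_torsion: float = np.nan
    mean_head_velocity: float = np.nan
    max_head_velocity: float = np.nan
    freq_bobbing: float = np.nan
    total_distance: float = np.nan
    mean_body_velocity: float = np.nan
    max_body_velocity: float = np.nan
    freq_body_axis_rot_cw: float = np.nan
    freq_body_axis_rot_ccw: float = np.nan
    freq_body_axis_rot_ipsi: float = np.nan
    freq_body_axis_rot_contra: float = np.nan
    freq_arena_rot_cw: float = np.nan
    freq_arena_rot_ccw: float = np.nan
    freq_arena_rot_ipsi: float = np.nan
    freq_arena_rot_contra: float = np.nan
    mean_absolute_meander: float = np.nan
    aggregate_meander: float = np.nan  # diagnostic, not a battery row

    def to_row(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in dataclasses.fields(cls)]


#: battery row -> SessionMetrics field(s); 19 rows, exhaustive. Rows whose
#: measurement column pairs two statistics (mean and max, high and low
#: frequency) map to both fields.
TABLE_FIELDS: dict[str, tuple[str, ...]] = {
    "movement_duration_not_moving": ("pct_not_moving",),
    "mobility_duration_highly_mobile": ("pct_highly_mobile",),
    "mobility_duration_mobile": ("pct_mobile",),
    "mobility_global": ("pct_global_mobility",),
    "mobility_duration_immobile": ("pct_immobile",),
    "acceleration_state_body": ("freq_body_accel_high", "freq_body_accel_low"),
    "acceleration_state_head": ("freq_head_accel_high", "freq_head_accel_low"),
    "positive_acceleration_mean": ("mean_positive_accel",),
    "negative_acceleration_mean": ("mean_negative_accel",),
    "relative_body_angle_mean": ("mean_body_torsion",),
    "velocity_head": ("mean_head_velocity", "max_head_velocity"),
    "cephalic_nystagmus_frequency": ("freq_bobbing",),
    "distance_moved_total": ("total_distance",),
    "velocity_body": ("mean_body_velocity", "max_body_velocity"),
    "body_axis_rotation_cw": ("freq_body_axis_rot_cw", "freq_body_axis_rot_contra"),
    "body_axis_rotation_ccw": ("freq_body_axis_rot_ccw", "freq_body_axis_rot_ipsi"),
    "arena_rotation_cw": ("freq_arena_rot_cw", "freq_arena_rot_contra"),
    "arena_rotation_ccw": ("freq_arena_rot_ccw", "freq_arena_rot_ipsi"),
    "absolute_meander_mean": ("mean_absolute_meander",),
}

REFERENCE_SESSION_S = 600.0


def moving_segments(
    v_body: kin.ScalarSeries, profile: AnalysisProfile
) -> st.IntervalSet:
    """Moving intervals used to gate every "when moving" variable."""
    moving, _ = st.movement_states(v_body, profile)
    return moving


def _filtered_velocity(
    ft: kin.FilteredTrack, window: int
) -> kin.ScalarSeries | None:
    if len(ft) < 2:
        return None
    return kin.velocity(ft.xy, ft.t, window)


def compute_session(
    traj: Trajectory,
    session: SessionInfo,
    profiles: ProfileSet | AnalysisProfile | None = None,
) -> SessionMetrics:
    """Compute the full battery for one session.

    Long tracking dropouts split the session; every state machine and filter
    runs per contiguous segment and the results are pooled. Undefined inputs
    (e.g. a missing area-change signal) leave their variables NaN without
    failing the rest of the battery.
    """
    if profiles is None or isinstance(profiles, AnalysisProfile):
        profiles = ProfileSet.from_profile(profiles)
    p = profiles.no_filter_all
    w = p.smoothing_window
    dt = traj.dt

    m = SessionMetrics()
    total_defined = traj.duration
    if total_defined == 0:
        return m

    # pooled accumulators across segments
    dur_moving = dur_not_moving = 0.0
    dur_imm = dur_mob = dur_high = 0.0
    area_defined_dur = 0.0
    n_body_high = n_body_low = n_head_high = n_head_low = 0
    pos_sum = neg_sum = 0.0
    pos_n = neg_n = 0
    torsion_sum = 0.0
    torsion_n = 0
    head_v_sum = 0.0
    head_v_n = 0
    head_v_max = -np.inf
    n_bob = 0
    dist_total = 0.0
    body_v_sum = 0.0
    body_v_n = 0
    body_v_max = -np.inf
    body_rot = rot.RotationCount("body_axis")
    arena_rot = rot.RotationCount("arena")
    meander_vals: list[np.ndarray] = []
    meander_turn_sum = 0.0
    meander_dist_sum = 0.0

    for seg in traj.segments():
        t = traj.t[seg]
        center = traj.center_xy[seg]
        nose = traj.nose_xy[seg]
        tail = traj.tail_xy[seg]
        if len(t) < 2:
            continue

        # --- no filter, all data -------------------------------------------
        v_center = kin.velocity(center, t, w)
        moving, not_moving = st.movement_states(v_center, p)
        dur_moving += moving.total_duration_s
        dur_not_moving += not_moving.total_duration_s

        if traj.area_change is not None:
            area = kin.ScalarSeries(
                t, kin.running_mean(traj.area_change[seg], w), "%"
            )
            imm, mob, high, _ = st.mobility_states(area, p)
            dur_imm += imm.total_duration_s
            dur_mob += mob.total_duration_s
            dur_high += high.total_duration_s
            area_defined_dur += (
                imm.total_duration_s + mob.total_duration_s + high.total_duration_s
            )

        a_body = kin.acceleration(v_center, w)
        hi, lo = st.acceleration_events(a_body, p)
        n_body_high += hi.count
        n_body_low += lo.count
        v_nose_raw = kin.velocity(nose, t, w)
        a_head = kin.acceleration(v_nose_raw, w)
        hi, lo = st.acceleration_events(a_head, p)
        n_head_high += hi.count
        n_head_low += lo.count

        av = a_body.v[a_body.mask]
        pos = av[av > 0]
        neg = av[av < 0]
        pos_sum += pos.sum()
        pos_n += len(pos)
        neg_sum += neg.sum()
        neg_n += len(neg)

        # --- MDM, all data -------------------------------------------------
        ft_center = kin.mdm_filter(center, t, p.mdm_threshold)
        tors = rot.torsion_series(nose, center, tail, session.lesion_side)
        tors = tors[ft_center.indices]
        ok = ~np.isnan(tors)
        torsion_sum += tors[ok].sum()
        torsion_n += int(ok.sum())

        ft_nose = kin.mdm_filter(nose, t, p.mdm_threshold)
        v_head = _filtered_velocity(ft_nose, w)
        if v_head is not None:
            vals = v_head.v[v_head.mask]
            head_v_sum += vals.sum()
            head_v_n += len(vals)
            if len(vals):
                head_v_max = max(head_v_max, float(vals.max()))
            n_bob += st.bobbing_events(v_head, p).count

        # --- MDM, when moving ---------------------------------------------
        in_moving = moving.contains(ft_center.t)
        steps = ft_center.step_distance
        dist_total += float(np.nansum(steps[in_moving]))
        v_body = _filtered_velocity(ft_center, w)
        if v_body is not None:
            sel = in_moving & v_body.mask
            vals = v_body.v[sel]
            body_v_sum += vals.sum()
            body_v_n += len(vals)
            if len(vals):
                body_v_max = max(body_v_max, float(vals.max()))

        h_body = kin.body_axis_heading(center, nose, t)
        body_rot = body_rot + rot.count_rotations_in_segments(
            h_body, moving, p.body_axis_rotation_threshold, "body_axis"
        )
        h_path = kin.path_heading(center, t, p.arena_rotation_min_distance)
        arena_rot = arena_rot + rot.count_rotations_in_segments(
            h_path, moving, p.arena_rotation_threshold, "arena"
        )

        if len(ft_center) >= 3:
            turns = np.abs(kin.turn_angles(ft_center.xy))
            dists = ft_center.step_distance[2:]
            keep = moving.contains(ft_center.t[1:-1])
            if keep.any():
                meander_vals.append(turns[keep] / dists[keep])
                meander_turn_sum += turns[keep].sum()
                meander_dist_sum += dists[keep].sum()

    # --- pooled session values --------------------------------------------
    m.pct_not_moving = 100.0 * dur_not_moving / total_defined
    if traj.area_change is not None and area_defined_dur > 0:
        m.pct_immobile = 100.0 * dur_imm / area_defined_dur
        m.pct_mobile = 100.0 * dur_mob / area_defined_dur
        m.pct_highly_mobile = 100.0 * dur_high / area_defined_dur
        m.pct_global_mobility = m.pct_mobile + m.pct_highly_mobile

    scale = 1.0
    if abs(total_defined - REFERENCE_SESSION_S) > dt:
        scale = REFERENCE_SESSION_S / total_defined
        warnings.warn(
            f"session duration {total_defined:.1f}s != "
            f"{REFERENCE_SESSION_S:.0f}s; frequencies rescaled to a "
            "600-s equivalent",
            stacklevel=2,
        )
    m.freq_body_accel_high = n_body_high * scale
    m.freq_body_accel_low = n_body_low * scale
    m.freq_head_accel_high = n_head_high * scale
    m.freq_head_accel_low = n_head_low * scale
    m.freq_bobbing = n_bob * scale

    m.mean_positive_accel = pos_sum / pos_n if pos_n else np.nan
    m.mean_negative_accel = neg_sum / neg_n if neg_n else np.nan
    m.mean_body_torsion = torsion_sum / torsion_n if torsion_n else np.nan
    m.mean_head_velocity = head_v_sum / head_v_n if head_v_n else np.nan
    m.max_head_velocity = head_v_max if head_v_n else np.nan
    m.total_distance = dist_total
    m.mean_body_velocity = body_v_sum / body_v_n if body_v_n else np.nan
    m.max_body_velocity = body_v_max if body_v_n else np.nan

    body_mapped = rot.map_direction(body_rot, session.lesion_side)
    arena_mapped = rot.map_direction(arena_rot, session.lesion_side)
    m.freq_body_axis_rot_cw = body_mapped.cw * scale
    m.freq_body_axis_rot_ccw = body_mapped.ccw * scale
    m.freq_body_axis_rot_ipsi = body_mapped.ipsilesional * scale
    m.freq_body_axis_rot_contra = body_mapped.contralesional * scale
    m.freq_arena_rot_cw = arena_mapped.cw * scale
    m.freq_arena_rot_ccw = arena_mapped.ccw * scale
    m.freq_arena_rot_ipsi = arena_mapped.ipsilesional * scale
    m.freq_arena_rot_contra = arena_mapped.contralesional * scale

    if meander_vals:
        allvals = np.concatenate(meander_vals)
        m.mean_absolute_meander = float(allvals.mean())
        m.aggregate_meander = (
            meander_turn_sum / meander_dist_sum
            if meander_dist_sum > 0
            else np.nan
        )
    return m


def summarize_cohort(
    rows: list[tuple[SessionInfo, SessionMetrics]]
) -> pd.DataFrame:
    """Group x day cohort summary: mean and SEM per metric, long format.

    SEM is sample SD / sqrt(n); NaN for n = 1. Metrics undefined for a
    session are dropped from that cell's n.
    """
    if not rows:
        raise ValueError("need at least one session")
    records = []
    for session, m in rows:
        rec = {"group": session.group, "day": session.day}
        rec.update(m.to_row())
        records.append(rec)
    df = pd.DataFrame(records)
    metric_cols = SessionMetrics.field_names()
    long = df.melt(
        id_vars=["group", "day"],
        value_vars=metric_cols,
        var_name="metric",
        value_name="value",
    ).dropna(subset=["value"])
    out = (
        long.groupby(["group", "day", "metric"], sort=True)["value"]
        .agg(mean="mean", sem=lambda x: x.sem(ddof=1), n="count")
        .reset_index()
    )
    out.loc[out["n"] == 1, "sem"] = np.nan
    return out
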