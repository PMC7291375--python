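"""Synthetic open-field trajectories with the statistical structure of
tracked rodent sessions.

The center point alternates between rest and move bouts (a two-state Markov
process with exponential dwell times). While moving it performs a correlated
random walk: per-frame heading increments are Gaussian with variance
``heading_diffusion * dt`` plus a deterministic ``circling_bias * dt`` drift,
and per-frame speeds are gamma-distributed (right-skewed, so the session
maximum far exceeds the mean, as real tracks show). Walls reflect the
heading, with an optional bias that aligns the heading with the nearest wall.

The nose rides ahead of the center on the body axis, rotated by the body
torsion angle plus noise; the tail mirrors it behind. Bobbing (cephalic
nystagmus) events are Poisson-timed bursts during which the nose oscillates
laterally with a constant supra-threshold frame-to-frame speed while the
center point is unaffected — a stylized tracker signal reproducing the
head-versus-body velocity dissociation. The silhouette area-change signal is
a gain on body speed plus the nose's relative speed, plus noise, clipped at
zero.

Phase presets encode the study conditions: a sham/pre-op baseline, the acute
phase of a unilateral vestibular lesion (slow, long rests, tortuous paths,
ipsilesional torsion) and the compensated/overcompensated phase (fast,
ipsilesional circling, bobbing, contralesional torsion).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .io_config import ArenaSpec, Trajectory

BOBBING_EVENT_FRAMES = 6          # 0.24 s at 25 Hz, above the 0.20 s floor
BOBBING_MIN_SEPARATION_S = 2.0
SPEED_SHAPE = 6.0                 # gamma shape: right-skewed, max >> mean
TORSION_NOISE_DEG = 3.0
TORSION_NOISE_TAU_S = 8.0         # AR(1) time constant of the torsion wobble
REST_JITTER_CM = 0.02             # tracker noise while resting, well under MDM
WALL_MARGIN_CM = 4.0
MAX_BODY_TURN_RATE = 300.0        # deg/s the body axis can actually turn


@dataclass(frozen=True)
class SimSpec:
    """Generator parameters for one behavioral phase."""

    phase: str = "sham"
    seed: int = 0
    duration: float = 600.0           # s
    sample_rate: float = 25.0         # Hz
    mean_move_speed: float = 15.0     # cm/s while in the move state
    rest_rate: float = 0.06           # per-s rate of leaving move (entering rest)
    move_rate: float = 0.25           # per-s rate of leaving rest (entering move)
    heading_diffusion: float = 60.0   # deg^2/s
    circling_bias: float = 0.0        # deg/s, CCW-positive
    bobbing_rate: float = 0.0         # events per 600 s
    bobbing_peak_speed: float = 160.0 # cm/s, must exceed the 100 cm/s threshold
    torsion_mean: float = 0.0         # deg, positive toward contralesional side
    body_length: float = 20.0         # cm nose-to-tail
    area_change_gain: float = 0.4     # % per cm/s of body + relative nose speed
    area_change_noise: float = 0.25   # % additive noise SD
    wall_following_strength: float = 0.5
    lesion_side: str = "left"

    def __post_init__(self) -> None:
        for name in ("rest_rate", "move_rate", "bobbing_rate",
                     "heading_diffusion", "area_change_gain",
                     "area_change_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        if self.bobbing_rate > 0 and self.bobbing_peak_speed <= 100.0:
            raise ValueError("bobbing_peak_speed must exceed 100 cm/s")
        if self.mean_move_speed < 0 or self.body_length <= 0:
            raise ValueError("invalid speed or body length")
        if self.lesion_side not in ("left", "right"):
            raise ValueError(f"unknown lesion_side {self.lesion_side!r}")

    def replace(self, **kw) -> "SimSpec":
        return dataclasses.replace(self, **kw)


#: Phase presets. Speeds and rest fractions follow the cohort kinetics the
#: battery is meant to resolve: the acute lesion phase is slow with long
#: rests, high path tortuosity and the body bent toward the lesioned side;
#: the compensated phase is faster than baseline with ipsilesional circling,
#: ~25 bobbing bursts per 10 min and the body bent toward the intact side.
_PRESETS: dict[str, dict] = {
    "sham": dict(
        mean_move_speed=16.0, rest_rate=0.06, move_rate=0.25,
        heading_diffusion=60.0, circling_bias=0.0, bobbing_rate=0.0,
        torsion_mean=0.0,
    ),
    "acute": dict(
        mean_move_speed=8.0, rest_rate=0.20, move_rate=0.09,
        heading_diffusion=600.0, circling_bias=0.0, bobbing_rate=0.0,
        torsion_mean=-6.0,
    ),
    "compensated": dict(
        mean_move_speed=24.0, rest_rate=0.05, move_rate=0.35,
        heading_diffusion=60.0, circling_bias=12.0, bobbing_rate=25.0,
        torsion_mean=5.0,
    ),
}
_PRESETS["preop"] = dict(_PRESETS["sham"])


def phase_preset(phase: str, *, seed: int = 0,
                 lesion_side: str = "left", **overrides) -> SimSpec:
    """Parameter set for a named behavioral phase.

    ``circling_bias`` and ``torsion_mean`` in the presets are expressed in
    the ipsi/contralesional convention and converted to the geometric
    CW/CCW frame for the requested lesion side: with a left lesion the
    ipsilesional direction is CCW (positive bias) and the contralesional
    side of the body axis is the clockwise one.
    """
    if phase not in _PRESETS:
        raise ValueError(
            f"unknown phase {phase!r}; expected one of {sorted(_PRESETS)}"
        )
    params = dict(_PRESETS[phase])
    if lesion_side == "right":
        # ipsilesional circling flips to CW for a right lesion
        params["circling_bias"] = -params["circling_bias"]
    params.update(overrides)
    return SimSpec(phase=phase, seed=seed, lesion_side=lesion_side, **params)


def _reflect(pos: float, lo: float, hi: float) -> float:
    while pos < lo or pos > hi:
        if pos < lo:
            pos = 2 * lo - pos
        if pos > hi:
            pos = 2 * hi - pos
    return pos


def _bobbing_starts(rng: np.random.Generator, n_frames: int, rate: float,
                    duration: float, dt: float) -> np.ndarray:
    """Poisson number of event-start frames with a minimum separation."""
    lam = rate * duration / 600.0
    n = rng.poisson(lam)
    if n == 0:
        return np.empty(0, dtype=int)
    sep = int(BOBBING_MIN_SEPARATION_S / dt)
    usable = n_frames - BOBBING_EVENT_FRAMES - sep
    starts: list[int] = []
    tries = 0
    while len(starts) < n and tries < 10000:
        c = int(rng.integers(sep, usable))
        if all(abs(c - s) >= sep for s in starts):
            starts.append(c)
        tries += 1
    return np.sort(np.asarray(starts, dtype=int))


def simulate(spec: SimSpec, arena: ArenaSpec | None = None) -> Trajectory:
    """Generate one session trajectory. Identical spec -> identical output."""
    arena = arena or ArenaSpec()
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.sample_rate
    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) * dt

    # rest/move bout process
    moving = np.zeros(n, dtype=bool)
    if spec.move_rate > 0:
        p_move = spec.move_rate / (spec.move_rate + max(spec.rest_rate, 1e-12))
        state = bool(rng.random() < p_move)
        p_stop = 1.0 - np.exp(-spec.rest_rate * dt)
        p_go = 1.0 - np.exp(-spec.move_rate * dt)
        for i in range(n):
            moving[i] = state
            if state and rng.random() < p_stop:
                state = False
            elif not state and rng.random() < p_go:
                state = True

    # correlated random walk of the center point; the center's reflective
    # bounds are inset by half the body length so the nose and tail always
    # stay inside the physical arena
    half = spec.body_length / 2.0
    lo = np.array([half, half])
    hi = np.array([arena.width - half, arena.height - half])
    center = np.empty((n, 2))
    heading = np.empty(n)
    center[0] = (arena.width / 2.0, arena.height / 2.0)
    heading[0] = rng.uniform(0.0, 360.0)
    sigma_h = np.sqrt(spec.heading_diffusion * dt)
    scale = spec.mean_move_speed / SPEED_SHAPE if spec.mean_move_speed else 0.0
    speeds = np.where(
        moving,
        rng.gamma(SPEED_SHAPE, scale if scale > 0 else 1.0, size=n)
        if scale > 0
        else 0.0,
        0.0,
    )
    jitter = rng.normal(0.0, REST_JITTER_CM, size=(n, 2))
    dh = spec.circling_bias * dt + rng.normal(0.0, sigma_h, size=n)

    margin = half + WALL_MARGIN_CM
    for i in range(1, n):
        h = heading[i - 1] + (dh[i] if moving[i] else 0.0)
        if moving[i] and spec.wall_following_strength > 0:
            x, y = center[i - 1]
            walls = []  # tangent headings of nearby walls
            if y < margin:
                walls += [0.0, 180.0]
            if y > arena.height - margin:
                walls += [0.0, 180.0]
            if x < margin:
                walls += [90.0, 270.0]
            if x > arena.width - margin:
                walls += [90.0, 270.0]
            if walls:
                # align with whichever wall tangent needs the smallest turn;
                # chirality-neutral, so it adds no net rotation of its own
                deltas = [(w - h + 180.0) % 360.0 - 180.0 for w in walls]
                delta = min(deltas, key=abs)
                h += spec.wall_following_strength * delta * dt * 5.0
        step = speeds[i] * dt
        hx = np.radians(h)
        x = center[i - 1, 0] + step * np.cos(hx)
        y = center[i - 1, 1] + step * np.sin(hx)
        if not moving[i]:
            x = center[i - 1, 0] + jitter[i, 0]
            y = center[i - 1, 1] + jitter[i, 1]
        if x < lo[0] or x > hi[0] or y < lo[1] or y > hi[1]:
            x = _reflect(x, lo[0], hi[0])
            y = _reflect(y, lo[1], hi[1])
            # reflect the heading off whichever wall was hit
            h = np.degrees(
                np.arctan2(y - center[i - 1, 1], x - center[i - 1, 0])
            )
        center[i] = (x, y)
        heading[i] = h

    # nose and tail on the body axis; torsion bends the nose toward the
    # contralesional side by `torsion_mean` (sign convention handled here).
    # The wobble around the mean is AR(1) with a seconds-scale time constant:
    # a real head swings slowly relative to the frame rate, and white noise
    # here would masquerade as nose motion in the area-change signal.
    rho = np.exp(-dt / TORSION_NOISE_TAU_S)
    innov = rng.normal(0.0, TORSION_NOISE_DEG * np.sqrt(1 - rho**2), size=n)
    wobble = np.empty(n)
    wobble[0] = rng.normal(0.0, TORSION_NOISE_DEG)
    for i in range(1, n):
        wobble[i] = rho * wobble[i - 1] + innov[i]
    geom_sign = -1.0 if spec.lesion_side == "left" else 1.0
    torsion_geom = geom_sign * (spec.torsion_mean + wobble)

    # the body axis follows the movement heading at a bounded turn rate:
    # wall bounces reverse the heading within one frame, but a real body
    # swings around over a few hundred ms, so an uncapped axis would throw
    # nose-speed spikes indistinguishable from bobbing
    max_step = MAX_BODY_TURN_RATE * dt
    body_axis = np.empty(n)
    body_axis[0] = heading[0]
    for i in range(1, n):
        delta = (heading[i] - body_axis[i - 1] + 180.0) % 360.0 - 180.0
        body_axis[i] = body_axis[i - 1] + np.clip(delta, -max_step, max_step)
    ax = np.radians(body_axis)
    bend = np.radians(body_axis + torsion_geom)
    nose = center + half * np.column_stack((np.cos(bend), np.sin(bend)))
    tail = center - half * np.column_stack((np.cos(ax), np.sin(ax)))

    # bobbing bursts: lateral nose oscillation at constant per-frame speed
    nose_extra = np.zeros(n)
    if spec.bobbing_rate > 0:
        amp = spec.bobbing_peak_speed * dt / 2.0
        for s in _bobbing_starts(rng, n, spec.bobbing_rate, spec.duration, dt):
            for k in range(BOBBING_EVENT_FRAMES):
                nose_extra[s + k] = amp if k % 2 else -amp
    perp = np.column_stack((-np.sin(ax), np.cos(ax)))
    nose = nose + nose_extra[:, None] * perp
    # the center's inset bounds keep the body inside; bobbing sweeps may
    # still poke the nose marginally past a wall, so clamp those only
    np.clip(nose[:, 0], 0.0, arena.width, out=nose[:, 0])
    np.clip(nose[:, 1], 0.0, arena.height, out=nose[:, 1])

    # silhouette area-change signal
    body_speed = np.zeros(n)
    body_speed[1:] = np.hypot(*np.diff(center, axis=0).T) / dt
    rel_nose = np.zeros(n)
    rel = (nose - center) - np.vstack(([0, 0], (nose - center)[:-1]))
    rel_nose[1:] = np.hypot(rel[1:, 0], rel[1:, 1]) / dt
    area = spec.area_change_gain * (body_speed + rel_nose) + rng.normal(
        0.0, spec.area_change_noise, size=n
    )
    area = np.clip(area, 0.0, None)
    area[0] = np.nan

    return Trajectory(
        t=t,
        nose_xy=nose,
        center_xy=center,
        tail_xy=tail,
        area_change=area,
        mask=np.ones(n, dtype=bool),
        sample_rate=spec.sample_rate,
    )
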