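# Methods

## Scope and data model

`ofpheno` computes a 19-variable posturo-locomotor battery from open-field
video-tracking exports: per-frame positions (cm) of three body points —
nose, center (body centroid) and tail base — plus a per-frame percent
change of the detected body silhouette ("area change"). The arena is a
square open field (80 × 80 cm floor by default) in a corner-origin, y-up
Cartesian frame; pixel-to-cm calibration is assumed upstream. Sessions are
10 min at 25 Hz by default; the sample rate is inferred from the time
column and must be uniform within 1%.

The battery exists to quantify the posturo-locomotor syndrome of a
unilateral vestibular lesion and its compensation over time: an acute phase
(roughly the first post-lesion week) with collapsed locomotion, high path
tortuosity and an ipsilesional body bend, followed by a compensated phase
with locomotor overshoot, ipsilesional circling, cephalic nystagmus
("bobbing") and a contralesional body bend.

## The battery

Three analysis profiles share one threshold set and differ only in
filtering and segmentation:

1. **No filter, all data** — movement and mobility states, acceleration
   states, positive/negative acceleration means.
2. **MDM, all data** — body torsion, head (nose) velocity, bobbing.
3. **MDM, when moving** — distance, body velocity, rotations, meander.

**MDM (minimal distance moved) filter.** Greedy rule: a sample is accepted
iff it lies at least 0.7 cm from the last accepted sample; the first sample
is always accepted. This suppresses tracker jitter; with threshold 0 it is
the identity. Whether the commercial tracker's MDM resets on direction
change is undocumented; the greedy distance rule is normative here and is
oracle-tested.

**Smoothing.** All velocity and acceleration series are centered moving
averages over 3 samples (edges use the available shorter window; undefined
samples are excluded from their windows but never invented: a structurally
undefined sample — e.g. the first, which has no step — stays undefined
after smoothing). A centered window was chosen because it adds no phase lag
to event timing; the alignment is not otherwise constrained.

**Velocity and acceleration.** Per-step speed is Euclidean displacement
over the step time, assigned to the later sample. Acceleration is the
signed derivative of scalar speed — not the vector-acceleration magnitude —
because the battery's positive/negative split (speeding up vs slowing
down) is only meaningful for a signed scalar. A numerical floor of
1e-9 cm/s² separates "zero" from differencing dust when classifying
low-acceleration states.

**Movement (hysteresis).** Two-threshold automaton on the smoothed
center-point speed: undefined until the speed first exceeds 2.00 cm/s
(→ moving) or first drops below 1.75 cm/s (→ not moving); moving persists
until speed < 1.75, not moving until speed > 2.00. Comparisons are strict,
so speed born inside the band stays undefined. Undefined samples occur only
as a prefix or around masked dropouts; percentages are over the full
defined session, with undefined as its own (usually one-sample) category.

**Mobility.** Sample-wise classification of the smoothed area-change
signal: > 5% highly mobile, < 1% immobile, otherwise mobile (the boundary
values 1% and 5% are assigned to "mobile"; the band is ambiguous at its
endpoints and a closed interval is the simplest consistent choice). Global
mobility = mobile% + highly mobile%. Mobility is fully independent of
displacement; when the area-change column is absent the four mobility
variables are reported undefined (NaN), never zero, and the rest of the
battery still computes.

**Acceleration events.** A high event is a maximal run with a > 50 cm/s²
lasting at least 0.20 s; a low event is a maximal run with 0 < a ≤ 50
cm/s². Low events still mean speeding up — deceleration is summarized
separately by the negative-acceleration mean. The minimum-duration
exclusion is stated only for high events in the source settings, but is
applied to both by default (configurable via `min_duration_on_low`):
without it, low-event counts explode at the sampling-noise floor.

**Bobbing (cephalic nystagmus).** One event per maximal run of smoothed
MDM-filtered nose speed ≥ 100 cm/s; events (runs) are counted, not
samples.

**Rotations.** Two kinds: body-axis rotation (spinning in place; heading of
the center→nose vector, threshold 30°) and arena rotation (circling travel;
heading of the center-point path gated at 2 cm displacements, threshold
50°). Headings are unwrapped so consecutive differences are minimal signed
turns. The counter sums signed increments; excursions against the current
direction are tolerated — subtracted from the accumulator — while their
cumulative magnitude stays below the threshold; an excursion reaching the
threshold resets the accumulator to that excursion (direction flips). Each
±360° of accumulated turn counts one CCW/CW rotation. The proprietary
semantics of the tracker's "rotation threshold" are unknown; this
tolerated-counter-rotation reading is normative for this package and is
verified against an independent extremum-tracking reimplementation on
randomized heading walks. Both rotation kinds are counted only within
moving segments, and the accumulator does not carry across segment
boundaries. CCW/CW counts are relabeled ipsi/contralesional by lesion side:
left lesion → CCW is ipsilesional; right lesion mirrors.

**Meander.** Per accepted MDM step inside moving segments, |turn angle at
the vertex| / length of the step leaving it, in deg/cm; the session value
is the mean over steps. The per-step mean is the primary statistic
(matching the battery's "mean" measurement); the aggregate ratio
Σ|turn|/Σdistance is reported alongside (`aggregate_meander`) because the
per-step mean is step-length sensitive.

**Body torsion.** Signed angle from the tail→center vector to the
center→nose vector, wrapped to (−180°, 180°], averaged over MDM-accepted
samples. Sign is anchored to the lesion: positive means the nose deviates
toward the contralesional (intact) side for either lesion side. Samples
with a zero-length body vector are skipped.

**Session assembly.** Each variable is computed under exactly the profile
its battery row prescribes. Tracking dropouts of ≤ 5 samples are bridged
linearly (flagged in `Trajectory.interpolated`); longer gaps split the
session into independent segments for every state machine and filter —
this prevents spurious velocity spikes across dropouts. Event frequencies
are raw counts per 10-min session (the magnitudes of the source kinetics
imply counts per session, not per minute); sessions of other durations are
linearly rescaled to a 600-s equivalent with a warning. Maximum velocities
are taken after smoothing, since raw per-frame maxima are dominated by
tracker noise. Cohort summaries report mean and SEM (sample SD/√n, NaN for
n = 1) per group × day cell in a long table; inferential statistics
(RM-ANOVA etc.) are deliberately out of scope — the tidy CSV is the
hand-off point.

## Synthetic sessions

No raw tracks are publicly deposited for this paradigm, so the package
ships a generator that emulates the statistical structure the battery
assumes, making every metric testable end to end.

The center point alternates between rest and move bouts (two-state Markov
process; `move_rate` and `rest_rate` are the per-second rates of entering
and leaving the move state). While moving it performs a correlated random
walk: per-frame heading increments are Gaussian with variance
`heading_diffusion·dt` plus a deterministic `circling_bias·dt`; per-frame
speeds are gamma-distributed (shape 6) with mean `mean_move_speed`, so the
session maximum sits well above the mean. At rest the center jitters with
0.02 cm tracker noise. The center's reflective bounds are inset by half the
body length so nose and tail always stay inside the arena; near walls an
optional wall-following term aligns the heading with the nearest wall
tangent (choosing the tangent needing the smallest turn, which is
chirality-neutral and adds no net rotation of its own).

The body axis follows the movement heading at a bounded turn rate
(300°/s): wall bounces reverse the heading within one frame, and an
uncapped axis would throw nose-speed spikes indistinguishable from
bobbing. The nose rides half a body length ahead of the axis, rotated by
the torsion angle (mean `torsion_mean` in the contralesional-positive
convention, plus an AR(1) wobble of 3° SD with an 8-s time constant — a
real head swings slowly relative to the frame rate, and white wobble would
masquerade as nose motion in the area-change signal). The tail mirrors the
nose behind the center.

Bobbing events are Poisson-timed (`bobbing_rate` per 600 s, ≥ 2 s apart);
during an event (0.24 s) the nose oscillates laterally with a constant
frame-to-frame speed of `bobbing_peak_speed` (default 160 cm/s) while the
center is unaffected. This is a stylized tracker signal, not a
biomechanical head sweep; it reproduces the head-versus-body velocity
dissociation (head velocity spikes with an unimpaired body). The
area-change signal is `gain·(body speed + nose relative speed) + noise`,
clipped at zero, with the first sample undefined — so immobility tracks
rest bouts and high mobility tracks locomotion.

### Phase presets

| parameter | sham/preop | acute | compensated |
|---|---|---|---|
| mean move speed (cm/s) | 16 | 8 | 24 |
| rest rate / move rate (s⁻¹) | 0.06 / 0.25 | 0.20 / 0.09 | 0.05 / 0.35 |
| heading diffusion (deg²/s) | 60 | 600 | 60 |
| circling bias (deg/s, ipsi) | 0 | 0 | 12 |
| bobbing rate (per 600 s) | 0 | 0 | 25 |
| torsion mean (deg) | 0 | −6 (ipsilesional) | +5 (contralesional) |

The presets were designed against the published cohort kinetics as
calibration anchors — acute-day-1 immobility near 60%, collapsed distance
and velocity; compensated-phase bobbing near 25 events/10 min, ipsilesional
arena-rotation excess, contralesional torsion of a few degrees — but those
live-animal means are anchors for preset design, not test oracles: the
presets are this package's own model, and the tests assert closed forms,
conservation identities, parameter recovery and qualitative orderings
instead.

### What the generator does and does not emulate

It reproduces bounded exploration, bout structure, phase-dependent speed
and its dissociations, circling chirality, torsion, bobbing and an
area-change channel consistent with its kinematics. It does not model gait,
thigmotaxis statistics, rearing/grooming, tracker identity swaps, lens
distortion or segmentation noise beyond Gaussian jitter. Passing tests
therefore show that the analysis correctly measures trajectories with the
assumed statistical structure — not that the presets are a quantitative
model of any real cohort.

## Numerical and validation choices

- Closed-form oracle: a CCW circle (r = 10 cm, v = 15 cm/s, nose tangent,
  600 s) has mean body velocity 15 cm/s (chord error < 0.1%), meander
  180/(πr) ≈ 5.73 deg/cm, and ⌊9000/2πr⌋ = 143 arena = body-axis CCW
  rotations.
- Parameter recovery runs on always-moving sessions in a 400 × 400 cm
  arena so the correlated random walk is not perturbed by walls; in the
  80-cm field a circling radius of v/ω routinely exceeds the arena and the
  closed form `bias·T/360` no longer applies.
- The battery's mean body velocity is sampled at MDM-accepted samples,
  which over-weights fast stretches (acceptance happens sooner when the
  animal is fast); with the shape-6 speed law the bias is ≈ +5–8%, within
  the 10% recovery band and visible in the recovery numbers.
- Problem sizes used in the validation suites: 1000 random trajectories of
  200–2000 samples for operator-oracle equivalence, 20 seeds × 600 s for
  parameter recovery, 5 seeds per phase for ordering — sizes at which the
  checked statistics are stable while the full suite runs in about a
  minute.
- Determinism: one `numpy` Generator seeded from `SimSpec.seed` drives all
  randomness with a fixed draw order; CSVs are written with a fixed
  `%.12g` float format, so identical seeds give bit-identical files.

## Known limitations

- The rotation-counter and MDM semantics are this package's explicit
  definitions of underspecified proprietary tracker behavior; absolute
  counts may differ from the commercial implementation even where the
  qualitative kinetics agree.
- The area-change channel is a kinematic surrogate; real silhouette
  dynamics (postural changes at rest, grooming) can dissociate mobility
  from movement in ways the generator does not produce.
- Frequencies from sessions shorter than ~1 min rescale to 600-s
  equivalents with large variance; the rescaling warns but does not refuse.
- Meander's per-step mean diverges on near-zero steps; MDM gating bounds
  steps below by the 0.7 cm threshold, so the statistic is only meaningful
  on filtered tracks.
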