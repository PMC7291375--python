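# ofpheno — open-field posturo-locomotor phenotyping

`ofpheno` quantifies the posturo-locomotor behavior of a rodent exploring a
square open field (80 × 80 cm), starting from video-tracker exports: the
per-frame positions of three body points (nose, body center, tail base) and
a per-frame percent change of the detected body silhouette. It computes a
19-variable battery designed to resolve the behavioral syndrome of a
unilateral vestibular lesion and its compensation — and ships a synthetic
trajectory generator for sham, acute-lesion and compensated phases, so the
whole analysis is buildable and testable without commercial tracking
software or animal data.

It is aimed at behavioral and vestibular physiologists who have (or want to
emulate) point-tracking exports and need transparent, reproducible
definitions of the derived variables.

## The battery

From a track $(x_t, y_t)$ sampled at rate $f$ (default 25 Hz), with all
velocity/acceleration series smoothed by a centered 3-sample running mean:

- **Movement** — hysteresis automaton on center-point speed $v$: moving
  when $v > 2.00$ cm/s, not moving when $v < 1.75$ cm/s, state held in
  between; reported as % time not moving.
- **Mobility** — silhouette area change $A_t$ (%): immobile $A < 1$,
  mobile $1 \le A \le 5$, highly mobile $A > 5$; global mobility is
  mobile + highly mobile. Fully independent of displacement.
- **Acceleration** — signed $\dot v$; high events $\dot v > 50$ cm/s² of
  ≥ 0.20 s, low events $0 < \dot v \le 50$; plus means of the positive and
  negative samples separately, for body (center) and head (nose).
- **MDM filter** — greedy minimal-distance-moved smoothing: keep a sample
  only if it is ≥ 0.7 cm from the last kept sample.
- **Distance, body/head velocity** (mean and max), **bobbing** (cephalic
  nystagmus: events of nose speed ≥ 100 cm/s), computed on MDM-filtered
  tracks; distance/velocity restricted to moving segments.
- **Rotations** — body-axis (center→nose heading, 30° tolerance) and arena
  (path heading gated at 2 cm, 50° tolerance) full-turn counts, CW/CCW,
  relabeled ipsi/contralesional by lesion side (left lesion: CCW is
  ipsilesional).
- **Meander** — mean |turn angle|/step distance (deg/cm) of the filtered
  moving track: path tortuosity.
- **Body torsion** — signed bend between tail→center and center→nose
  vectors, positive toward the intact side.

Definitions, sign conventions and edge rules are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate a compensated-phase session (left lesion) and compute its battery:

```python
from ofpheno import SessionInfo, compute_session, phase_preset, simulate

spec = phase_preset("compensated", seed=7, lesion_side="left")
traj = simulate(spec)
session = SessionInfo(animal_id="uvn01", group="uvn", lesion_side="left", day=10)
m = compute_session(traj, session)
```

Formatting the headline fields of `m` prints:

```
distance moved           12188 cm
mean body velocity       25.19 cm/s
immobile                  12.0 %
arena rotations ipsi        43
arena rotations contra       6
bobbing events              28
body torsion              5.05 deg
meander                   3.70 deg/cm
```

Read: in 10 minutes this synthetic animal travels 122 m at a brisk
25 cm/s, circles overwhelmingly toward its lesioned side (43 ipsi- vs 6
contralesional arena rotations), shows ~28 bobbing bursts and holds its
nose bent ~5° toward the intact side — the compensated/overcompensated
phenotype. A sham session under the same battery shows balanced rotations,
no bobbing and ~0° torsion.

The same pipeline runs from the shell:

```bash
ofpheno simulate --phase acute --seed 3 --lesion-side left --out track.csv
ofpheno compute --input track.csv --group uvn --lesion-side left --day 1 --out metrics.csv
ofpheno cohort --metrics metrics.csv --out summary.csv
```

## Analysis scripts

`analysis/` holds the narrative pipeline: `01_simulate_tracks.py` writes
example tracker CSVs per phase, `02_compute_battery.py` simulates a full
longitudinal cohort (8 sham + 8 lesioned animals, pre-op and days 1–30) and
writes one battery row per session, `03_cohort_summary.py` aggregates them
into group × day mean ± SEM kinetics under `results/`.

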