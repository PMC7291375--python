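#!/usr/bin/env python
"""Simulate the full longitudinal cohort and compute the 19-variable battery.

Eight lesioned and eight sham animals, each recorded pre-operatively
(day -1) and on days 1, 2, 3, 7, 10, 14, 21 and 30: sham animals use the
sham preset throughout; lesioned animals are acute on days 1-3 (with the
deficit easing on days 2-3) and compensated from day 7 on. One row of
session metrics per animal-day is written to results/session_metrics.csv.
"""

from pathlib import Path

from ofpheno import SessionInfo, compute_session, phase_preset, simulate, write_metrics

RESULTS = Path(__file__).resolve().parents[1] / "results"
DAYS = (-1, 1, 2, 3, 7, 10, 14, 21, 30)
N_PER_GROUP = 8
BASE_SEED = 515001

# day-graded easing of the acute deficit for lesioned animals
UVN_PHASE_BY_DAY = {
    -1: ("preop", {}),
    1: ("acute", {}),
    2: ("acute", {"mean_move_speed": 11.0, "rest_rate": 0.14, "move_rate": 0.14,
                  "heading_diffusion": 300.0, "torsion_mean": -4.0}),
    3: ("acute", {"mean_move_speed": 12.0, "rest_rate": 0.11, "move_rate": 0.17,
                  "heading_diffusion": 200.0, "torsion_mean": -3.0}),
}


def uvn_spec(day: int, seed: int):
    phase, overrides = UVN_PHASE_BY_DAY.get(day, ("compensated", {}))
    return phase_preset(phase, seed=seed, lesion_side="left", **overrides)


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    rows = []
    for group_idx, group in enumerate(("sham", "uvn")):
        for animal in range(N_PER_GROUP):
            for day_idx, day in enumerate(DAYS):
                seed = BASE_SEED + 1000 * group_idx + 10 * animal + day_idx
                if group == "sham":
                    spec = phase_preset("sham", seed=seed, lesion_side="left")
                else:
                    spec = uvn_spec(day, seed)
                session = SessionInfo(
                    animal_id=f"{group}{animal:02d}",
                    group=group,
                    lesion_side="left",
                    day=day,
                )
                traj = simulate(spec)
                rows.append((session, compute_session(traj, session)))
        print(f"{group}: {N_PER_GROUP * len(DAYS)} sessions computed")
    out = RESULTS / "session_metrics.csv"
    write_metrics(rows, out)
    print(f"wrote {out} ({len(rows)} rows)")


if __name__ == "__main__":
    main()
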