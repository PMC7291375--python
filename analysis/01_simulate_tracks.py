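#!/usr/bin/env python
"""Generate one example tracking CSV per behavioral phase.

Writes tracker-dialect CSVs (t_s, nose/center/tail coordinates in cm,
area-change %) for a sham session, an acute-lesion session and a
compensated-phase session of 10 min at 25 Hz, and prints the basic facts of
each track. These are the same generator settings the test suite validates;
the tracks are written so they can be inspected or fed to the CLI
(`ofpheno compute`).
"""

from pathlib import Path

import numpy as np

from ofpheno import ArenaSpec, phase_preset, simulate, write_trajectory

OUT = Path(__file__).resolve().parents[1] / "results" / "tracks"
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    arena = ArenaSpec()
    for phase in ("sham", "acute", "compensated"):
        spec = phase_preset(phase, seed=SEED, lesion_side="left")
        traj = simulate(spec, arena)
        path = OUT / f"{phase}_example.csv"
        write_trajectory(traj, path)
        disp = np.hypot(*np.diff(traj.center_xy, axis=0).T)
        print(
            f"{phase:12s} {len(traj)} samples at {traj.sample_rate:.0f} Hz, "
            f"raw path {disp.sum():.0f} cm, "
            f"x range [{traj.center_xy[:, 0].min():.1f}, "
            f"{traj.center_xy[:, 0].max():.1f}] cm -> {path.name}"
        )


if __name__ == "__main__":
    main()
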