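#!/usr/bin/env python
"""Aggregate session metrics into group x day mean +/- SEM kinetics.

Reads results/session_metrics.csv (written by 02_compute_battery.py),
writes the long-format cohort summary to results/cohort_summary.csv and
prints the recovery kinetics of the headline variables: the lesioned group
collapses on day 1 (distance, velocity, immobility, meander) and
overshoots after day 7 (velocity, ipsilesional rotations, bobbing).
"""

from pathlib import Path

import pandas as pd

from ofpheno import SessionInfo, SessionMetrics, summarize_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"

SHOW = [
    "total_distance",
    "mean_body_velocity",
    "pct_immobile",
    "mean_absolute_meander",
    "freq_arena_rot_ipsi",
    "freq_bobbing",
    "mean_body_torsion",
]


def main() -> None:
    df = pd.read_csv(RESULTS / "session_metrics.csv")
    rows = []
    for _, r in df.iterrows():
        session = SessionInfo(
            animal_id=str(r["animal_id"]),
            group=str(r["group"]),
            lesion_side=str(r["lesion_side"]),
            day=int(r["day"]),
        )
        m = SessionMetrics(**{k: r[k] for k in SessionMetrics.field_names()})
        rows.append((session, m))
    summary = summarize_cohort(rows)
    out = RESULTS / "cohort_summary.csv"
    summary.to_csv(out, index=False, float_format="%.12g")
    print(f"wrote {out} ({len(summary)} cells)\n")

    for metric in SHOW:
        sub = summary[summary.metric == metric]
        wide = sub.pivot(index="day", columns="group", values="mean").round(2)
        sem = sub.pivot(index="day", columns="group", values="sem").round(2)
        print(f"== {metric} (mean +/- SEM, n=8) ==")
        for day in wide.index:
            print(
                f"  day {day:>3}: sham {wide.loc[day, 'sham']:>9} "
                f"+/- {sem.loc[day, 'sham']:<7} "
                f"uvn {wide.loc[day, 'uvn']:>9} +/- {sem.loc[day, 'uvn']}"
            )
        print()


if __name__ == "__main__":
    main()
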