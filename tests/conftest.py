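import numpy as np
import pytest

from ofpheno import (
    AnalysisProfile,
    SessionInfo,
    Trajectory,
    compute_session,
    phase_preset,
    simulate,
)


@pytest.fixture
def profile():
    return AnalysisProfile()


def make_circle_trajectory(
    r: float = 10.0,
    speed: float = 15.0,
    duration: float = 600.0,
    sample_rate: float = 25.0,
    ccw: bool = True,
    body_half: float = 10.0,
) -> Trajectory:
    """Analytic circular path: center on a circle of radius r at constant
    speed, nose leading tangentially, tail trailing."""
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    omega = (1.0 if ccw else -1.0) * speed / r
    th = omega * t
    center = np.column_stack((40 + r * np.cos(th), 40 + r * np.sin(th)))
    sgn = 1.0 if ccw else -1.0
    tangent = np.column_stack((-sgn * np.sin(th), sgn * np.cos(th)))
    nose = center + body_half * tangent
    tail = center - body_half * tangent
    return Trajectory(
        t, nose, center, tail, None, np.ones(n, dtype=bool), sample_rate
    )


@pytest.fixture(scope="session")
def circle_trajectory():
    return make_circle_trajectory()


@pytest.fixture(scope="session")
def circle_metrics(circle_trajectory):
    return compute_session(
        circle_trajectory, SessionInfo(animal_id="circle", lesion_side="left")
    )


PHASES = ("sham", "acute", "compensated")
COHORT_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def simulated_cohort():
    """Metrics for 5 seeds of each phase preset (left lesion), shared across
    the partition and phenotype-ordering suites."""
    out = {}
    for phase in PHASES:
        rows = []
        for seed in COHORT_SEEDS:
            traj = simulate(phase_preset(phase, seed=seed))
            session = SessionInfo(
                animal_id=f"{phase}{seed}",
                group="sham" if phase == "sham" else "uvn",
                lesion_side="left",
                day=1,
            )
            rows.append((session, traj, compute_session(traj, session)))
        out[phase] = rows
    return out
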