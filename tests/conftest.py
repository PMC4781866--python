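import numpy as np
import pytest

from attnalloc.model import ConditionDesign
from attnalloc.simulator import (
    SubjectPolicy,
    build_session_schedule,
    simulate_subject,
    subject_rngs,
)


def grid_invert(pct, pcb, a_top=1.0, a_bottom=1.0):
    """Independent brute-force inverse of the conditional-rate equations.

    2-D grid search over (p, g) in [0,1]^2 minimizing squared residuals:
    coarse step 1e-3 over the full square, then two local refinement passes
    reaching step < 1e-6.  Deliberately unrelated to the closed-form path
    it is used to check.
    """
    p = np.linspace(0.0, 1.0, 1001)[:, None]
    g = np.linspace(0.0, 1.0, 1001)[None, :]

    def cost(pg, gg):
        return (a_top * (pg + (1 - pg) * gg) - pct) ** 2 + (
            a_bottom * ((1 - pg) + pg * gg) - pcb
        ) ** 2

    c = cost(p, g)
    i, j = np.unravel_index(np.argmin(c), c.shape)
    best_p, best_g = float(p[i, 0]), float(g[0, j])
    # local refinement: windows generous enough that an elongated
    # least-squares valley cannot strand the coarse minimum outside them
    half = 0.02
    while half > 2e-6:
        pw = np.linspace(max(best_p - half, 0.0), min(best_p + half, 1.0), 201)[:, None]
        gw = np.linspace(max(best_g - half, 0.0), min(best_g + half, 1.0), 201)[None, :]
        c = cost(pw, gw)
        i, j = np.unravel_index(np.argmin(c), c.shape)
        best_p, best_g = float(pw[i, 0]), float(gw[0, j])
        half /= 10.0
    return best_p, best_g


def simulate_cohort(
    root_seed,
    p_top,
    n_subjects,
    policy,
    n_sessions=2,
):
    """Simulated trial logs for a cohort of subjects in one condition."""
    design = ConditionDesign.from_top(p_top)
    logs = []
    for rng in subject_rngs(root_seed, n_subjects):
        schedules = [
            build_session_schedule(rng, design, session_index=s + 1)
            for s in range(n_sessions)
        ]
        logs.append(simulate_subject(schedules, policy, rng))
    return logs


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def two_session_log():
    """One lapse-free subject with fixed p = 0.75 at PT = 0.75."""
    policy = SubjectPolicy(kind="fixed", p0=0.75, lapse_rate=0.0)
    return simulate_cohort(11, 0.75, 1, policy)[0]
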