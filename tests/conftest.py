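import numpy as np
import pytest

from aaqsp import pbpk, scoring
from aaqsp.synthetic import toy_one_compartment_drug, toy_physiology


@pytest.fixture(scope="session")
def physiology():
    return pbpk.packaged_physiology()


@pytest.fixture(scope="session")
def runner():
    """Session-wide scenario runner (caches network baseline and controls)."""
    return scoring.ScenarioRunner()


@pytest.fixture(scope="session")
def scenarios():
    return scoring.load_scenarios()


@pytest.fixture()
def toy_iv_setup():
    """One-compartment iv toy: V = 10 L, first-order elimination 0.1/h."""
    phys = toy_physiology(volume=10.0)
    drug = toy_one_compartment_drug(ke_per_min=0.1 / 60.0, molecular_weight=300.0)
    model = pbpk.build_model(phys, drug)
    return phys, drug, model


def euler_integrate(rhs, y0, t_end, dt):
    """Brute-force fixed-step Euler oracle shared by network/induction tests."""
    n = int(round(t_end / dt))
    y = np.asarray(y0, dtype=float).copy()
    ts = [0.0]
    ys = [y.copy()]
    t = 0.0
    for _ in range(n):
        y = y + dt * np.asarray(rhs(t, y))
        t += dt
        ts.append(t)
        ys.append(y.copy())
    return np.asarray(ts), np.asarray(ys).T
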