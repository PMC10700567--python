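import numpy as np
import pytest

from cyclesim.dynamics import net_joint_moments
from cyclesim.model import HillCurves, default_model, generic_model
from cyclesim.solver import (
    ActuatorChannel,
    CollocationGrid,
    CollocationProblem,
    MuscleChannel,
    ObjectiveConfig,
)
from cyclesim.synth import TrialMeta, synthesize_trial

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def model75():
    """Generic reference model (1.75 m / 75 kg)."""
    return generic_model()


@pytest.fixture(scope="session")
def curves():
    return HillCurves()


@pytest.fixture(scope="session")
def mid_trial():
    """A mid-power trial near the cohort-mean power, with its model."""
    meta = TrialMeta("MID", 1.75, 75.0, 85.0, 137.0, seed=42)
    model = default_model(meta.height_m, meta.mass_kg)
    trial = synthesize_trial(meta, model=model)
    return meta, model, trial


@pytest.fixture(scope="session")
def mid_dynamics(mid_trial):
    meta, model, trial = mid_trial
    moments, inter = net_joint_moments(trial.kin, trial.loads["r"], model,
                                       trial.geom, side="r")
    return moments, inter


def make_toy_problem(n_per_rev=21, cadence=80.0, demand=20.0, n_muscles=1,
                     with_reserve=True, mode="J1", f_max=1000.0, arm=0.05,
                     kappa_act=900.0, kappa_pas=5.0, tau_act=0.01, tau_deact=0.04):
    """Single-DOF rigid-muscle collocation problem with constant demand."""
    grid = CollocationGrid.from_cadence(cadence, n_per_rev=n_per_rev)
    N = grid.n_nodes
    curves = HillCurves()
    muscles = [
        MuscleChannel(name=f"m{i + 1}", f_max=f_max, tau_act=tau_act,
                      tau_deact=tau_deact, rigid=True,
                      arms={"dof1": np.full(N, arm)},
                      kappa_act=np.full(N, kappa_act),
                      kappa_pas=np.full(N, kappa_pas))
        for i in range(n_muscles)
    ]
    actuators = [ActuatorChannel("res1", "dof1", 1.0)] if with_reserve else []
    demand_arr = demand if isinstance(demand, np.ndarray) else np.full(N, float(demand))
    cfg = ObjectiveConfig(mode=mode)
    prob = CollocationProblem(grid, muscles, {"dof1": demand_arr}, actuators, cfg, curves)
    return grid, prob, cfg
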