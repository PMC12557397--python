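import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20250922)


@pytest.fixture
def small_ensemble(rng):
    """Tiny 4-trajectory ensemble, equal length, 3 contacts."""
    from pathsim import ContactTrajectory, TrajectoryEnsemble
    trajs = [
        ContactTrajectory(1.0 + rng.random((10, 3)), dt=1.0, traj_id=f"t{i}",
                          contact_labels=["A:1", "A:2", "A:3"])
        for i in range(4)
    ]
    return TrajectoryEnsemble(trajs, labels=["p0", "p0", "p1", "p1"])


def random_trajectory(rng, k, m, traj_id="x"):
    from pathsim import ContactTrajectory
    return ContactTrajectory(rng.random((k, m)) * 2.0, traj_id=traj_id,
                             contact_labels=[f"c{j}" for j in range(m)])
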