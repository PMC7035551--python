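import numpy as np
import pytest

from patbp.models import BaselineState, ModelParams
from patbp.synth import PATTrajectory, SubjectProfile


@pytest.fixture
def baseline_params() -> ModelParams:
    """dMK-BH anchored at the 120/80 textbook baseline."""
    return ModelParams("dMK-BH", baseline=BaselineState(
        sbp0=120.0, dbp0=80.0, pat0=0.25, gamma=0.031))


@pytest.fixture
def quiet_profile() -> SubjectProfile:
    """A jitter-free subject for deterministic round trips."""
    return SubjectProfile("S01", sbp0=120.0, dbp0=80.0, pat0=0.25,
                          pat_jitter_sd=0.0, pat_slow_sd=0.0)


@pytest.fixture
def short_trajectory(quiet_profile) -> PATTrajectory:
    """Ten noiseless beats with slowly recovering PAT."""
    from patbp.synth import simulate_pat_trajectory
    traj = simulate_pat_trajectory(quiet_profile, duration=9.0, seed=0)
    assert len(traj.beat_times) >= 10
    return PATTrajectory(beat_times=traj.beat_times[:10],
                         pat_true=traj.pat_true[:10])
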