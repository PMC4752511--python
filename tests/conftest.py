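import numpy as np
import pytest

from antirace import REFERENCE_PARAMS, ModelParams, SubjectData
from antirace.simulate import simulate_anti, simulate_pro


@pytest.fixture(scope="session")
def ref_params() -> ModelParams:
    return REFERENCE_PARAMS


@pytest.fixture(scope="session")
def control_params() -> ModelParams:
    """A behaviorally realistic parameter set (~68% anti accuracy, pro RT
    ~0.34 s, correct-anti RT close to pro, fast errors)."""
    return ModelParams(
        v_pre=5.2, v_inhib=6.0, v_exec=7.1, a_mean=1.0, a_diff=0.0, t=0.15, t_exec=0.05
    )


def make_subject(params, n_pro, n_anti, seed, subject_id="s0", stage=None):
    rng = np.random.default_rng(seed)
    pro = simulate_pro(params, n_pro, rng)
    anti_rt, anti_ok = simulate_anti(params, n_anti, rng)
    return SubjectData(
        subject_id=subject_id, pro_rts=pro, anti_rts=anti_rt, anti_correct=anti_ok, stage=stage
    )


@pytest.fixture(scope="session")
def small_subject(control_params) -> SubjectData:
    """200 pro + 200 anti trials at the control parameter set."""
    return make_subject(control_params, 200, 200, seed=42)
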