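import numpy as np
import pytest

from motordcm.cohort import DEFAULT_A_MEANS
from motordcm.generative import ConnectivityParams, build_design
from motordcm.model_space import REGIONS, get_model

_IDX = {r: i for i, r in enumerate(REGIONS)}


def params_for(model_id: str, b_values: dict | None = None,
               c_u1: float = 0.10) -> ConnectivityParams:
    """Group-mean connectivity parameters on a model's support."""
    model = get_model(model_id)
    A = np.zeros((4, 4))
    for i, j in zip(*np.nonzero(model.a_mask)):
        A[i, j] = DEFAULT_A_MEANS[(REGIONS[j], REGIONS[i])]
    B = np.zeros((4, 4))
    for (src, tgt), v in (b_values or {}).items():
        B[_IDX[tgt], _IDX[src]] = v
    C = np.zeros((4, 2))
    C[_IDX["PFC"], 0] = c_u1
    return ConnectivityParams(A=A, B=B, C=C)


@pytest.fixture(scope="session")
def e2():
    return get_model("E2")


@pytest.fixture(scope="session")
def e2_params():
    return params_for("E2", {("PFC", "preSMA"): 0.06, ("preSMA", "PFC"): 0.05})


@pytest.fixture(scope="session")
def short_design():
    """A quick 60-volume design used by inversion unit tests."""
    return build_design(16, soa=2.5, seed=7, n_volumes=60)


@pytest.fixture(scope="session")
def study_design():
    """The study's session design: 40 trials per condition, 150 volumes."""
    return build_design(40, soa=2.5, seed=11, n_volumes=150)
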