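import numpy as np
import pandas as pd
import pytest

from chunkrt import make_illusory_matrix
from chunkrt.simulate import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def illusory():
    return make_illusory_matrix()


@pytest.fixture(scope="session")
def size2_cohort():
    """Six simulated participants trained on size-2 (AB) sequences."""
    return simulate_cohort(CohortSpec(n_participants=6, condition="size2", seed=5))


@pytest.fixture(scope="session")
def independent_cohort():
    """Six simulated participants trained on chunk-free sequences."""
    return simulate_cohort(
        CohortSpec(n_participants=6, condition="independent", seed=5)
    )


@pytest.fixture(scope="session")
def size3_cohort():
    """Twenty simulated participants trained on size-3 (ABC) sequences."""
    return simulate_cohort(CohortSpec(n_participants=20, condition="size3", seed=5))


@pytest.fixture(scope="session")
def fast_cohort():
    return simulate_cohort(
        CohortSpec(n_participants=6, condition="illusory-fast", seed=11)
    )


@pytest.fixture(scope="session")
def accurate_cohort():
    return simulate_cohort(
        CohortSpec(n_participants=6, condition="illusory-accurate", seed=11)
    )


def make_trials(
    participant="p1",
    group="g",
    instructions=None,
    responses=None,
    rts=None,
    block=1,
    block_role="baseline",
    start_trial=1,
):
    """Hand-built trial-log fragment with the standard schema."""
    if instructions is None:
        n = len(rts) if rts is not None else 20
        instructions = ("ABCD" * (n // 4 + 1))[:n]
    n = len(instructions)
    responses = responses if responses is not None else instructions
    rts = rts if rts is not None else [400.0] * n
    return pd.DataFrame(
        {
            "participant": [participant] * n,
            "group": [group] * n,
            "block": [block] * n,
            "block_role": [block_role] * n,
            "trial": list(range(start_trial, start_trial + n)),
            "instruction": list(instructions),
            "response": list(responses),
            "rt": list(map(float, rts)),
            "correct": [i == r for i, r in zip(instructions, responses)],
        }
    )


@pytest.fixture
def trials_builder():
    return make_trials
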