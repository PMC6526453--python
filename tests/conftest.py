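import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pendiff import DiffusionParams, simulate_trials
from pendiff.cohort import OLDER_MEANS, YOUNGER_MEANS

settings.register_profile(
    "pendiff",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("pendiff")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def younger_means() -> DiffusionParams:
    return YOUNGER_MEANS


@pytest.fixture
def older_means() -> DiffusionParams:
    return OLDER_MEANS


def make_trials(
    params: DiffusionParams,
    n_word: int,
    n_nonword: int,
    rng: np.random.Generator,
    pid: str = "P1",
    dt: float = 2e-4,
) -> pd.DataFrame:
    """Minimal trial table from direct diffusion simulation (no page layout)."""
    frames = []
    for cond, n in (("word", n_word), ("nonword", n_nonword)):
        up, rt = simulate_trials(params, cond, n, rng, dt=dt)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "session": 3,
                    "page": 1,
                    "slot": 2,
                    "condition": cond,
                    "is_reference": False,
                    "is_practice": False,
                    "response": np.where(up, "word", "nonword"),
                    "rt_s": rt,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def make_trials_fn():
    return make_trials
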