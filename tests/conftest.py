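import numpy as np
import pandas as pd
import pytest

from moralcomp import DesignSpec, build_schedules
from moralcomp.models import get_model


@pytest.fixture(scope="session")
def design():
    return DesignSpec()


@pytest.fixture(scope="session")
def factorial_hw():
    """The 64-trial factorial as plain (H, W) arrays (4 repeats per cell)."""
    H = np.repeat([1, 2, 3, 4], 16).astype(float)
    W = np.tile(np.repeat([1, 2, 3, 4], 4), 4).astype(float)
    return H, W


@pytest.fixture(scope="session")
def schedule_one(design):
    return build_schedules(design, 1, seed=11)


def make_cohort_params(n, seed, lam=2.0, model="1.3"):
    """Participant parameter table drawn from the default cohort ranges."""
    from moralcomp.simulate import CohortSpec, generate_cohort_params

    spec = CohortSpec(model=model, n_participants=n, lam=lam)
    return generate_cohort_params(spec, seed)


def softmax_oracle(U, lam):
    """Independent brute-force softmax: direct summation over all options,
    no numerical stabilisation."""
    import math

    num = [math.exp(lam * u) for u in U]
    total = sum(num)
    return np.array([v / total for v in num])
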