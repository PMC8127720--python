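import numpy as np
import pandas as pd
import pytest

from belugaclock.io import BetaMatrix
from belugaclock.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort shared across tests (fast to fit)."""
    cfg = SimulationConfig(
        n_samples=40, n_probes=300, n_age_informative=15, n_sex_linked=5,
        rng_seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_beta(values, sample_ids=None, probe_ids=None) -> BetaMatrix:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return BetaMatrix(
        pd.DataFrame(
            values,
            index=sample_ids or [f"s{i}" for i in range(n)],
            columns=probe_ids or [f"cg{j:05d}" for j in range(p)],
        )
    )
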