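import numpy as np
import pandas as pd
import pytest

from favsdm import SyntheticSpec, gen_covariates, gen_presence


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def covariates(default_spec) -> pd.DataFrame:
    return gen_covariates(default_spec)


@pytest.fixture(scope="session")
def dataset(default_spec, covariates) -> pd.DataFrame:
    """Full-size synthetic OGU table with presence drawn from the known logit."""
    sim = gen_presence(covariates, default_spec.true_beta,
                       default_spec.target_prevalence, seed=1)
    return sim.table


@pytest.fixture(scope="session")
def small_dataset() -> pd.DataFrame:
    """Small, strongly informative table for fast fitting tests: one active
    variable on a balanced outcome."""
    rng = np.random.default_rng(5)
    n = 600
    x = rng.normal(size=n)
    noise = rng.normal(size=(n, 3))
    from scipy.special import expit
    p = expit(1.5 * x)
    y = (rng.random(n) < p).astype(int)
    return pd.DataFrame({
        "ogu_id": [f"c{i}" for i in range(n)],
        "presence": y, "active": x,
        "noise1": noise[:, 0], "noise2": noise[:, 1], "noise3": noise[:, 2],
    })
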