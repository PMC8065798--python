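import numpy as np
import pandas as pd
import pytest

from mcakm import synthetic


@pytest.fixture(scope="session")
def table1_spec():
    return synthetic.cohort_preset("table1", seed=11)


@pytest.fixture(scope="session")
def table1_cohort(table1_spec):
    return synthetic.generate_cohort(table1_spec)


@pytest.fixture
def random_table():
    """Factory for small random categorical tables."""

    def make(n_rows=30, n_vars=4, n_levels=3, seed=0):
        rng = np.random.default_rng(seed)
        data = {
            f"v{j}": pd.Categorical.from_codes(
                rng.integers(0, n_levels, n_rows), categories=[f"L{l}" for l in range(n_levels)]
            )
            for j in range(n_vars)
        }
        df = pd.DataFrame(data)
        # re-draw any variable that came out single-level
        for col in df.columns:
            while df[col].nunique() < 2:
                df[col] = pd.Categorical.from_codes(
                    rng.integers(0, n_levels, n_rows), categories=[f"L{l}" for l in range(n_levels)]
                )
        return df

    return make


@pytest.fixture(scope="session")
def toy_claims():
    spec = synthetic.cohort_preset("table1", seed=0)
    claims = synthetic.generate_claims(spec, "toy_filter")
    birthdates = synthetic.generate_birthdates(spec, "toy_filter")
    return claims, birthdates
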