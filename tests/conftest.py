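import numpy as np
import pytest

from pipuq import evaluation, synthetic


@pytest.fixture(scope="session")
def guh_cohort():
    return synthetic.generate_cohort(120, seed=11, site="GUH")


@pytest.fixture(scope="session")
def guh_records(guh_cohort):
    return synthetic.simulate_records(guh_cohort, n_days=3, seed=11)


@pytest.fixture(scope="session")
def hetero_split():
    """Train/test split of the heteroscedastic regression benchmark."""
    df = synthetic.heteroscedastic_regression_data(n=5000, seed=7)
    return df.iloc[:4000].reset_index(drop=True), df.iloc[4000:].reset_index(drop=True)


@pytest.fixture(scope="session")
def hetero_ensemble(hetero_split):
    from pipuq import quantile_uq

    train, _ = hetero_split
    return quantile_uq.fit_quantile_ensemble(
        train, evaluation.gbt_factory(random_state=0), 0.80, ["x1", "x2"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
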