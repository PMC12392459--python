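import numpy as np
import pytest

from fastgrowth import datasets


@pytest.fixture(scope="session")
def solvation_records():
    return datasets.load_solvation_table()


@pytest.fixture(scope="session")
def logp_reference():
    return datasets.load_logp_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def scipy_ad_oracle(values: np.ndarray) -> float:
    """Independent Anderson-Darling oracle: scipy's raw A² with the
    estimated-parameters small-sample factor applied to the statistic."""
    import warnings
    from scipy import stats
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        a2 = stats.anderson(np.asarray(values), "norm").statistic
    n = len(values)
    return float(a2 * (1 + 0.75 / n + 2.25 / n ** 2))
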