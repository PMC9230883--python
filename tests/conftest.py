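import numpy as np
import pytest

from apval import TruthSpec, study_design, study_truth_spec, simulate_validation_dataset


@pytest.fixture
def design():
    return study_design()


@pytest.fixture
def truth():
    return study_truth_spec(seed=123)


@pytest.fixture
def noiseless_truth(design):
    return TruthSpec(
        design=design,
        bias_pct=(0.0,) * 5,
        cv_within_pct=(0.0,) * 5,
        cv_between_pct=(0.0,) * 5,
        cal_cv_within_pct=0.0,
        day_effect_cv_pct=0.0,
        seed=1,
    )


@pytest.fixture
def table(truth):
    return simulate_validation_dataset(truth, seed=2024)


@pytest.fixture
def noiseless_table(noiseless_truth):
    return simulate_validation_dataset(noiseless_truth)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
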