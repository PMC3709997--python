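import numpy as np
import pytest

from mudswim import SurveyConfig, generate_survey


@pytest.fixture(scope="session")
def default_survey():
    """One full survey under the default (study-like) conditions."""
    return generate_survey(SurveyConfig(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
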