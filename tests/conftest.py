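import pandas as pd
import pytest

from streamn2o.survey_processing import classify_records
from streamn2o.synthetic_data import generate_strata, generate_survey
from streamn2o.upscaling import strata_from_frame


@pytest.fixture(scope="session")
def survey():
    """One seeded full-size synthetic survey plus its truth sidecar."""
    frame, truth = generate_survey(seed=1)
    return frame, truth


@pytest.fixture(scope="session")
def records(survey) -> pd.DataFrame:
    """The classified analysis table for the session survey."""
    frame, _ = survey
    return classify_records(frame)


@pytest.fixture(scope="session")
def strata_frame() -> pd.DataFrame:
    return generate_strata()


@pytest.fixture(scope="session")
def strata(strata_frame):
    return strata_from_frame(strata_frame)
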