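import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import exponential_cohort, make_obs  # noqa: E402

from nmrsurv.records_io import Event  # noqa: E402


@pytest.fixture
def toy_observations():
    """Five-animal worked example: deaths at 200, 300, 400; censors at 250, 350."""
    return [
        make_obs(200, Event.DEATH),
        make_obs(250, Event.CENSOR),
        make_obs(300, Event.DEATH),
        make_obs(350, Event.CENSOR),
        make_obs(400, Event.DEATH),
    ]


@pytest.fixture
def exponential_observations():
    """2000 uncensored exponential lifespans at 1e-4/day past entry."""
    return exponential_cohort(2000, 1e-4, seed=42)
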