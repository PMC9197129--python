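import warnings

import pytest

from socialddm import (
    FitOptions,
    Strategy,
    build_session,
    fit_subject,
    get_model,
    make_agent,
    simulate_subject,
)
from socialddm.fitting import preprocess


@pytest.fixture(scope="session")
def session_plan():
    return build_session(seed=11)


@pytest.fixture(scope="session")
def ingroup_agent():
    return make_agent(Strategy.INGROUP_DRIVEN, seed=7)


@pytest.fixture(scope="session")
def subject_trials(ingroup_agent, session_plan):
    """One simulated ingroup-driven subject, preprocessed."""
    trials = simulate_subject(ingroup_agent, session_plan, subject="s01")
    kept, _ = preprocess(trials)
    return kept


@pytest.fixture(scope="session")
def fit35(subject_trials):
    """Model-35 (type-varying drift, z free) fit of the fixture subject."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_subject(get_model(35), subject_trials, FitOptions(restarts=3, seed=5))
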