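import pytest

from pbma import case_study


@pytest.fixture(scope="session")
def tree():
    return case_study.load_criterion_tree()


@pytest.fixture(scope="session")
def criterion_scores():
    return case_study.load_criterion_scores()


@pytest.fixture(scope="session")
def recorded_finals():
    return case_study.recorded_final_scores()


@pytest.fixture(scope="session")
def registry():
    return case_study.load_registry()


@pytest.fixture(scope="session")
def ballotbox():
    return case_study.load_ballotbox()


@pytest.fixture(scope="session")
def recorded_decisions():
    return case_study.recorded_decisions()
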