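import numpy as np
import pytest

from groupseq import (
    DesignSpec,
    StageSchedule,
    StoppingRule,
    larger_study_designs,
    small_study_designs,
)


@pytest.fixture(scope="session")
def small_schedule():
    return StageSchedule((6, 12, 18))


@pytest.fixture(scope="session")
def larger_schedule():
    return StageSchedule((18, 36))


@pytest.fixture(scope="session")
def small_designs():
    return small_study_designs()


@pytest.fixture(scope="session")
def larger_designs():
    return larger_study_designs()


@pytest.fixture(scope="session")
def fixed_design_n18():
    return DesignSpec(
        StageSchedule((18,)), StoppingRule(kind="fixed", alpha=0.05), label="fixed18"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20170310)
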