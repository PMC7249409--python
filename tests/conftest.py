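import numpy as np
import pytest

from augbin import (
    ComponentRule,
    CompositeRule,
    Direction,
    JointParams,
    TrialData,
)


@pytest.fixture
def median_rule() -> CompositeRule:
    """Responder = continuous component >= 0 AND binary criterion met."""
    return CompositeRule(ComponentRule(Direction.AT_LEAST, 0.0))


@pytest.fixture
def shrinkage_rule() -> CompositeRule:
    """Tumour-response style rule on signed percent change: <= -30 AND b = 1."""
    return CompositeRule(ComponentRule(Direction.AT_MOST, -30.0))


@pytest.fixture
def independent_params() -> JointParams:
    """Components independent given arm (gamma2 = 0)."""
    return JointParams(0.0, 0.0, 1.0, 0.0, 0.0, 0.0)


def make_trial(z, y, b, ids=None) -> TrialData:
    z = np.asarray(z)
    if ids is None:
        ids = [f"s{i}" for i in range(len(z))]
    return TrialData(ids, z, y, b)


@pytest.fixture
def toy_trial() -> TrialData:
    """Four subjects: two meet both criteria, one fails the continuous
    criterion, one fails the binary criterion."""
    return make_trial(
        z=[0, 0, 1, 1],
        y=[0.5, 2.0, -1.0, 1.0],
        b=[1, 1, 1, 0],
    )
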