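import numpy as np
import pytest

from mase import (
    ExchangePoint,
    LysateComposition,
    LysateLabel,
    MixingProtocol,
    RateConstants,
    predict_R,
)


@pytest.fixture
def equivalent_protocol():
    """Canonical assay: equal-concentration lysates, 1:1 mix."""
    return MixingProtocol.equivalent(1.0)


@pytest.fixture
def unequal_b_protocol():
    """Negative control: labeled lysate with doubled total B."""
    return MixingProtocol(
        lysate_unlabeled=LysateComposition(1.0, 1.0, LysateLabel.UNLABELED_TAGGED),
        lysate_labeled=LysateComposition(1.0, 2.0, LysateLabel.LABELED_UNTAGGED),
    )


def noiseless_series(k_off, t_points):
    return [ExchangePoint(float(t), predict_R(k_off, float(t))) for t in t_points]


@pytest.fixture
def hour_grid():
    """0..8 h in half-hour steps (17 points), seconds."""
    return np.arange(0.0, 28801.0, 1800.0)
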