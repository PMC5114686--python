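import pytest

from thresholdcross import DesignParams, RuleTag, ThresholdRule


@pytest.fixture
def params() -> DesignParams:
    """Reference planning assumptions: delta=0.2, sigma=1, one-sided
    alpha=2.5%, 80% power."""
    return DesignParams(delta=0.2)


@pytest.fixture
def naive_rule() -> ThresholdRule:
    return ThresholdRule(RuleTag.NAIVE_MEAN)


@pytest.fixture
def ci_rule() -> ThresholdRule:
    return ThresholdRule(RuleTag.CI_UPPER)
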