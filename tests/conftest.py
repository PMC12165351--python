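import pytest

from flexpst import GroupSummary, InferenceWeights


@pytest.fixture
def weights():
    """Conventional trial decision parameters: pr=0.5, C=0.25, d=0.5."""
    return InferenceWeights(pr=0.5, C=0.25, d=0.5)


@pytest.fixture
def replica1():
    """First hemoglobin-trial replica: 11.1±2.0 vs 13.4±4.3, n=50/arm."""
    return (GroupSummary(n=50, mean=11.1, sd=2.0),
            GroupSummary(n=50, mean=13.4, sd=4.3))


@pytest.fixture
def replica2():
    """Second replica of the same trial: 11.0±1.8 vs 12.4±4.4, n=50/arm."""
    return (GroupSummary(n=50, mean=11.0, sd=1.8),
            GroupSummary(n=50, mean=12.4, sd=4.4))
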