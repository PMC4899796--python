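import pytest
from hypothesis import settings

from opttrend.datasets import adprt_example_model, adprt_lung_cancer

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def adprt():
    """ADPRT Val762Ala lung-cancer table: 1000 cases, 1018 controls."""
    return adprt_lung_cancer()


@pytest.fixture
def worked_model():
    """The illustrative effect model: q=0.4, HWE, RR=1.25, CV=0.4, dosage."""
    return adprt_example_model()
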