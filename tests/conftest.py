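import pytest

from twbio.datasets import tw_samples


@pytest.fixture(scope="session")
def samples():
    """The seven characterized wastewater samples (controls excluded)."""
    return tw_samples()
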