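import warnings

import pytest

from mirsubpath.model import SubpathwayModel
from mirsubpath.synth import generate_all, test_scale_spec as small_spec

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def bundle():
    """One deterministic test-scale synthetic cohort shared across tests."""
    return generate_all(small_spec(7))


@pytest.fixture(scope="session")
def fitted():
    """The full pipeline fitted on the shared synthetic cohort."""
    model = SubpathwayModel.from_synthetic(small_spec(7))
    return model.fit()
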