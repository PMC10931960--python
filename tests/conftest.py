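import pytest

from pelvimark import PelvisTemplate, generate_truth
from pelvimark.synthetic_data import TRUTH_ANNOTATOR


@pytest.fixture(scope="session")
def template():
    return PelvisTemplate()


@pytest.fixture(scope="session")
def truth_study(template):
    """Five noiseless images with their truth table."""
    return generate_truth(template, n_images=5, pt_jitter_deg=5.0, seed=11)


@pytest.fixture(scope="session")
def truth_annotator():
    return TRUTH_ANNOTATOR
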