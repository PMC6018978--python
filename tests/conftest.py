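import pytest

from madskit.conservation import load_matrix
from madskit.simulate import preset_profiles, simulate_family


@pytest.fixture(scope="session")
def blosum40():
    return load_matrix("BLOSUM40")


@pytest.fixture(scope="session")
def sep3_family():
    """A 78-sequence SEP3-style synthetic family, fixed seed."""
    return simulate_family(preset_profiles("SEP3-like"), n_seqs=78, label="SEP3-like", seed=7)
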