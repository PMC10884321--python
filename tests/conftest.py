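import pytest

from caindex import load_fixture


@pytest.fixture(scope="session")
def bundle():
    return load_fixture()


@pytest.fixture(scope="session")
def control(bundle):
    return bundle.control


def structure_key(profile, name):
    """(group, name) key for a structure name unique within a profile."""
    return next(k for k in profile.states if k[1] == name)
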