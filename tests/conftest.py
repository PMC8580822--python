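import pytest

from gpcrstates.fixture_factory import BundleSpec, make_ideal_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default 7x25 ideal bundle shared by read-only tests."""
    return make_ideal_bundle(BundleSpec())


@pytest.fixture(scope="session")
def bundle_with_sidechains():
    """Bundle carrying a few full side chains at classic motif positions."""
    spec = BundleSpec(substitutions=(
        ("3x49", "D"), ("3x50", "R"), ("6x48", "W"), ("7x49", "N"),
        ("7x50", "P"), ("5x58", "Y")))
    return make_ideal_bundle(spec)
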