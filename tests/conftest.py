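import pytest

from mitovulture import packaged_feature_table
from mitovulture.substitution_sites import load_reference_sites


@pytest.fixture(scope="session")
def vulture_table():
    """The packaged S. calvus mitogenome annotation (39 features, 17,750 bp)."""
    return packaged_feature_table()


@pytest.fixture(scope="session")
def owv_nwv_sites():
    """The published 67-site OWV-vs-NWV cross-class substitution list."""
    return load_reference_sites("owv_nwv")


@pytest.fixture(scope="session")
def calvus_sites():
    """The published 43-site S. calvus-vs-other-Gypini substitution list."""
    return load_reference_sites("calvus_gypini")
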