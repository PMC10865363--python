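import pytest

from bizinc.synthetic import SiteSpec, build_site
from bizinc.synthetic_complexes import all_synthetic_complexes


@pytest.fixture(scope="session")
def reference_complexes():
    """The five synthetic stand-in complexes, built once per session."""
    return all_synthetic_complexes()


@pytest.fixture(scope="session")
def canonical_site():
    """Noise-free monosubstituted sulfamide site with its ground truth."""
    return build_site(SiteSpec())


@pytest.fixture()
def site_spec():
    return SiteSpec()
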