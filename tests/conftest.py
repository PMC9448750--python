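import numpy as np
import pytest
from importlib import resources

from ffpecorrect import SignatureSet, bundled_signatures


@pytest.fixture(scope="session")
def ref_signatures() -> SignatureSet:
    """Packaged synthetic COSMIC-like reference signature set."""
    ref = resources.files("ffpecorrect.data").joinpath(
        "synthetic_cosmic_like_signatures.tsv"
    )
    with resources.as_file(ref) as path:
        return SignatureSet.from_tsv(path)


@pytest.fixture(scope="session")
def w1_unrepaired():
    return bundled_signatures("unrepaired")


@pytest.fixture(scope="session")
def w1_repaired():
    return bundled_signatures("repaired")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
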