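import pytest

from mutascope.synthetic_data import ReferenceSpec, make_reference


@pytest.fixture(scope="session")
def hotspot_ref():
    """183-nt coding sequence with the RAS hotspot template in place."""
    return make_reference(ReferenceSpec(length=183, hotspot_template=True, seed=7))


@pytest.fixture(scope="session")
def cds576():
    """Full-length 576-nt coding sequence, GC-matched to HRAS (~59.1%)."""
    return make_reference(
        ReferenceSpec(length=576, gc_target=0.591, hotspot_template=True, seed=42)
    )
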