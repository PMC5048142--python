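import pytest

from prdm9znf.simulate import SimConfig, make_reference_exon


@pytest.fixture(scope="session")
def reference():
    """A wild-type exon with 6 array fingers and its construction record."""
    cfg = SimConfig(seed=11)
    exon, truth = make_reference_exon(cfg, n_fingers=6)
    return exon, truth, cfg
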