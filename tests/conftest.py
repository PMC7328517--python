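import numpy as np
import pytest

from mitodyn import synthetic


@pytest.fixture(scope="session")
def truth():
    """Default desk-scale planted study (2 x 20 Mb)."""
    return synthetic.make_truth(7)


@pytest.fixture(scope="session")
def structured_hic(truth):
    """Balanced fully-structured (mixing = 1) contact maps with O/E."""
    from mitodyn import hic

    out = {}
    for chrom, cm in synthetic.gen_contacts(truth, mixing=1.0).items():
        hic.balance(cm)
        oe, expected = hic.observed_expected(cm)
        out[chrom] = (cm, oe, expected)
    return out


@pytest.fixture(scope="session")
def mitotic_hic(truth):
    """Balanced structureless (mixing = 0) contact maps with O/E."""
    from mitodyn import hic

    out = {}
    for chrom, cm in synthetic.gen_contacts(truth, mixing=0.0).items():
        hic.balance(cm)
        oe, expected = hic.observed_expected(cm)
        out[chrom] = (cm, oe, expected)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
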