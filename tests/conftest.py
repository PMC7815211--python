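import numpy as np
import pytest

from tissuemech import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_valid_tensions(rng, n):
    """Random tension triples strictly inside the Neumann validity domain."""
    out = []
    while len(out) < n:
        ct_a = rng.uniform(0.5, 2.0)
        ct_b = rng.uniform(0.5, 2.0)
        lo, hi = abs(ct_a - ct_b), ct_a + ct_b
        # stay away from the point-contact and engulfment limits
        t_ab = rng.uniform(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo))
        out.append((ct_a, ct_b, t_ab))
    return out


@pytest.fixture
def symmetric_doublet():
    return syn.simulate_doublet(syn.DoubletParams(ct_a=1.0, ct_b=1.0, t_ab=1.0))


@pytest.fixture
def membrane_fixture():
    """Closed square membrane at 100 on a cytoplasm-filled field at 10."""
    img = np.full((128, 128), 10.0)
    img[30:33, 30:99] = 100.0
    img[96:99, 30:99] = 100.0
    img[30:99, 30:33] = 100.0
    img[30:99, 96:99] = 100.0
    return img
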