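import numpy as np
import pytest

from cotransfold.geometry import (
    EXTENDED,
    TorsionTriple,
    build_from_torsions,
)

HELIX = TorsionTriple(-57.0, -47.0, 180.0)
STRAND = TorsionTriple(-139.0, 135.0, 180.0)


@pytest.fixture
def ideal_helix12():
    return build_from_torsions("A" * 12, [HELIX] * 12)


@pytest.fixture
def extended30():
    return build_from_torsions("A" * 30, [EXTENDED] * 30)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_torsions(rng, n):
    """Valid random triples: phi/psi anywhere, omega near trans."""
    out = []
    for _ in range(n):
        phi = float(rng.uniform(-179.0, 179.0))
        psi = float(rng.uniform(-179.0, 179.0))
        omega = float(rng.uniform(160.0, 179.0)) * (1 if rng.random() < 0.5 else -1)
        out.append(TorsionTriple(phi, psi, omega))
    return out
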