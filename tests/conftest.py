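import numpy as np
import pytest

from ensemblemap import ReferenceEngine, fixture_sequence


@pytest.fixture(scope="session")
def engine():
    """One shared reference engine; its partition tables are cached."""
    return ReferenceEngine()


@pytest.fixture(scope="session")
def hairpin():
    return fixture_sequence("hairpin")


@pytest.fixture(scope="session")
def toggle():
    """Riboswitch-like toggle sequence with two mutually exclusive helices."""
    return fixture_sequence("riboswitch_like")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_bppm(rng, n=8, seq_id="rand"):
    """A random valid base-pair probability matrix (symmetric, row mass <= 1)."""
    from ensemblemap import BasePairProbabilityMatrix

    A = rng.random((n, n))
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 0.0)
    A = A / A.sum(axis=1).max()
    return BasePairProbabilityMatrix(sequence_id=seq_id, P=A)
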