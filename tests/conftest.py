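import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mlsakit import synthetic_data as sd
from mlsakit.seqio import GeneAlignment


@pytest.fixture(scope="session")
def genus_scale_bundle():
    """One default-configuration fixture (23 strains, 9 species) shared by
    the tests that only read from it."""
    return sd.make_fixture(sd.SimulationConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_alignment(locus, n_strains, n_columns, rng, ids=None):
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    ids = ids or [f"s{i + 1}" for i in range(n_strains)]
    seqs = {
        sid: bytes(rng.choice(bases, size=n_columns)).decode()
        for sid in ids
    }
    return GeneAlignment(locus, seqs)
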