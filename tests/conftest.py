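import numpy as np
import pytest

from metacodon.seqcore import CdsCollection, CdsRecord, standard_code


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture()
def toy_collection():
    """Four short hand-written CDSs with known codon content."""
    records = [
        CdsRecord("g1", "ATGTTTTTCAAA"),        # M F F K
        CdsRecord("g2", "ATGCTGCTGGAA"),        # M L L E
        CdsRecord("g3", "ATGGGCGGAGGG"),        # M G G G
        CdsRecord("g4", "ATGAAAAAGTAA"),        # M K K stop
    ]
    return CdsCollection("toy", records)


def random_cds(rng: np.random.Generator, n_codons: int, code=None) -> str:
    """A random in-frame CDS built from sense codons only."""
    if code is None:
        code = standard_code()
    sense = list(code.sense_codons)
    return "".join(rng.choice(sense, size=n_codons))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
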