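import numpy as np
import pytest

from idrpred.kmers import build_kmer_table
from idrpred.seq_io import ProteinRecord
from idrpred.synth import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def tiny_corpus():
    """A small reproducible synthetic corpus (shared across tests)."""
    cfg = SynthConfig(n_proteins=8, length_range=(60, 90), seed=11)
    records, pssms = generate_corpus(cfg)
    return records, pssms


@pytest.fixture(scope="session")
def tiny_tables(tiny_corpus):
    records, _ = tiny_corpus
    return build_kmer_table(records, 2), build_kmer_table(records, 3)


@pytest.fixture()
def record_60():
    seq = "MKVLAEDTSGRPQNWYHCIF" * 3
    return ProteinRecord("p60", seq)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
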