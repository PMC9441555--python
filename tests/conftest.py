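import numpy as np
import pytest

from tcrbind.data_io import PairRecord, PairTable
from tcrbind.encoding import build_vocabulary, init_random_embeddings
from tcrbind.model import ModelConfig, init_model


@pytest.fixture(scope="session")
def residue_vocabs():
    return build_vocabulary("residue"), build_vocabulary("residue")


@pytest.fixture()
def toy_table():
    """Ten valid pairs over three peptides, one CDR3 shared across peptides."""
    recs = [
        PairRecord("CASSLGQAYEQYF", "GILGFVFTL", 1),
        PairRecord("CASSLGQAYEQYF", "NLVPMVATV", 1),
        PairRecord("CASRPGLAGGRPEQYF", "NLVPMVATV", 1),
        PairRecord("CASSIRSSYEQYF", "GILGFVFTL", 1),
        PairRecord("CASSPGTGGYGYTF", "GLCTLVAML", 1),
        PairRecord("CASSQDRGRYGYTF", "GLCTLVAML", 1),
        PairRecord("CASSYSTGDEQFF", "GILGFVFTL", 1),
        PairRecord("CASSFGREQYF", "NLVPMVATV", 1),
        PairRecord("CASSPLSGGTDTQYF", "GLCTLVAML", 1),
        PairRecord("CASSALASYNEQFF", "GILGFVFTL", 1),
    ]
    return PairTable(records=recs)


@pytest.fixture(scope="session")
def tiny_model(residue_vocabs):
    """A small but non-degenerate model for shape/behaviour tests."""
    vt, vp = residue_vocabs
    cfg = ModelConfig(
        embed_dim=8, lstm_hidden=6, dropout_rate=0.0, pep_hidden=(10,),
        clf_hidden=(7,), attn_input="hidden", seed=42,
    )
    te = init_random_embeddings(vt, 8, seed=1)
    pe = init_random_embeddings(vp, 8, seed=2)
    return init_model(cfg, te, pe)


@pytest.fixture(scope="session")
def default_model(residue_vocabs):
    """Default-configuration model (embed 70, BiLSTM 80, one layer)."""
    vt, vp = residue_vocabs
    cfg = ModelConfig(seed=42)
    te = init_random_embeddings(vt, 70, seed=1)
    pe = init_random_embeddings(vp, 70, seed=2)
    return init_model(cfg, te, pe)


def random_records(rng: np.random.Generator, n: int, label_rng=None):
    """Random valid pair records (CDR3 11-18 residues, 9-mer peptides)."""
    from tcrbind.data_io import AA_ALPHABET

    alpha = np.array(list(AA_ALPHABET))
    recs = []
    for _ in range(n):
        L = int(rng.integers(11, 19))
        cdr3 = "".join(rng.choice(alpha, size=L))
        pep = "".join(rng.choice(alpha, size=9))
        lab = int(rng.integers(0, 2))
        recs.append(PairRecord(cdr3, pep, lab))
    return recs
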