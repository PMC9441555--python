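"""Sequence tokenization, padding and embedding for CDR3/peptide inputs.

Two token granularities are supported: single residues (character level,
21-token vocabulary: 20 amino acids plus the pad placeholder "X") and
overlapping amino-acid triplets ("words" of three consecutive residues,
placeholder "XXX").  Sequences are truncated/right-padded to fixed lengths —
18 residues for CDR3 and 9 for peptides (16 and 7 at triplet granularity, the
same residue span).  Embeddings are either small random initialisations,
trained end-to-end with the classifier, or skip-gram word vectors pre-trained
on a CDR3 corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import AA_ALPHABET, PairRecord

__all__ = [
    "CDR3_MAX_RESIDUES",
    "PEPTIDE_MAX_RESIDUES",
    "Vocabulary",
    "EmbeddingTable",
    "EncodedBatch",
    "EncodingError",
    "build_vocabulary",
    "tokenize",
    "pad_or_truncate",
    "init_random_embeddings",
    "train_word_embeddings",
    "encode_batch",
    "max_len_for",
    "save_word_vectors",
    "load_word_vectors",
]

CDR3_MAX_RESIDUES = 18
PEPTIDE_MAX_RESIDUES = 9

_PLACEHOLDER = {"residue": "X", "triplet": "XXX"}


class EncodingError(ValueError):
    """Fatal error while tokenizing or encoding sequences."""


def max_len_for(kind: str, granularity: str) -> int:
    """Fixed padded length for ``kind`` in {"cdr3", "peptide"} at a granularity.

    Triplet lengths are the residue maxima minus two, so both granularities
    cover the same residue span.
    """
    base = CDR3_MAX_RESIDUES if kind == "cdr3" else PEPTIDE_MAX_RESIDUES
    return base if granularity == "residue" else base - 2


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token inventory at residue or triplet granularity."""

    granularity: str
    tokens: tuple[str, ...]
    index_of: dict[str, int] = field(repr=False)

    @property
    def placeholder(self) -> str:
        return _PLACEHOLDER[self.granularity]

    @property
    def placeholder_index(self) -> int:
        return self.index_of[self.placeholder]

    def __len__(self) -> int:
        return len(self.tokens)


def build_vocabulary(granularity: str, corpus: list[str] | None = None) -> Vocabulary:
    """Build the token vocabulary for a granularity.

    Residue granularity yields the fixed 21-token vocabulary (20 amino acids
    alphabetically, placeholder "X" last).  Triplet granularity yields the
    placeholder "XXX" followed by the sorted unique overlapping 3-mers of the
    corpus (required, non-empty).
    """
    if granularity == "residue":
        tokens = tuple(AA_ALPHABET) + ("X",)
    elif granularity == "triplet":
        if not corpus:
            raise EncodingError("triplet vocabulary requires a non-empty corpus")
        kmers: set[str] = set()
        for seq in corpus:
            kmers.update(tokenize(seq, "triplet"))
        tokens = ("XXX",) + tuple(sorted(kmers))
    else:
        raise EncodingError(f"unknown granularity {granularity!r}")
    return Vocabulary(
        granularity=granularity,
        tokens=tokens,
        index_of={t: i for i, t in enumerate(tokens)},
    )


def tokenize(seq: str, granularity: str) -> list[str]:
    """Split a sequence into residue characters or overlapping 3-mers (stride 1)."""
    if granularity == "residue":
        return list(seq)
    if granularity == "triplet":
        if len(seq) < 3:
            raise EncodingError(f"sequence {seq!r} too short for triplet tokens")
        return [seq[i : i + 3] for i in range(len(seq) - 2)]
    raise EncodingError(f"unknown granularity {granularity!r}")


def pad_or_truncate(tokens: list[str], max_len: int, placeholder: str) -> list[str]:
    """Keep the first ``max_len`` tokens; right-pad shorter lists with the placeholder."""
    if max_len < 1:
        raise EncodingError("max_len must be >= 1")
    if len(tokens) >= max_len:
        return list(tokens[:max_len])
    return list(tokens) + [placeholder] * (max_len - len(tokens))


@dataclass
class EmbeddingTable:
    """A |V| x d matrix of token vectors tied to a :class:`Vocabulary`."""

    vocab: Vocabulary
    vectors: np.ndarray  # (|V|, d) float32
    origin: str  # "random" or "pretrained"

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float32)
        if self.vectors.shape[0] != len(self.vocab):
            raise EncodingError("one embedding row per vocabulary token required")
        if not np.all(np.isfinite(self.vectors)):
            raise EncodingError("embedding entries must be finite")


def init_random_embeddings(vocab: Vocabulary, d: int = 70, seed: int = 0) -> EmbeddingTable:
    """Uniform random embeddings on [-0.5/d, 0.5/d], reproducible by seed."""
    if d < 1:
        raise EncodingError("embedding dimension must be >= 1")
    rng = np.random.default_rng(seed)
    scale = 0.5 / d
    vectors = rng.uniform(-scale, scale, size=(len(vocab), d)).astype(np.float32)
    return EmbeddingTable(vocab=vocab, vectors=vectors, origin="random")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def train_word_embeddings(
    corpus: list[str],
    granularity: str = "residue",
    d: int = 70,
    window: int = 2,
    epochs: int = 10,
    seed: int = 0,
    negative: int = 5,
    learning_rate: float = 0.025,
) -> EmbeddingTable:
    """Pre-train token vectors on a sequence corpus with skip-gram negative sampling.

    Each sequence is one sentence of residue or triplet tokens.  Skip-gram
    with ``negative`` noise draws per context, a symmetric window and a
    linearly decaying learning rate; negatives are drawn from the unigram
    distribution raised to 3/4.  The placeholder token receives a zero vector
    and never participates in training (it does not occur in raw sequences).
    """
    if not corpus:
        raise EncodingError("empty embedding corpus")
    vocab = build_vocabulary(granularity, corpus if granularity == "triplet" else None)
    sentences = [
        [vocab.index_of[t] for t in tokenize(seq, granularity)] for seq in corpus
    ]
    counts = np.zeros(len(vocab), dtype=np.float64)
    for sent in sentences:
        for tok in sent:
            counts[tok] += 1
    if int((counts > 0).sum()) < 2:
        raise EncodingError("corpus yields fewer than 2 distinct tokens")

    rng = np.random.default_rng(seed)
    noise = counts**0.75
    noise[vocab.placeholder_index] = 0.0
    noise /= noise.sum()

    vec_in = ((rng.random((len(vocab), d)) - 0.5) / d).astype(np.float64)
    vec_out = np.zeros((len(vocab), d), dtype=np.float64)

    total_steps = max(1, epochs * sum(len(s) for s in sentences))
    step = 0
    for _epoch in range(epochs):
        for sent in sentences:
            for pos, center in enumerate(sent):
                lr = learning_rate * max(1e-4, 1.0 - step / total_steps)
                step += 1
                lo = max(0, pos - window)
                hi = min(len(sent), pos + window + 1)
                for cpos in range(lo, hi):
                    if cpos == pos:
                        continue
                    context = sent[cpos]
                    targets = np.concatenate(
                        ([context], rng.choice(len(vocab), size=negative, p=noise))
                    )
                    labels = np.zeros(len(targets))
                    labels[0] = 1.0
                    v = vec_in[center]
                    outs = vec_out[targets]
                    g = (_sigmoid(outs @ v) - labels) * lr
                    vec_in[center] -= g @ outs
                    vec_out[targets] -= np.outer(g, v)

    vec_in[vocab.placeholder_index] = 0.0
    return EmbeddingTable(
        vocab=vocab, vectors=vec_in.astype(np.float32), origin="pretrained"
    )


@dataclass
class EncodedBatch:
    """Fixed-length integer index matrices plus labels, ready for the network."""

    cdr3_idx: np.ndarray  # (B, L_t) int64
    pep_idx: np.ndarray  # (B, L_p) int64
    cdr3_len: np.ndarray  # (B,) true pre-pad token counts (capped at L_t)
    pep_len: np.ndarray  # (B,)
    labels: np.ndarray  # (B,) float32 in {0, 1}
    n_unknown: int = 0  # tokens mapped to the placeholder for being out-of-vocabulary

    def __len__(self) -> int:
        return int(self.cdr3_idx.shape[0])

    def subset(self, indices: np.ndarray) -> "EncodedBatch":
        idx = np.asarray(indices)
        return EncodedBatch(
            cdr3_idx=self.cdr3_idx[idx],
            pep_idx=self.pep_idx[idx],
            cdr3_len=self.cdr3_len[idx],
            pep_len=self.pep_len[idx],
            labels=self.labels[idx],
            n_unknown=self.n_unknown,
        )


def _encode_one(
    seq: str, vocab: Vocabulary, max_len: int
) -> tuple[list[int], int, int]:
    tokens = pad_or_truncate(tokenize(seq, vocab.granularity), max_len, vocab.placeholder)
    unknown = 0
    idx = []
    for t in tokens:
        j = vocab.index_of.get(t)
        if j is None:
            j = vocab.placeholder_index
            unknown += 1
        idx.append(j)
    true_len = min(
        len(tokenize(seq, vocab.granularity)),
        max_len,
    )
    return idx, true_len, unknown


def encode_batch(
    records: list[PairRecord],
    vocab_t: Vocabulary,
    vocab_p: Vocabulary,
    L_t: int | None = None,
    L_p: int | None = None,
) -> EncodedBatch:
    """Encode pair records into fixed-length index matrices.

    Out-of-vocabulary tokens (triplets unseen in the training corpus) map to
    the placeholder index and are counted in ``n_unknown``.
    """
    if not records:
        raise EncodingError("cannot encode an empty record list")
    L_t = L_t if L_t is not None else max_len_for("cdr3", vocab_t.granularity)
    L_p = L_p if L_p is not None else max_len_for("peptide", vocab_p.granularity)

    cdr3_rows, pep_rows, cdr3_lens, pep_lens = [], [], [], []
    unknown = 0
    for r in records:
        row, n, u = _encode_one(r.cdr3, vocab_t, L_t)
        cdr3_rows.append(row)
        cdr3_lens.append(n)
        unknown += u
        row, n, u = _encode_one(r.peptide, vocab_p, L_p)
        pep_rows.append(row)
        pep_lens.append(n)
        unknown += u
    return EncodedBatch(
        cdr3_idx=np.asarray(cdr3_rows, dtype=np.int64),
        pep_idx=np.asarray(pep_rows, dtype=np.int64),
        cdr3_len=np.asarray(cdr3_lens, dtype=np.int64),
        pep_len=np.asarray(pep_lens, dtype=np.int64),
        labels=np.asarray([r.label for r in records], dtype=np.float32),
        n_unknown=unknown,
    )


# ---------------------------------------------------------------------------
# Word-vector text format ("|V| d" header, then "token v1 ... vd" per line)


def save_word_vectors(table: EmbeddingTable, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table.vocab)} {table.dim}\n")
        for token, row in zip(table.vocab.tokens, table.vectors):
            fh.write(token + " " + " ".join(f"{v:.6g}" for v in row) + "\n")


def load_word_vectors(path: str, granularity: str) -> EmbeddingTable:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().split()
        n, d = int(header[0]), int(header[1])
        tokens, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            tokens.append(parts[0])
            rows.append([float(v) for v in parts[1 : d + 1]])
    if len(tokens) != n:
        raise EncodingError(f"word-vector file {path!r} is truncated")
    vocab = Vocabulary(
        granularity=granularity,
        tokens=tuple(tokens),
        index_of={t: i for i, t in enumerate(tokens)},
    )
    return EmbeddingTable(
        vocab=vocab, vectors=np.asarray(rows, dtype=np.float32), origin="pretrained"
    )
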