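"""Synthetic TCR-peptide repertoires with peptide-specific middle motifs.

Real CDR3β sequences share conserved N-/C-terminal scaffolds (typically
"CAS..." to "...F") while the middle region carries the antigen-binding
signal and differs sharply between peptides.  The generator emulates exactly
that structure: every positive CDR3 is built as::

    "CAS" + random residues + motif + random residues + "F"

where the motif is private to the paired peptide and each motif position is
substituted (to one of the 19 other residues) with probability
``mutation_rate``.  Negatives are produced by the shuffled-peptide sampler
from :mod:`tcrbind.data_io`.  Ground-truth motif coordinates are stored in
each positive record's ``meta`` field so attention-localization experiments
have an exact target.

The generator does not attempt to match real V(D)J recombination statistics,
database length distributions or MHC restriction — only the conserved
termini, the modal 11-18 residue length range and the motif structure the
classifier is meant to exploit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .data_io import AA_ALPHABET, PairRecord, PairTable, PairTableError, generate_negatives

__all__ = ["SynthConfig", "SynthError", "generate_repertoire", "ground_truth"]


class SynthError(ValueError):
    """Fatal synthetic-repertoire configuration error."""


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    ``mutation_rate`` is the per-motif-position substitution probability;
    ``negative_ratio`` of 0 emits positives only.  The minimum CDR3 length
    must leave room for the scaffold plus at least one random residue on each
    side of the motif, i.e. ``cdr3_len_range[0] >= motif_len + 6``.
    """

    n_peptides: int = 5
    pairs_per_peptide: int = 200
    peptide_len: int = 9
    cdr3_len_range: tuple[int, int] = (11, 18)
    motif_len: int = 4
    mutation_rate: float = 0.0
    negative_ratio: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cdr3_len_range
        if self.n_peptides < 1 or self.pairs_per_peptide < 1:
            raise SynthError("n_peptides and pairs_per_peptide must be >= 1")
        if not (0 < lo <= hi):
            raise SynthError("invalid cdr3_len_range")
        if lo < self.motif_len + 6:
            raise SynthError(
                "min cdr3 length must be >= motif_len + 6 "
                "(scaffold CAS...F plus >= 1 flanking residue per side)"
            )
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise SynthError("mutation_rate must lie in [0, 1]")
        if self.negative_ratio < 0:
            raise SynthError("negative_ratio must be >= 0")


_ALPHA = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_ALPHA[rng.integers(0, len(_ALPHA), size=length)]).decode()


def _mutate(rng: np.random.Generator, motif: str, rate: float) -> str:
    if rate == 0.0:
        return motif
    out = list(motif)
    for i, ch in enumerate(out):
        if rng.random() < rate:
            others = AA_ALPHABET.replace(ch, "")
            out[i] = others[rng.integers(len(others))]
    return "".join(out)


def generate_repertoire(cfg: SynthConfig, max_retries: int = 100) -> PairTable:
    """Draw a labelled pair table under the configured conditions.

    Positives carry ``meta`` of the form ``motif=<seq>;start=<i>;end=<j>``
    (half-open span of the implanted, possibly mutated, motif within the
    CDR3).  Exactly ``n_peptides * pairs_per_peptide`` positives are
    produced, with distinct CDR3s per peptide, plus negatives at
    ``negative_ratio``.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)

    for _ in range(max_retries):
        peptides = []
        seen = set()
        while len(peptides) < cfg.n_peptides:
            p = _random_seq(rng, cfg.peptide_len)
            if p not in seen:
                seen.add(p)
                peptides.append(p)
        motifs = [_random_seq(rng, cfg.motif_len) for _ in peptides]
        if len(set(motifs)) == len(motifs):
            break
    else:
        raise SynthError("could not draw distinct peptide motifs")

    lo, hi = cfg.cdr3_len_range
    records: list[PairRecord] = []
    for pep, motif in zip(peptides, motifs):
        used: set[str] = set()
        for _ in range(cfg.pairs_per_peptide):
            for _ in range(max_retries):
                L = int(rng.integers(lo, hi + 1))
                n_extra = L - 4 - cfg.motif_len  # residues outside scaffold+motif
                n_left = int(rng.integers(1, n_extra))  # >= 1 on each side
                n_right = n_extra - n_left
                implant = _mutate(rng, motif, cfg.mutation_rate)
                cdr3 = (
                    "CAS"
                    + _random_seq(rng, n_left)
                    + implant
                    + _random_seq(rng, n_right)
                    + "F"
                )
                if cdr3 not in used:
                    used.add(cdr3)
                    start = 3 + n_left
                    records.append(
                        PairRecord(
                            cdr3,
                            pep,
                            label=1,
                            meta=f"motif={motif};start={start};end={start + cfg.motif_len}",
                        )
                    )
                    break
            else:
                raise SynthError(
                    f"could not draw a fresh CDR3 for peptide {pep!r} "
                    f"after {max_retries} tries"
                )

    table = PairTable(records=records)
    if cfg.negative_ratio >= 1:
        neg_seed = int(np.random.default_rng([cfg.seed, 1]).integers(2**31 - 1))
        try:
            table = generate_negatives(table, cfg.negative_ratio, seed=neg_seed)
        except PairTableError as exc:
            raise SynthError(str(exc)) from exc
    return table


def ground_truth(cfg: SynthConfig, table: PairTable) -> dict:
    """Recover peptide->motif and per-CDR3 motif spans from a generated table.

    Returns ``{"motifs": {peptide: motif}, "spans": {cdr3: [start, end]}}``
    with half-open spans.  Spans are keyed by CDR3 string, so they also apply
    to negatives built from the same CDR3s.
    """
    motifs: dict[str, str] = {}
    spans: dict[str, list[int]] = {}
    for r in table.records:
        if r.label != 1 or not r.meta.startswith("motif="):
            continue
        fields = dict(kv.split("=", 1) for kv in r.meta.split(";"))
        motifs[r.peptide] = fields["motif"]
        spans[r.cdr3] = [int(fields["start"]), int(fields["end"])]
    if len(motifs) != cfg.n_peptides:
        raise SynthError(
            f"table carries motifs for {len(motifs)} peptides, "
            f"config expects {cfg.n_peptides}"
        )
    return {"motifs": motifs, "spans": spans}


def write_ground_truth(truth: dict, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)
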