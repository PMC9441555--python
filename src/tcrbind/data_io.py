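"""Reading, filtering, negative sampling and task splitting of TCR-peptide pair tables.

Pair tables hold labelled (CDR3β, peptide) amino-acid sequence pairs as
exported from curated TCR specificity databases (McPAS-TCR / VDJdb style
dumps).  This module implements the screening rules applied to such tables
(de-duplication, CDR3 length bounds, minimum per-peptide support), the
shuffled-peptide negative-pair generator, and the two evaluation splits:

* TPP-I  -- pair-disjoint k-fold cross-validation (TCRs and peptides may be
  shared between train and test, pairs may not);
* TPP-II -- repeated random splits that are *group-disjoint on the CDR3
  string*, so every test TCR is unseen during training.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AA_ALPHABET",
    "PairRecord",
    "PairTable",
    "FilterConfig",
    "SplitSpec",
    "PairTableError",
    "read_pair_table",
    "write_pair_table",
    "filter_pairs",
    "generate_negatives",
    "make_split_tpp1",
    "make_split_tpp2",
]

#: The 20 standard amino-acid one-letter codes (alphabetical).
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)


class PairTableError(ValueError):
    """Fatal error while reading, filtering or sampling a pair table."""


@dataclass(frozen=True)
class PairRecord:
    """One labelled CDR3β-peptide pair.

    ``label`` is 1 for a binder, 0 for a non-binder.  ``meta`` carries
    free-text provenance (the synthetic generator stores implanted-motif
    coordinates there).
    """

    cdr3: str
    peptide: str
    label: int = 1
    meta: str = ""

    def __post_init__(self) -> None:
        if not self.cdr3 or not self.peptide:
            raise PairTableError("cdr3 and peptide must be non-empty")
        if not _AA_SET.issuperset(self.cdr3):
            raise PairTableError(f"cdr3 {self.cdr3!r} contains non-standard residues")
        if not _AA_SET.issuperset(self.peptide):
            raise PairTableError(f"peptide {self.peptide!r} contains non-standard residues")
        if self.label not in (0, 1):
            raise PairTableError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class PairTable:
    """An ordered collection of :class:`PairRecord` plus per-rule removal counts."""

    records: list[PairRecord] = field(default_factory=list)
    filter_log: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, PairTable) and self.records == other.records

    @property
    def positives(self) -> list[PairRecord]:
        return [r for r in self.records if r.label == 1]

    @property
    def peptides(self) -> list[str]:
        """Distinct peptides in first-occurrence order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.peptide, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cdr3": [r.cdr3 for r in self.records],
                "peptide": [r.peptide for r in self.records],
                "label": [r.label for r in self.records],
                "meta": [r.meta for r in self.records],
            }
        )


@dataclass(frozen=True)
class FilterConfig:
    """Screening thresholds applied by :func:`filter_pairs`.

    Lengths are in amino-acid residues.  ``min_peptide_support`` is the
    minimum number of distinct positive CDR3 partners a peptide needs to be
    retained.  ``require_canonical`` additionally restricts CDR3s to the
    canonical C...F junction motif (off by default).
    """

    min_len: int = 6
    max_len: int = 30
    min_peptide_support: int = 50
    require_canonical: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise PairTableError("require 0 < min_len <= max_len")
        if self.min_peptide_support < 1:
            raise PairTableError("min_peptide_support must be >= 1")


@dataclass
class SplitSpec:
    """Fold/repeat assignments for one evaluation task.

    ``folds`` is a list of ``(train, validation, test)`` integer index arrays
    into the table the split was built from.
    """

    task: str  # "TPP-I" or "TPP-II"
    folds: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "task": self.task,
                "seed": self.seed,
                "folds": [
                    {
                        "train": np.asarray(tr).tolist(),
                        "validation": np.asarray(va).tolist(),
                        "test": np.asarray(te).tolist(),
                    }
                    for tr, va, te in self.folds
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitSpec":
        obj = json.loads(text)
        folds = [
            (
                np.asarray(f["train"], dtype=np.intp),
                np.asarray(f["validation"], dtype=np.intp),
                np.asarray(f["test"], dtype=np.intp),
            )
            for f in obj["folds"]
        ]
        return cls(task=obj["task"], folds=folds, seed=obj["seed"])


# ---------------------------------------------------------------------------
# I/O


def _detect_sep(path: str) -> str:
    name = str(path).lower()
    if name.endswith((".tsv", ".tab")):
        return "\t"
    if name.endswith(".csv"):
        return ","
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_pair_table(path: str, has_label: bool = True) -> PairTable:
    """Read a delimited pair table (CSV/TSV with ``cdr3``, ``peptide``[, ``label``]).

    Sequences are upper-cased; rows with missing fields, residues outside the
    20-letter alphabet, or a non-binary label are dropped and counted under
    ``filter_log["malformed"]``.  When ``has_label`` is false every row gets
    label 1.  An unreadable file or a file with zero valid rows is fatal.
    """
    try:
        df = pd.read_csv(path, sep=_detect_sep(path), dtype=str, keep_default_na=False)
    except (OSError, pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise PairTableError(f"cannot read pair table {path!r}: {exc}") from exc

    cols = {c.strip().lower(): c for c in df.columns}
    for required in ("cdr3", "peptide"):
        if required not in cols:
            raise PairTableError(f"{path!r} lacks required column {required!r}")
    label_col = cols.get("label") if has_label else None
    meta_col = cols.get("meta")

    table = PairTable()
    for row in df.itertuples(index=False):
        row = row._asdict()
        cdr3 = str(row[cols["cdr3"]]).strip().upper()
        pep = str(row[cols["peptide"]]).strip().upper()
        if label_col is not None:
            raw = str(row[label_col]).strip()
            try:
                label = int(float(raw))
            except ValueError:
                label = -1
        else:
            label = 1
        meta = str(row[meta_col]).strip() if meta_col is not None else ""
        try:
            table.records.append(PairRecord(cdr3, pep, label, meta))
        except PairTableError:
            table.filter_log["malformed"] += 1
    if not table.records:
        raise PairTableError(
            f"{path!r} contains no valid rows "
            f"({table.filter_log['malformed']} malformed rows)"
        )
    return table


def write_pair_table(table: PairTable, path: str) -> None:
    """Write a pair table as delimited text with header ``cdr3,peptide,label[,meta]``.

    The delimiter follows the file extension (tab for .tsv/.tab, comma
    otherwise).  The ``meta`` column is emitted only when some record carries
    metadata, so plain tables round-trip byte-identically.
    """
    df = table.to_frame()
    if not df["meta"].astype(bool).any():
        df = df.drop(columns=["meta"])
    sep = "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","
    try:
        df.to_csv(path, sep=sep, index=False, lineterminator="\n")
    except OSError as exc:
        raise PairTableError(f"cannot write pair table {path!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# Filtering


def filter_pairs(table: PairTable, cfg: FilterConfig | None = None) -> PairTable:
    """Apply the screening rules, in order, returning a new table.

    1. drop exact duplicate (cdr3, peptide, label) records, then resolve
       label conflicts on the same (cdr3, peptide) by keeping the first
       occurrence (logged as ``label_conflict``);
    2. drop records whose CDR3 length falls outside [min_len, max_len]
       (and, when ``require_canonical``, CDR3s not matching C...F);
    3. drop records whose peptide is supported by fewer than
       ``min_peptide_support`` distinct positive CDR3 partners, with support
       counted after rules 1-2.

    Removing every record is fatal; the error carries the per-rule counts.
    """
    cfg = cfg or FilterConfig()
    log = Counter(table.filter_log)

    seen_exact: set[tuple[str, str, int]] = set()
    seen_pair: dict[tuple[str, str], int] = {}
    stage1: list[PairRecord] = []
    for r in table.records:
        key = (r.cdr3, r.peptide, r.label)
        if key in seen_exact:
            log["duplicate"] += 1
            continue
        pair = (r.cdr3, r.peptide)
        if pair in seen_pair and seen_pair[pair] != r.label:
            log["label_conflict"] += 1
            continue
        seen_exact.add(key)
        seen_pair[pair] = r.label
        stage1.append(r)

    stage2: list[PairRecord] = []
    for r in stage1:
        if not (cfg.min_len <= len(r.cdr3) <= cfg.max_len):
            log["length"] += 1
            continue
        if cfg.require_canonical and not (r.cdr3[0] == "C" and r.cdr3[-1] == "F"):
            log["non_canonical"] += 1
            continue
        stage2.append(r)

    support: dict[str, set[str]] = {}
    for r in stage2:
        if r.label == 1:
            support.setdefault(r.peptide, set()).add(r.cdr3)
    kept: list[PairRecord] = []
    for r in stage2:
        if len(support.get(r.peptide, ())) < cfg.min_peptide_support:
            log["peptide_support"] += 1
            continue
        kept.append(r)

    if not kept:
        raise PairTableError(f"all records removed by filtering: {dict(log)}")
    return PairTable(records=kept, filter_log=log)


# ---------------------------------------------------------------------------
# Negative sampling


def generate_negatives(
    table: PairTable, ratio: int, seed: int, max_retries: int = 1000
) -> PairTable:
    """Augment a positives-only table with shuffled-peptide negative pairs.

    Each negative keeps a positive record's CDR3 and replaces the peptide by
    one drawn uniformly from the table's *other* peptides.  Candidates that
    collide with a positive pair or an already-emitted negative are redrawn
    (at most ``max_retries`` times, then fatal).  Exactly
    ``ratio x n_positives`` negatives are appended after the positives;
    output is reproducible for a fixed seed.
    """
    if any(r.label != 1 for r in table.records):
        raise PairTableError("generate_negatives expects a positives-only table")
    if ratio < 1:
        raise PairTableError("ratio must be a positive integer")
    if ratio > 15:
        warnings.warn(
            f"negative:positive ratio {ratio}:1 is outside the studied 1:1-15:1 range",
            stacklevel=2,
        )
    peptides = table.peptides
    if len(peptides) < 2:
        raise PairTableError("need at least 2 distinct peptides to sample negatives")

    rng = np.random.default_rng(seed)
    positive_pairs = {(r.cdr3, r.peptide) for r in table.records}
    emitted: set[tuple[str, str]] = set()
    negatives: list[PairRecord] = []
    for rec in table.records:
        others = [p for p in peptides if p != rec.peptide]
        for _ in range(ratio):
            for _ in range(max_retries):
                cand = (rec.cdr3, others[rng.integers(len(others))])
                if cand not in positive_pairs and cand not in emitted:
                    emitted.add(cand)
                    negatives.append(
                        PairRecord(cand[0], cand[1], label=0, meta="negative")
                    )
                    break
            else:
                raise PairTableError(
                    f"retry budget exhausted sampling a negative for cdr3 {rec.cdr3!r}"
                )
    return PairTable(
        records=list(table.records) + negatives, filter_log=Counter(table.filter_log)
    )


# ---------------------------------------------------------------------------
# Splits


def _stratified_quarter(
    indices: np.ndarray, labels: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split ``indices`` 3/4 train : 1/4 validation, stratified by label."""
    train: list[int] = []
    val: list[int] = []
    for lab in np.unique(labels):
        grp = indices[labels == lab]
        grp = grp[rng.permutation(len(grp))]
        n_val = len(grp) // 4
        val.extend(grp[:n_val])
        train.extend(grp[n_val:])
    return np.sort(np.asarray(train, dtype=np.intp)), np.sort(
        np.asarray(val, dtype=np.intp)
    )


def make_split_tpp1(table: PairTable, k: int = 5, seed: int = 0) -> SplitSpec:
    """Pair-disjoint k-fold cross-validation split (TPP-I).

    Records are shuffled and cut into ``k`` folds whose sizes differ by at
    most one.  For each fold the fold itself is the test set and the
    remainder is split 3/4 train : 1/4 validation, stratified by label.
    """
    n = len(table)
    if k < 2:
        raise PairTableError("k must be >= 2")
    if k > n:
        raise PairTableError(f"k={k} exceeds the {n} available records")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_chunks = np.array_split(order, k)
    labels = np.array([r.label for r in table.records])
    folds = []
    for chunk in fold_chunks:
        test = np.sort(chunk.astype(np.intp))
        rest = np.setdiff1d(np.arange(n, dtype=np.intp), test)
        train, val = _stratified_quarter(rest, labels[rest], rng)
        folds.append((train, val, test))
    return SplitSpec(task="TPP-I", folds=folds, seed=seed)


def make_split_tpp2(
    table: PairTable,
    train_fraction: float = 0.8,
    n_repeats: int = 30,
    seed: int = 0,
) -> SplitSpec:
    """Repeated CDR3-group-disjoint splits (TPP-II, unseen-TCR generalisation).

    For every repeat, distinct CDR3 strings are shuffled and assigned whole
    to the train side greedily until the train-side record count reaches
    ``train_fraction`` of the table; the remaining groups form the test set.
    One quarter of train-side records (stratified by label) becomes
    validation.  No CDR3 string ever appears on both sides of a repeat.
    """
    if not (0.0 < train_fraction < 1.0):
        raise PairTableError("train_fraction must lie in (0, 1)")
    if n_repeats < 1:
        raise PairTableError("n_repeats must be >= 1")
    n = len(table)
    groups: dict[str, list[int]] = {}
    for i, r in enumerate(table.records):
        groups.setdefault(r.cdr3, []).append(i)
    if len(groups) < 2:
        raise PairTableError("need at least 2 distinct cdr3 groups for TPP-II")
    group_keys = list(groups)
    labels = np.array([r.label for r in table.records])
    quota = int(round(train_fraction * n))

    folds = []
    for rep in range(n_repeats):
        rng = np.random.default_rng([seed, rep])
        order = rng.permutation(len(group_keys))
        train_side: list[int] = []
        test_side: list[int] = []
        for gi in order:
            members = groups[group_keys[gi]]
            if len(train_side) < quota:
                train_side.extend(members)
            else:
                test_side.extend(members)
        if not test_side:  # quota swallowed everything; move the last group over
            last = groups[group_keys[order[-1]]]
            train_side = train_side[: -len(last)]
            test_side = last
        train_side_arr = np.asarray(sorted(train_side), dtype=np.intp)
        train, val = _stratified_quarter(train_side_arr, labels[train_side_arr], rng)
        folds.append((train, val, np.asarray(sorted(test_side), dtype=np.intp)))
    return SplitSpec(task="TPP-II", folds=folds, seed=seed)
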