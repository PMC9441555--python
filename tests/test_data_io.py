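"""Pair-table I/O, screening rules, negative sampling and task splits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcrbind.data_io import (
    FilterConfig,
    PairRecord,
    PairTable,
    PairTableError,
    SplitSpec,
    filter_pairs,
    generate_negatives,
    make_split_tpp1,
    make_split_tpp2,
    read_pair_table,
    write_pair_table,
)


class TestReadWrite:
    def test_non_alphabet_rows_are_dropped_and_logged(self, tmp_path):
        p = tmp_path / "pairs.csv"
        p.write_text(
            "cdr3,peptide,label\n"
            "CASSLGQAYEQYF,GILGFVFTL,1\n"
            "CABSLGQAYEQYF,GILGFVFTL,1\n"  # B is not a standard residue
            "CASSIRSSYEQYF,NLVPMVATV,0\n"
        )
        table = read_pair_table(p)
        assert len(table) == 2
        assert table.filter_log["malformed"] == 1

    def test_empty_file_is_fatal(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(PairTableError):
            read_pair_table(p)

    def test_all_malformed_is_fatal_with_count(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("cdr3,peptide,label\nCAB1,GILGFVFTL,1\n")
        with pytest.raises(PairTableError, match="1 malformed"):
            read_pair_table(p)

    def test_missing_label_column_defaults_to_positive(self, tmp_path):
        p = tmp_path / "pairs.csv"
        p.write_text("cdr3,peptide\nCASSLGQAYEQYF,GILGFVFTL\n")
        table = read_pair_table(p, has_label=False)
        assert table.records[0].label == 1

    @pytest.mark.parametrize("ext", ["csv", "tsv"])
    def test_round_trip(self, toy_table, tmp_path, ext):
        path = tmp_path / f"pairs.{ext}"
        write_pair_table(toy_table, path)
        assert read_pair_table(path) == toy_table

    def test_lowercase_input_is_uppercased(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("cdr3\tpeptide\tlabel\ncasslgqayeqyf\tgilgfvftl\t1\n")
        assert read_pair_table(p).records[0].cdr3 == "CASSLGQAYEQYF"

    def test_empty_table_writes_header_only(self, tmp_path):
        path = tmp_path / "empty_out.csv"
        write_pair_table(PairTable(), path)
        assert path.read_text() == "cdr3,peptide,label\n"

    def test_missing_directory_is_fatal(self, toy_table, tmp_path):
        with pytest.raises(PairTableError):
            write_pair_table(toy_table, tmp_path / "no" / "such" / "dir.csv")


class TestFilterPairs:
    CFG = FilterConfig(min_peptide_support=1)

    @pytest.mark.parametrize("bad_len", [5, 31])
    def test_length_bounds(self, bad_len):
        bad = PairRecord("A" * bad_len, "GILGFVFTL", 1)
        ok = PairRecord("CASSLGQAYEQYF", "GILGFVFTL", 1)
        out = filter_pairs(PairTable(records=[bad, ok]), self.CFG)
        assert out.records == [ok]
        assert out.filter_log["length"] == 1

    def test_exact_duplicate_keeps_one(self):
        r = PairRecord("CASSLGQAYEQYF", "GILGFVFTL", 1)
        out = filter_pairs(PairTable(records=[r, r]), self.CFG)
        assert len(out) == 1
        assert out.filter_log["duplicate"] == 1

    def test_label_conflict_keeps_first_occurrence(self):
        a = PairRecord("CASSLGQAYEQYF", "GILGFVFTL", 1)
        b = PairRecord("CASSLGQAYEQYF", "GILGFVFTL", 0)
        out = filter_pairs(PairTable(records=[a, b]), self.CFG)
        assert out.records == [a]
        assert out.filter_log["label_conflict"] == 1

    def test_peptide_support_threshold(self):
        """P1 has 60 distinct positive partners, P2 has 3; only P1 survives."""
        recs = [PairRecord(f"CASS{i:02d}".replace("0", "G").replace("1", "A")
                           .replace("2", "S").replace("3", "T").replace("4", "V")
                           .replace("5", "L").replace("6", "I").replace("7", "P")
                           .replace("8", "Y").replace("9", "W") + "EQYF",
                           "GILGFVFTL", 1) for i in range(60)]
        recs += [PairRecord("CASSLGQAYEQY" + aa, "NLVPMVATV", 1) for aa in "FWY"]
        out = filter_pairs(
            PairTable(records=recs), FilterConfig(min_peptide_support=50)
        )
        assert len(out) == 60
        assert out.filter_log["peptide_support"] == 3
        assert all(r.peptide == "GILGFVFTL" for r in out.records)

    def test_canonical_flag_default_off(self):
        non_canon = PairRecord("ASSLGQAYEQY", "GILGFVFTL", 1)
        assert filter_pairs(PairTable(records=[non_canon]), self.CFG).records == [non_canon]
        strict = FilterConfig(min_peptide_support=1, require_canonical=True)
        with pytest.raises(PairTableError):
            filter_pairs(PairTable(records=[non_canon]), strict)

    def test_idempotent(self, toy_table):
        cfg = FilterConfig(min_peptide_support=2)
        once = filter_pairs(toy_table, cfg)
        twice = filter_pairs(once, cfg)
        assert twice.records == once.records

    def test_all_removed_is_fatal(self):
        with pytest.raises(PairTableError, match="length"):
            filter_pairs(PairTable(records=[PairRecord("CASSF", "GILGFVFTL", 1)]),
                         self.CFG)


class TestGenerateNegatives:
    def _positives(self):
        return PairTable(records=[
            PairRecord("CASSLGQAYEQYF", "GILGFVFTL", 1),
            PairRecord("CASSIRSSYEQYF", "NLVPMVATV", 1),
            PairRecord("CASSPGTGGYGYTF", "GLCTLVAML", 1),
            PairRecord("CASSFGREQYF", "GILGFVFTL", 1),
        ])

    def test_counts_and_disjointness(self):
        out = generate_negatives(self._positives(), ratio=2, seed=0)
        pos = [r for r in out.records if r.label == 1]
        neg = [r for r in out.records if r.label == 0]
        assert (len(pos), len(neg)) == (4, 8)
        assert not {(r.cdr3, r.peptide) for r in neg} & {(r.cdr3, r.peptide) for r in pos}

    @staticmethod
    def _wide_table(n_peptides=20):
        """One positive per peptide; every cdr3 has many candidate negatives."""
        peps = [f"GILGFVFT{aa}" for aa in "ACDEFGHIKLMNPQRSTVWY"[:n_peptides]]
        return PairTable(records=[
            PairRecord(f"CASSLGQ{aa}YEQYF", pep, 1)
            for aa, pep in zip("ACDEFGHIKLMNPQRSTVWY", peps)
        ])

    def test_ratio_one_matches_positive_count(self):
        table = self._wide_table()
        out = generate_negatives(table, ratio=1, seed=3)
        assert sum(r.label == 0 for r in out.records) == len(table)

    def test_seed_reproducibility_is_byte_identical(self, tmp_path):
        table = self._wide_table()
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_pair_table(generate_negatives(table, 3, seed=11), a)
        write_pair_table(generate_negatives(table, 3, seed=11), b)
        assert a.read_bytes() == b.read_bytes()

    def test_single_peptide_is_fatal(self):
        table = PairTable(records=[PairRecord("CASSLGQAYEQYF", "GILGFVFTL", 1)])
        with pytest.raises(PairTableError):
            generate_negatives(table, 1, seed=0)

    def test_mixed_label_input_rejected(self):
        table = PairTable(records=[PairRecord("CASSLGQAYEQYF", "GILGFVFTL", 0)])
        with pytest.raises(PairTableError):
            generate_negatives(table, 1, seed=0)

    def test_ratio_above_fifteen_warns(self):
        with pytest.warns(UserWarning):
            generate_negatives(self._wide_table(), 16, seed=0)

    def test_exhausted_retry_budget_names_cdr3(self):
        # 1 cdr3 x 2 peptides, both pairs positive: no negative is possible
        table = PairTable(records=[
            PairRecord("CASSLGQAYEQYF", "GILGFVFTL", 1),
            PairRecord("CASSLGQAYEQYF", "NLVPMVATV", 1),
        ])
        with pytest.raises(PairTableError, match="CASSLGQAYEQYF"):
            generate_negatives(table, 1, seed=0, max_retries=20)


class TestSplits:
    def _table(self, n=100, n_cdr3=None, rng_seed=0):
        from conftest import random_records

        rng = np.random.default_rng(rng_seed)
        recs = random_records(rng, n)
        if n_cdr3 is not None:  # force shared cdr3 groups
            pool = [r.cdr3 for r in recs[:n_cdr3]]
            recs = [
                PairRecord(pool[i % n_cdr3], r.peptide, r.label)
                for i, r in enumerate(recs)
            ]
        return PairTable(records=recs)

    def test_tpp1_fold_sizes_and_partition(self):
        table = self._table(100)
        split = make_split_tpp1(table, k=5, seed=1)
        tests = [te for _, _, te in split.folds]
        assert [len(t) for t in tests] == [20] * 5
        union = np.sort(np.concatenate(tests))
        assert np.array_equal(union, np.arange(100))
        for tr, va, te in split.folds:
            assert len(tr) + len(va) + len(te) == 100
            assert not set(tr) & set(va) and not set(tr) & set(te)
            # inner split is ~3/4 train, 1/4 validation
            assert abs(len(va) - 20) <= 2

    def test_tpp1_deterministic(self):
        table = self._table(57)
        a = make_split_tpp1(table, k=5, seed=9)
        b = make_split_tpp1(table, k=5, seed=9)
        for (t1, v1, s1), (t2, v2, s2) in zip(a.folds, b.folds):
            assert np.array_equal(t1, t2) and np.array_equal(v1, v2) and np.array_equal(s1, s2)

    def test_tpp1_k_larger_than_table_is_fatal(self):
        with pytest.raises(PairTableError):
            make_split_tpp1(self._table(3), k=5, seed=0)

    def test_tpp2_group_disjoint_every_repeat(self):
        table = self._table(120, n_cdr3=30)
        split = make_split_tpp2(table, n_repeats=10, seed=4)
        for tr, va, te in split.folds:
            side = {table.records[i].cdr3 for i in np.concatenate([tr, va])}
            test = {table.records[i].cdr3 for i in te}
            assert not side & test

    def test_tpp2_group_atomicity(self):
        recs = [PairRecord("CASSLGQAYEQYF", f"GILGFVFT{aa}", 1) for aa in "LVAMKRSTYW"]
        recs += [PairRecord(f"CASSIRSSYEQY{aa}", "NLVPMVATV", 1) for aa in "FLVAMKRSTW"]
        split = make_split_tpp2(PairTable(records=recs), n_repeats=5, seed=0)
        shared = [i for i, r in enumerate(recs) if r.cdr3 == "CASSLGQAYEQYF"]
        for tr, va, te in split.folds:
            train_side = set(tr) | set(va)
            assert set(shared) <= train_side or set(shared) <= set(te)

    def test_tpp2_repeats_are_distinct_but_reproducible(self):
        table = self._table(150, n_cdr3=60)
        a = make_split_tpp2(table, n_repeats=30, seed=2)
        b = make_split_tpp2(table, n_repeats=30, seed=2)
        assert len(a.folds) == 30
        for (t1, _, s1), (t2, _, s2) in zip(a.folds, b.folds):
            assert np.array_equal(t1, t2) and np.array_equal(s1, s2)
        test_sets = {tuple(te.tolist()) for _, _, te in a.folds}
        assert len(test_sets) > 1  # repeats differ from each other

    def test_tpp2_needs_two_groups(self):
        recs = [PairRecord("CASSLGQAYEQYF", f"GILGFVFT{aa}", 1) for aa in "LV"]
        with pytest.raises(PairTableError):
            make_split_tpp2(PairTable(records=recs), n_repeats=2, seed=0)

    def test_split_spec_json_round_trip(self):
        split = make_split_tpp1(self._table(30), k=3, seed=5)
        back = SplitSpec.from_json(split.to_json())
        assert back.task == split.task and back.seed == split.seed
        for (a1, b1, c1), (a2, b2, c2) in zip(split.folds, back.folds):
            assert np.array_equal(a1, a2) and np.array_equal(b1, b2) and np.array_equal(c1, c2)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    ratio=st.integers(min_value=1, max_value=5),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_negative_count_invariant(ratio, seed):
    """|negatives| == ratio * |positives| and negatives never collide with positives."""
    peps = [f"NLVPMVAT{aa}" for aa in "ACDEFGHIKL"]  # 10 peptides, 1 positive each
    recs = [
        PairRecord(f"CASSLGQ{aa}YEQYF", pep, 1)
        for aa, pep in zip("ACDEFGHIKL", peps)
    ]
    out = generate_negatives(PairTable(records=recs), ratio, seed)
    neg = [(r.cdr3, r.peptide) for r in out.records if r.label == 0]
    assert len(neg) == ratio * len(recs)
    assert len(set(neg)) == len(neg)
    assert not set(neg) & {(r.cdr3, r.peptide) for r in recs}
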