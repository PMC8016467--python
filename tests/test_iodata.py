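"""Dataset I/O, unit conversion, binarization and split integrity."""

import numpy as np
import pytest

from dtikit import iodata

SEQ = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"


def write_tsv(path, rows, header="smiles\ttarget_sequence\tlabel"):
    path.write_text(header + "\n" + "".join(r + "\n" for r in rows))


class TestPairsTable:
    def test_duplicate_rows_are_deduplicated(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        write_tsv(p, [f"CCO\t{SEQ}\t7.1", f"CCN\t{SEQ}\t6.2", f"CCO\t{SEQ}\t7.1"])
        ds = iodata.read_pairs_table(p)
        assert len(ds.compounds) == 2
        assert len(ds.proteins) == 1
        assert len(ds) == 2
        assert ds.skip_report["duplicate_pairs"] == 1

    def test_header_only_gives_empty_dataset(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        write_tsv(p, [])
        ds = iodata.read_pairs_table(p)
        assert len(ds) == 0

    def test_invalid_smiles_row_skipped_and_counted(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        write_tsv(p, [f"C1CC\t{SEQ}\t5.0", f"CCO\t{SEQ}\t7.0"])
        ds = iodata.read_pairs_table(p)
        assert len(ds) == 1
        assert ds.skip_report["invalid_smiles"] == 1

    def test_missing_column_is_configuration_error(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("smiles\tlabel\nCCO\t7.0\n")
        with pytest.raises(KeyError, match="target_sequence"):
            iodata.read_pairs_table(p)

    def test_roundtrip_reproduces_pairs_and_labels_exactly(self, tmp_path, small_dataset):
        p = tmp_path / "rt.tsv"
        iodata.write_pairs_table(small_dataset, p)
        back = iodata.read_pairs_table(p)
        assert list(back.triples()) == list(small_dataset.triples())

    def test_custom_column_map(self, tmp_path):
        p = tmp_path / "pairs.csv"
        p.write_text(f"drug,prot,affinity\nCCO,{SEQ},7.0\n")
        ds = iodata.read_pairs_table(
            p, {"smiles": "drug", "sequence": "prot", "label": "affinity"})
        assert len(ds) == 1


class TestAffinityMatrix:
    def _write(self, tmp_path, drugs, seqs, matrix):
        d, t, m = tmp_path / "d.txt", tmp_path / "t.txt", tmp_path / "m.tsv"
        d.write_text("".join(s + "\n" for s in drugs))
        t.write_text("".join(s + "\n" for s in seqs))
        m.write_text("".join("\t".join(r) + "\n" for r in matrix))
        return d, t, m

    def test_missing_cell_dropped(self, tmp_path):
        args = self._write(tmp_path, ["CCO", "CCN"], [SEQ, SEQ[::-1]],
                           [["7.0", "NaN"], ["5.5", "6.0"]])
        ds = iodata.read_affinity_matrix(*args)
        assert len(ds) == 3

    def test_fully_observed_row_major_labels(self, tmp_path):
        seqs = [SEQ, SEQ[::-1], SEQ[3:] + "AAA"]
        args = self._write(tmp_path, ["CCO", "CCN"], seqs,
                           [["1", "2", "3"], ["4", "5", "6"]])
        ds = iodata.read_affinity_matrix(*args)
        assert len(ds) == 6
        assert [lab for _, _, lab in ds.pairs] == [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]

    def test_empty_inputs_give_empty_dataset(self, tmp_path):
        args = self._write(tmp_path, [], [], [])
        assert len(iodata.read_affinity_matrix(*args)) == 0

    def test_dimension_mismatch_is_format_error(self, tmp_path):
        args = self._write(tmp_path, ["CCO"], [SEQ], [["1", "2"]])
        with pytest.raises(ValueError, match="cells"):
            iodata.read_affinity_matrix(*args)

    def test_fasta_targets_accepted(self, tmp_path):
        d = tmp_path / "d.txt"; d.write_text("CCO\n")
        t = tmp_path / "t.fasta"; t.write_text(f">p1\n{SEQ}\n")
        m = tmp_path / "m.tsv"; m.write_text("7.5\n")
        ds = iodata.read_affinity_matrix(d, t, m)
        assert len(ds) == 1 and ds.pairs[0][2] == 7.5


class TestFasta:
    def test_single_and_wrapped_records(self, tmp_path):
        p = tmp_path / "f.fasta"
        p.write_text(">p1 some description\nACDE\n>p2\nACD\nEFG\n")
        recs = iodata.read_fasta(p)
        assert [r.id for r in recs] == ["p1", "p2"]
        assert recs[0].sequence == "ACDE"
        assert recs[1].sequence == "ACDEFG"

    def test_illegal_characters_error_names_the_record(self, tmp_path):
        p = tmp_path / "f.fasta"
        p.write_text(">p1\nAC*DE\n")
        with pytest.raises(ValueError, match="p1"):
            iodata.read_fasta(p)

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "f.fasta"
        p.write_text("")
        assert iodata.read_fasta(p) == []


class TestPScale:
    def test_known_values(self):
        assert iodata.convert_affinity_to_pscale(1.0) == pytest.approx(9.0)
        assert iodata.convert_affinity_to_pscale(10_000.0) == pytest.approx(5.0)

    def test_strictly_decreasing(self):
        assert iodata.convert_affinity_to_pscale(10) > iodata.convert_affinity_to_pscale(100)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            iodata.convert_affinity_to_pscale(0.0)

    def test_inverse_roundtrip_over_wide_range(self):
        nm = np.logspace(-3, 6, 25)
        back = iodata.convert_pscale_to_affinity(iodata.convert_affinity_to_pscale(nm))
        assert np.allclose(back, nm, rtol=1e-12)


class TestBinarize:
    def test_ge_direction(self):
        assert iodata.binarize([5.0, 7.1, 9.0], 7.0, "ge") == [0, 1, 1]

    def test_le_direction_and_empty(self):
        assert iodata.binarize([5.0, 7.1], 7.0, "le") == [1, 0]
        assert iodata.binarize([], 7.0) == []

    def test_all_below_threshold(self):
        assert iodata.binarize([1.0, 2.0], 10.0) == [0, 0]


class TestDetectTask:
    @pytest.mark.parametrize("labels,expected", [
        ([0, 1, 1, 0], "classification"),
        ([5.0, 7.3], "regression"),
        ([0.0, 1.0, 0.5], "regression"),
    ])
    def test_detection(self, labels, expected):
        assert iodata.detect_task(labels) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            iodata.detect_task([])


class TestSplits:
    def test_random_split_sizes_and_conservation(self, small_dataset):
        sp = iodata.data_process(small_dataset, "random", (0.7, 0.1, 0.2), seed=42)
        n = len(small_dataset)
        assert sp.sizes == (n - int(0.1 * n) - int(0.2 * n), int(0.1 * n), int(0.2 * n))
        assert sum(sp.sizes) == n

    def test_same_seed_reproduces_split_exactly(self, small_dataset):
        a = iodata.data_process(small_dataset, "random", seed=5)
        b = iodata.data_process(small_dataset, "random", seed=5)
        assert list(a.train.triples()) == list(b.train.triples())
        assert list(a.test.triples()) == list(b.test.triples())

    @pytest.mark.parametrize("method,attr", [
        ("cold_drug", "compounds"), ("cold_protein", "proteins")])
    def test_cold_split_zero_entity_leakage(self, small_dataset, method, attr):
        sp = iodata.data_process(small_dataset, method, (0.5, 0.25, 0.25), seed=0)
        folds = [sp.train, sp.valid, sp.test]
        ids = [{rec.id for rec in getattr(f, attr)} for f in folds]
        # brute-force scan over all pairs in all folds
        for i in range(3):
            for j in range(i + 1, 3):
                assert not ids[i] & ids[j]
        assert sum(sp.sizes) == len(small_dataset)

    def test_union_of_folds_equals_input(self, small_dataset):
        sp = iodata.data_process(small_dataset, "cold_drug", (0.5, 0.25, 0.25), seed=2)
        got = sorted(
            t for f in (sp.train, sp.valid, sp.test) for t in f.triples())
        assert got == sorted(small_dataset.triples())

    def test_cold_split_with_too_few_entities_rejected(self):
        ds = iodata.InteractionDataset.from_triples(
            [("CCO", SEQ, 1.0), ("CCN", SEQ, 2.0)])
        with pytest.raises(ValueError, match="at least 3"):
            iodata.data_process(ds, "cold_protein", seed=0)

    def test_bad_fractions_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            iodata.data_process(small_dataset, "random", (0.5, 0.2, 0.2), seed=0)

    def test_unknown_method_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="unknown split method"):
            iodata.data_process(small_dataset, "scaffold", seed=0)
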