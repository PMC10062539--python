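import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddgcv import (
    MutationDataset,
    MutationRecord,
    ProteinRecord,
    read_fasta,
    read_mutation_table,
    summarize,
    validate_dataset,
    write_fasta,
    write_mutation_table,
)
from ddgcv.data_model import ConfigurationError, DataModelError, RowError

from conftest import ALPHABET_SEQ, make_toy_dataset


def _write(path, text):
    path.write_text(text)
    return path


CSV3 = """protein_id,position,wt,mut,ddg,temp,ph
1BNI,10,L,A,1.25,25,7.0
1BNI,10,L,G,-0.75,25,7.0
2LZM,3,K,R,0.0,30,6.5
"""


class TestReadMutationTable:
    def test_three_row_csv_identity(self, tmp_path):
        ds = read_mutation_table(_write(tmp_path / "m.csv", CSV3))
        assert len(ds) == 3
        assert [r.protein_id for r in ds] == ["1BNI", "1BNI", "2LZM"]
        first = ds.records[0]
        assert (first.position, first.wt_residue, first.mut_residue) == (10, "L", "A")
        assert first.ddg == 1.25 and first.temperature == 25.0 and first.ph == 7.0
        assert all(r.direction.value == "forward" for r in ds)

    def test_wt_equal_mut_rejected_with_row(self, tmp_path):
        bad = CSV3.replace("1BNI,10,L,G", "1BNI,10,L,L")
        with pytest.raises(RowError, match="row 1"):
            read_mutation_table(_write(tmp_path / "m.csv", bad))

    def test_missing_column_names_the_column(self, tmp_path):
        text = CSV3.replace("ddg", "energy")
        with pytest.raises(ConfigurationError, match="ddg"):
            read_mutation_table(_write(tmp_path / "m.csv", text))
        # configurable column mapping resolves it
        ds = read_mutation_table(_write(tmp_path / "m2.csv", text),
                                 columns={"ddg": "energy"})
        assert len(ds) == 3

    def test_unparseable_number_reports_row(self, tmp_path):
        bad = CSV3.replace("-0.75", "oops")
        with pytest.raises(RowError, match="row 1"):
            read_mutation_table(_write(tmp_path / "m.csv", bad))

    def test_flip_sign_negates_ddg(self, tmp_path):
        ds = read_mutation_table(_write(tmp_path / "m.csv", CSV3), flip_sign=True)
        assert [r.ddg for r in ds] == [-1.25, 0.75, 0.0]

    def test_missing_temp_rejected_unless_imputed(self, tmp_path):
        text = CSV3.replace("1BNI,10,L,G,-0.75,25,7.0",
                            "1BNI,10,L,G,-0.75,,7.0")
        p = _write(tmp_path / "m.csv", text)
        with pytest.raises(RowError, match="missing temperature or pH"):
            read_mutation_table(p)
        ds = read_mutation_table(p, impute_missing=True)
        # median of the two present temperatures 25 and 30
        assert ds.records[1].temperature == 27.5

    def test_round_trip_is_value_exact(self, tmp_path):
        ds = make_toy_dataset()
        # exercise non-representable decimals too
        out = tmp_path / "rt.tsv"
        write_mutation_table(ds, out)
        back = read_mutation_table(out)
        for a, b in zip(ds.records, back.records):
            assert a.ddg == b.ddg
            assert a.temperature == b.temperature
            assert a.ph == b.ph
            assert (a.protein_id, a.position, a.wt_residue, a.mut_residue,
                    a.direction) == (b.protein_id, b.position, b.wt_residue,
                                     b.mut_residue, b.direction)


class TestFasta:
    def test_two_record_round_trip_and_uppercasing(self, tmp_path):
        p = _write(tmp_path / "s.fasta",
                   ">P1 some description\nacde\nFGHI\n>P2\nMKVL\n")
        prots = read_fasta(p)
        assert set(prots) == {"P1", "P2"}
        assert prots["P1"].sequence == "ACDEFGHI"
        out = tmp_path / "o.fasta"
        write_fasta(prots, out)
        assert read_fasta(out)["P1"].sequence == "ACDEFGHI"

    def test_non_canonical_residue_identified(self, tmp_path):
        p = _write(tmp_path / "s.fasta", ">P1\nACDX\n")
        with pytest.raises(DataModelError, match=r"P1.*X"):
            read_fasta(p)

    def test_duplicate_id_rejected(self, tmp_path):
        p = _write(tmp_path / "s.fasta", ">P1\nAC\n>P1\nMK\n")
        with pytest.raises(DataModelError, match="duplicate"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(DataModelError):
            read_fasta(_write(tmp_path / "s.fasta", "\n"))


class TestValidation:
    def test_consistent_dataset_has_empty_report(self, toy_dataset):
        assert validate_dataset(toy_dataset) == []

    def test_position_out_of_range(self, toy_dataset):
        toy_dataset.records.append(
            MutationRecord("TOY1", 99, "L", "A", 0.1, 25.0, 7.0)
        )
        report = validate_dataset(toy_dataset)
        assert len(report) == 1
        assert report[0].kind == "position_out_of_range"
        assert report[0].record_index == 3

    def test_wt_mismatch(self, toy_dataset):
        # TOY1 position 3 is D, not E
        toy_dataset.records.append(
            MutationRecord("TOY1", 3, "E", "A", 0.1, 25.0, 7.0)
        )
        report = validate_dataset(toy_dataset)
        assert [v.kind for v in report] == ["wt_mismatch"]

    def test_missing_sequence_reported(self, toy_dataset):
        toy_dataset.records.append(
            MutationRecord("NOPE", 1, "A", "G", 0.1, 25.0, 7.0)
        )
        assert [v.kind for v in validate_dataset(toy_dataset)] == [
            "missing_sequence"
        ]


class TestSummarize:
    def test_toy_counts(self, toy_dataset):
        counts = summarize(toy_dataset)
        assert counts == {
            "n_records": 3, "n_proteins": 2, "n_stabilizing": 1,
            "n_neutral": 1, "n_destabilizing": 1,
        }

    def test_empty_dataset_all_zero(self):
        counts = summarize(MutationDataset())
        assert all(v == 0 for v in counts.values())

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), max_size=40))
    def test_sign_classes_partition_records(self, ddgs):
        seq = ALPHABET_SEQ
        prot = ProteinRecord("P", seq)
        recs = [
            MutationRecord("P", 1, "A", "G", d, 25.0, 7.0) for d in ddgs
        ]
        counts = summarize(MutationDataset(recs, {"P": prot}))
        assert (counts["n_stabilizing"] + counts["n_neutral"]
                + counts["n_destabilizing"]) == counts["n_records"] == len(ddgs)


class TestRecordInvariants:
    def test_wt_equals_mut_rejected(self):
        with pytest.raises(DataModelError):
            MutationRecord("P", 1, "A", "A", 0.0, 25.0, 7.0)

    @pytest.mark.parametrize("field,value", [
        ("ddg", math.nan), ("temperature", math.inf), ("ph", math.nan),
    ])
    def test_non_finite_values_rejected(self, field, value):
        kwargs = dict(protein_id="P", position=1, wt_residue="A",
                      mut_residue="G", ddg=0.0, temperature=25.0, ph=7.0)
        kwargs[field] = value
        with pytest.raises(DataModelError):
            MutationRecord(**kwargs)

    def test_sequence_with_non_canonical_residue_rejected(self):
        with pytest.raises(DataModelError, match="non-canonical"):
            ProteinRecord("P", "ACDB")
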