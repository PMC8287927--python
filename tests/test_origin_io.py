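import json

import pandas as pd
import pytest

from busscan import (
    OriginRecord,
    SearchParams,
    read_origins,
    read_results,
    results_to_table,
    revcomp,
    search_origin,
    write_results,
)
from busscan.io import RESULT_COLUMNS
from busscan.simulate import PlantSpec, generate_origin


def write_fasta(path, records):
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


class TestReadOrigins:
    def test_fasta_single_record_gets_default_motif(self, tmp_path):
        path = tmp_path / "one.fasta"
        write_fasta(path, [("NC_000001", "ACGT" * 25)])
        records = read_origins(path, "fasta")
        assert len(records) == 1
        assert records[0].id == "NC_000001"
        assert records[0].box_motif == "TTATCCACA"
        assert len(records[0].sequence) == 100

    def test_empty_fasta_warns_and_returns_empty(self, tmp_path, caplog):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with caplog.at_level("WARNING", logger="busscan"):
            assert read_origins(path, "fasta") == []
        assert "no origin records" in caplog.text

    def test_illegal_record_rejected_run_continues(self, tmp_path, caplog):
        path = tmp_path / "mixed.fasta"
        write_fasta(path, [("good", "ACGT" * 10), ("bad", "ACGU" * 10), ("good2", "AAAA" * 10)])
        with caplog.at_level("WARNING", logger="busscan"):
            records = read_origins(path, "fasta")
        assert [r.id for r in records] == ["good", "good2"]
        assert "rejecting record bad" in caplog.text

    def test_doric_table_with_species_specific_motif(self, tmp_path):
        path = tmp_path / "doric.tsv"
        pd.DataFrame(
            {
                "id": ["ORI1", "ORI2"],
                "organism": ["Bacillus subtilis", "Helicobacter pylori"],
                "lineage": ["Bacillota;Bacilli", ""],
                "sequence": ["acgt" * 30, "ACGT" * 30],
                "box_motif": ["TTATNCACA", ""],
            }
        ).to_csv(path, sep="\t", index=False)
        records = read_origins(path, "doric_table")
        assert records[0].box_motif == "TTATNCACA"  # species-specific passes through
        assert records[1].box_motif == "TTATCCACA"  # empty cell falls back to default
        assert records[0].lineage == ("Bacillota", "Bacilli")
        assert records[0].sequence.isupper()

    def test_doric_table_requires_id_and_sequence_columns(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"name": ["x"], "dna": ["ACGT"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="doric_table must name"):
            read_origins(path, "doric_table")

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_origins(tmp_path / "nope.fasta", "fasta")


class TestWriteResults:
    def test_empty_results_write_header_only(self, tmp_path):
        out = tmp_path / "res.tsv"
        write_results([], out, "tsv")
        table = read_results(out)
        assert list(table.columns) == RESULT_COLUMNS
        assert len(table) == 0

    def test_not_found_row_has_empty_fields(self, tmp_path):
        origin = OriginRecord(id="bare", sequence="CGGCCGCGGC" * 5)
        result = search_origin(origin)
        out = tmp_path / "res.tsv"
        write_results([result], out, "tsv")
        row = read_results(out).iloc[0]
        assert row["found"] == "False"
        assert row["box1_start"] == "" and row["spacer"] == ""

    def test_tsv_and_json_agree(self, tmp_path):
        spec = PlantSpec(seed=5, arrangement="sole", box1_mm=1, spacer=12, trio_count=4)
        record, _ = generate_origin(spec, origin_id="P1")
        res = search_origin(record)
        write_results([res], tmp_path / "r.tsv", "tsv")
        write_results([res], tmp_path / "r.json", "json")
        tsv_row = read_results(tmp_path / "r.tsv").iloc[0]
        json_row = json.loads((tmp_path / "r.json").read_text())[0]
        assert int(tsv_row["box1_start"]) == int(json_row["box1_start"])
        assert tsv_row["trios"] == json_row["trios"]

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_reported_coordinates_slice_back_to_reported_sequences(self, strand):
        spec = PlantSpec(
            seed=17, arrangement="tandem_down", box1_mm=1, box2_mm=3, strand=strand
        )
        record, _ = generate_origin(spec, origin_id="RT")
        res = search_origin(record)
        assert res.found
        row = results_to_table([res]).iloc[0]
        seq = record.sequence
        for prefix in ("box1", "box2", "trio"):
            start = int(row[f"{prefix}_start"])
            end = int(row[f"{prefix}_end"])
            assert seq[start - 1 : end] == row[f"{prefix}_seq"]
        # the motif-strand trios reconstruct from the forward slice
        trio_fwd = row["trio_seq"]
        joined = "".join(row["trios"].split(","))
        assert joined == (trio_fwd if row["strand"] == "+" else revcomp(trio_fwd))

    def test_planted_fixture_row_matches_ground_truth(self):
        spec = PlantSpec(seed=23, arrangement="sole", box1_mm=2, spacer=13, trio_count=6)
        record, truth = generate_origin(spec, origin_id="GT")
        row = results_to_table([search_origin(record)]).iloc[0]
        assert row["found"]
        assert int(row["spacer"]) == truth.spacer
        assert int(row["trio_count"]) == truth.trio_count
        assert int(row["box1_mm"]) == truth.ref_mm
        assert int(row["box1_start"]) - 1 == truth.ref_start  # plus strand, 1-based out

    def test_result_table_roundtrip_preserves_fields(self, tmp_path):
        specs = [
            PlantSpec(seed=31, arrangement="sole", spacer=10, trio_count=3),
            PlantSpec(seed=37, arrangement="tandem_up", box1_mm=2, box2_mm=0, spacer=8),
        ]
        results = [search_origin(generate_origin(s, origin_id=f"R{i}")[0]) for i, s in enumerate(specs)]
        out = tmp_path / "round.tsv"
        write_results(results, out)
        table = read_results(out)
        direct = results_to_table(results).astype(str)
        pd.testing.assert_frame_equal(table, direct)
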