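"""Dialect parsing, coordinate normalisation, merging and antisense flags."""

from __future__ import annotations

import random

import pytest

from circkit.dialects import ToolDialect, get_dialect
from circkit.importer import (
    merge_predictions,
    parse_tool_output,
    read_merged_tsv,
    write_merged_tsv,
)
from circkit.records import BsjRecord, ExperimentDesign

from conftest import make_model

GENERIC = get_dialect("generic")


def _write(tmp_path, text, name="pred.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestParseToolOutput:
    def test_generic_one_based_inclusive_row_maps_identically(self, tmp_path):
        p = _write(tmp_path, "chr1 + 100 500 gene1 12\n")
        (rec,) = parse_tool_output(p, GENERIC, "s1")
        assert (rec.chrom, rec.strand, rec.start_up_bse, rec.end_down_bse) == ("chr1", "+", 100, 500)
        assert rec.counts == {("generic", "s1"): 12}

    def test_zero_based_half_open_normalises_to_same_junction(self, tmp_path):
        d = ToolDialect(
            tool_name="generic",
            column_map=GENERIC.column_map,
            coordinate_base=0,
            end_convention="half_open",
            sep=None,
        )
        p = _write(tmp_path, "chr1 + 99 500 gene1 12\n")
        (rec,) = parse_tool_output(p, d, "s1")
        assert (rec.start_up_bse, rec.end_down_bse) == (100, 500)

    def test_minus_strand_row_stored_in_transcription_order(self, tmp_path):
        p = _write(tmp_path, "chr1 - 100 500 gene1 3\n")
        (rec,) = parse_tool_output(p, GENERIC, "s1")
        assert (rec.start_up_bse, rec.end_down_bse) == (500, 100)
        assert rec.circ_id == "gene1|-|chr1|500|100"

    def test_zero_count_rows_are_retained(self, tmp_path):
        p = _write(tmp_path, "chr1 + 100 500 gene1 0\n")
        assert len(parse_tool_output(p, GENERIC, "s1")) == 1

    def test_unknown_strand_is_a_hard_error_with_line_number(self, tmp_path):
        p = _write(tmp_path, "chr1 + 100 500 gene1 1\nchr1 * 1 2 g 1\n")
        with pytest.raises(ValueError, match=":2"):
            parse_tool_output(p, GENERIC, "s1")

    def test_malformed_row_is_a_hard_error_with_line_number(self, tmp_path):
        p = _write(tmp_path, "chr1 + notanumber 500 gene1 1\n")
        with pytest.raises(ValueError, match=":1"):
            parse_tool_output(p, GENERIC, "s1")

    def test_missing_gene_column_yields_dot_gene(self, tmp_path, caplog):
        d = get_dialect("circmarker")
        p = _write(tmp_path, "chr1\t100\t500\t+\t7\n")
        with caplog.at_level("WARNING"):
            (rec,) = parse_tool_output(p, d, "s1")
        assert rec.gene == "."
        assert "no gene column" in caplog.text

    def test_knife_junction_string_is_decoded(self, tmp_path):
        d = get_dialect("knife")
        p = _write(tmp_path, "chr2|gene9:150|gene9:900|reg|-\t21\n")
        (rec,) = parse_tool_output(p, d, "s1")
        assert rec.gene == "gene9"
        assert (rec.start_up_bse, rec.end_down_bse) == (900, 150)
        assert rec.counts == {("knife", "s1"): 21}

    def test_minus_strand_sequence_equals_revcomp_of_plus_extraction(self, tmp_path):
        # the transcription-order convention is what makes extraction
        # strand-symmetric: verified end to end in test_sequences
        p = _write(tmp_path, "chr1 - 100 500 gene1 1\nchr1 + 100 500 gene1 1\n")
        minus, plus = parse_tool_output(p, GENERIC, "s1")
        assert {minus.genomic_start, minus.genomic_end} == {plus.genomic_start, plus.genomic_end}


def _rec(counts=None, gene="g1", strand="+", chrom="chr1", s=100, e=500):
    return BsjRecord(
        gene=gene,
        strand=strand,
        chrom=chrom,
        start_up_bse=s if strand == "+" else e,
        end_down_bse=e if strand == "+" else s,
        counts=dict(counts or {}),
    )


class TestMerge:
    def test_same_junction_from_two_tools_merges_with_n_tools_two(self):
        a = _rec({("t1", "s1"): 5})
        b = _rec({("t2", "s1"): 7})
        merged = merge_predictions([("t1", "s1", [a]), ("t2", "s1", [b])])
        assert len(merged) == 1
        assert merged[0].n_tools == 2
        assert merged[0].total_count == 12

    def test_disjoint_junctions_stay_separate(self):
        a = _rec({("t1", "s1"): 5}, s=100, e=500)
        b = _rec({("t2", "s1"): 7}, s=700, e=900)
        merged = merge_predictions([("t1", "s1", [a]), ("t2", "s1", [b])])
        assert len(merged) == 2
        assert all(r.n_tools == 1 for r in merged)

    def test_merge_is_idempotent_and_order_invariant(self):
        rng = random.Random(3)
        recs = [
            _rec({(t, smp): rng.randrange(10)}, s=s, e=s + 200)
            for s in (100, 400, 800)
            for t in ("t1", "t2")
            for smp in ("s1", "s2")
        ]
        sets = [("t", "s", [r]) for r in recs]
        merged = merge_predictions(sets)
        again = merge_predictions([("x", "y", merged)])
        assert [r.key for r in again] == [r.key for r in merged]
        assert [r.counts for r in again] == [r.counts for r in merged]
        shuffled = list(sets)
        rng.shuffle(shuffled)
        merged2 = merge_predictions(shuffled)
        assert [r.key for r in merged2] == [r.key for r in merged]

    def test_total_read_count_is_conserved(self):
        rng = random.Random(9)
        sets = []
        total = 0
        for t in ("t1", "t2", "t3"):
            recs = []
            for s in (100, 300, 500, 900):
                c = rng.randrange(20)
                total += c
                recs.append(_rec({(t, "s1"): c}, s=s, e=s + 150))
            sets.append((t, "s1", recs))
        merged = merge_predictions(sets)
        assert sum(r.total_count for r in merged) == total

    def test_conflicting_gene_symbols_kept_as_distinct_records(self, caplog):
        a = _rec({("t1", "s1"): 5}, gene="g1")
        b = _rec({("t2", "s1"): 7}, gene="g2")
        with caplog.at_level("WARNING"):
            merged = merge_predictions([("t1", "s1", [a]), ("t2", "s1", [b])])
        assert len(merged) == 2
        assert "conflicting gene symbols" in caplog.text

    def test_geneless_record_adopts_unique_coordinate_match(self):
        named = _rec({("t1", "s1"): 5}, gene="g1")
        dot = _rec({("cm", "s1"): 9}, gene=".")
        merged = merge_predictions([("t1", "s1", [named]), ("cm", "s1", [dot])])
        assert len(merged) == 1
        assert merged[0].gene == "g1"
        assert merged[0].n_tools == 2

    def test_tsv_round_trip_preserves_records(self, tmp_path):
        recs = merge_predictions(
            [
                ("t1", "s1", [_rec({("t1", "s1"): 5})]),
                ("t2", "s2", [_rec({("t2", "s2"): 0})]),  # reported zero survives
                ("t1", "s1", [_rec({("t1", "s1"): 3}, gene="g2", strand="-", s=700, e=900)]),
            ]
        )
        path = tmp_path / "merged.tsv"
        write_merged_tsv(recs, path)
        back = read_merged_tsv(path)
        assert [r.key for r in back] == [r.key for r in recs]
        assert [r.counts for r in back] == [r.counts for r in recs]
        assert [r.n_tools for r in back] == [r.n_tools for r in recs]


class TestFlagAntisense:
    def test_strand_conflict_on_exon_boundaries_is_antisense(self):
        model = make_model(strand="+")
        rec = _rec({("t", "s"): 1}, gene="geneA", strand="-", s=101, e=400)
        from circkit.importer import flag_antisense

        flag_antisense([rec], model)
        assert rec.antisense and not rec.unannotated

    def test_matching_strand_is_not_antisense(self):
        model = make_model(strand="+")
        rec = _rec(gene="geneA", strand="+", s=101, e=400)
        from circkit.importer import flag_antisense

        flag_antisense([rec], model)
        assert not rec.antisense

    def test_strand_conflict_off_boundaries_is_unannotated(self):
        model = make_model(strand="+")
        rec = _rec(gene="geneA", strand="-", s=150, e=350)
        from circkit.importer import flag_antisense

        flag_antisense([rec], model)
        assert not rec.antisense and rec.unannotated

    def test_gene_absent_from_annotation_is_unannotated(self):
        model = make_model()
        rec = _rec(gene="nosuchgene", strand="-", s=101, e=400)
        from circkit.importer import flag_antisense

        flag_antisense([rec], model)
        assert not rec.antisense and rec.unannotated

    def test_fixture_antisense_records_are_flagged(self, merged_records, manifest):
        flagged = {r.circ_id for r in merged_records if r.antisense}
        assert flagged == {a["circ_id"] for a in manifest["antisense"]}


def test_experiment_design_round_trip(tmp_path):
    p = tmp_path / "design.tsv"
    p.write_text("s1\tctrl\ns2\tctrl\ns3\tcase\n")
    d = ExperimentDesign.from_tsv(p)
    assert d.samples == ["s1", "s2", "s3"]
    assert d.conditions == ["ctrl", "case"]
    assert d.samples_for("case") == ["s3"]
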