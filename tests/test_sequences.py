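"""Strand-aware sequence extraction with circular topology."""

from __future__ import annotations

import pytest
from Bio.Seq import reverse_complement

from circkit.annotation import annotate_circ
from circkit.background import generate_random_bsjs
from circkit.records import BsjRecord
from circkit.sequences import (
    Genome,
    extract_across_bsj,
    extract_flanks,
    extract_internal,
    read_fasta,
    write_fasta,
)

from conftest import make_model


@pytest.fixture(scope="module")
def mini_genome(tmp_path_factory):
    # deterministic 1200-nt contig with a readable repeating pattern
    import random

    rng = random.Random(42)
    seq = "".join(rng.choice("ACGT") for _ in range(1200))
    p = tmp_path_factory.mktemp("g") / "mini.fa"
    p.write_text(">chr1\n" + "\n".join(seq[i : i + 60] for i in range(0, 1200, 60)) + "\n")
    return Genome(p), seq


def _circ(model, i, j, gene="geneA"):
    tx = model.genes[gene].transcripts["tx1"]
    rec = BsjRecord(
        gene=gene,
        strand=tx.strand,
        chrom=tx.chrom,
        start_up_bse=tx.transcribed_start(i),
        end_down_bse=tx.transcribed_end(j),
    )
    return annotate_circ(rec, model)


def naive_internal(circ, raw: str) -> str:
    """Independent slicing oracle: per-exon substring, join, revcomp."""
    parts = [raw[e.start - 1 : e.end] for e in sorted(circ.exons, key=lambda e: e.start)]
    seq = "".join(parts)
    return reverse_complement(seq) if circ.strand == "-" else seq


class TestInternal:
    def test_single_plus_exon_is_the_genome_slice(self, mini_genome):
        genome, raw = mini_genome
        model = make_model(exons=[(11, 16), (101, 140), (201, 260)])
        circ = _circ(model, 0, 0)
        assert extract_internal(circ, genome).sequence == raw[10:16]

    def test_minus_strand_is_reverse_complement(self, mini_genome):
        genome, raw = mini_genome
        model = make_model(strand="-", exons=[(11, 16), (101, 140), (201, 260)])
        circ = _circ(model, 2, 2)  # transcript index 2 = genomically first exon
        assert extract_internal(circ, genome).sequence == reverse_complement(raw[10:16])

    def test_hand_example_revcomp(self, tmp_path):
        p = tmp_path / "t.fa"
        p.write_text(">chr1\n" + "AACCGG" + "ACGT" * 30 + "\n")
        genome = Genome(p)
        model = make_model(strand="-", exons=[(1, 6), (20, 30), (50, 60)])
        circ = _circ(model, 2, 2)
        assert extract_internal(circ, genome).sequence == "CCGGTT"

    def test_multi_exon_equals_naive_oracle_both_strands(self, mini_genome):
        genome, raw = mini_genome
        for strand in "+-":
            model = make_model(strand=strand, exons=[(11, 60), (201, 300), (501, 620), (801, 900)])
            for i, j in [(0, 3), (1, 2), (0, 0), (2, 3)]:
                circ = _circ(model, i, j)
                got = extract_internal(circ, genome)
                assert got.sequence == naive_internal(circ, raw)
                assert got.circular and got.length == circ.len_exonic

    def test_exon_beyond_contig_is_hard_error(self, mini_genome):
        genome, _ = mini_genome
        model = make_model(exons=[(1100, 1300), (1301, 1310), (1320, 1330)])
        with pytest.raises(ValueError, match="bounds"):
            extract_internal(_circ(model, 0, 0), genome)


class TestAcrossBsj:
    def test_w2_takes_two_from_each_side(self, mini_genome, tmp_path):
        p = tmp_path / "t.fa"
        p.write_text(">chr1\nAAAACCCCGGGGTTTT\n")
        genome = Genome(p)
        model = make_model(exons=[(1, 8), (10, 12), (14, 16)])
        circ = _circ(model, 0, 0)  # internal = AAAACCCC
        assert extract_across_bsj(circ, genome, w=2).sequence == "CCAA"

    def test_short_internal_doubles(self, tmp_path):
        p = tmp_path / "t.fa"
        p.write_text(">chr1\nACGTTTTTTTTT\n")
        genome = Genome(p)
        model = make_model(exons=[(1, 3), (5, 7), (9, 11)])
        circ = _circ(model, 0, 0)  # internal = ACG, len < w
        assert extract_across_bsj(circ, genome, w=5).sequence == "ACGACG"

    def test_is_substring_of_doubled_internal_centered_on_junction(self, mini_genome):
        genome, raw = mini_genome
        model = make_model(exons=[(11, 60), (201, 300), (501, 620)])
        circ = _circ(model, 0, 2)
        internal = extract_internal(circ, genome).sequence
        across = extract_across_bsj(circ, genome, w=11).sequence
        doubled = internal + internal
        assert across == doubled[len(internal) - 11 : len(internal) + 11]


class TestFlanks:
    def _model(self, strand="+"):
        # 300-nt introns around 120-nt exons
        return make_model(
            strand=strand,
            exons=[(101, 220), (521, 640), (941, 1060)],
        )

    def test_window_length_is_intron_plus_exon_nt(self, mini_genome):
        genome, _ = mini_genome
        circ = _circ(self._model(), 1, 1)
        seqs = extract_flanks(circ, genome, intron_nt=200, exon_nt=10, mode="window")
        by_type = {s.seq_type: s for s in seqs}
        assert by_type["window_up"].length == 210
        assert by_type["window_down"].length == 210

    def test_window_composition_anchored_at_the_junction(self, mini_genome):
        genome, raw = mini_genome
        circ = _circ(self._model(), 1, 1)
        seqs = {s.seq_type: s.sequence for s in extract_flanks(circ, genome, 200, 10, "window")}
        # upstream: last 200 nt of intron (321..520) + first 10 of exon (521..530)
        assert seqs["window_up"] == raw[320:520] + raw[520:530]
        # downstream: last 10 of exon (631..640) + first 200 of intron (641..840)
        assert seqs["window_down"] == raw[630:640] + raw[640:840]

    def test_short_intron_is_clipped_with_warning(self, mini_genome, caplog):
        genome, _ = mini_genome
        model = make_model(exons=[(101, 220), (371, 490), (941, 1060)])  # 150-nt intron
        circ = _circ(model, 1, 1)
        with caplog.at_level("WARNING"):
            seqs = extract_flanks(circ, genome, intron_nt=200, exon_nt=10, mode="window")
        by_type = {s.seq_type: s for s in seqs}
        assert by_type["window_up"].length == 160
        assert "clipped" in caplog.text

    def test_introns_mode_returns_full_flanking_introns(self, mini_genome):
        genome, raw = mini_genome
        circ = _circ(self._model(), 1, 1)
        seqs = {s.seq_type: s.sequence for s in extract_flanks(circ, genome, mode="introns")}
        assert seqs["flank_intron_up"] == raw[220:520]
        assert seqs["flank_intron_down"] == raw[640:940]

    def test_missing_intron_side_is_omitted_with_warning(self, mini_genome, caplog):
        genome, _ = mini_genome
        circ = _circ(self._model(), 0, 1)  # first exon: no upstream intron
        with caplog.at_level("WARNING"):
            seqs = extract_flanks(circ, genome, mode="introns")
        assert [s.seq_type for s in seqs] == ["flank_intron_down"]
        assert "omitted" in caplog.text

    def test_minus_strand_windows_are_revcomp_of_mirrored_plus(self, mini_genome):
        genome, raw = mini_genome
        plus = {s.seq_type: s.sequence for s in extract_flanks(_circ(self._model("+"), 1, 1), genome, 200, 10, "window")}
        minus = {s.seq_type: s.sequence for s in extract_flanks(_circ(self._model("-"), 1, 1), genome, 200, 10, "window")}
        # the minus-strand upstream window covers the genomically
        # downstream interval, read reverse-complemented
        assert minus["window_up"] == reverse_complement(raw[630:640] + raw[640:840])
        assert minus["window_down"] == reverse_complement(raw[320:520] + raw[520:530])
        assert minus["window_up"] == reverse_complement(plus["window_down"])

    def test_bse_mode_returns_full_back_spliced_exons(self, mini_genome):
        genome, raw = mini_genome
        circ = _circ(self._model(), 0, 2)
        seqs = {s.seq_type: s.sequence for s in extract_flanks(circ, genome, mode="bse")}
        assert seqs["bse_up"] == raw[100:220]
        assert seqs["bse_down"] == raw[940:1060]


class TestFastaRoundTrip:
    def test_write_read_preserves_records(self, mini_genome, tmp_path):
        genome, _ = mini_genome
        model = make_model(exons=[(11, 60), (201, 300), (501, 620)])
        records = [extract_internal(_circ(model, 0, 2), genome), extract_across_bsj(_circ(model, 0, 2), genome)]
        p = tmp_path / "out.fa"
        write_fasta(records, p)
        back = read_fasta(p)
        assert [(r.circ_id, r.seq_type, r.sequence, r.circular) for r in back] == [
            (r.circ_id, r.seq_type, r.sequence, r.circular) for r in records
        ]

    def test_rna_flag_converts_t_to_u_for_display(self, mini_genome, tmp_path):
        genome, _ = mini_genome
        model = make_model(exons=[(11, 60), (201, 300), (501, 620)])
        rec = extract_internal(_circ(model, 0, 0), genome)
        p = tmp_path / "rna.fa"
        write_fasta([rec], p, rna=True)
        body = p.read_text().splitlines()[1]
        assert "T" not in body
        # reading converts back to DNA
        assert read_fasta(p)[0].sequence == rec.sequence


def test_random_fixture_circs_equal_naive_oracle(fixture_dir, gene_model, genome, manifest):
    """Extraction on many annotation-derived circs (both strands)
    matches the independent naive slicing implementation."""
    raw = {c: genome.fetch(c, 1, genome.length(c)) for c in manifest["chrom_sizes"]}
    records = generate_random_bsjs(gene_model, n=60, seed=3)
    strands = set()
    for rec in records:
        circ = annotate_circ(rec, gene_model)
        assert circ.matched
        strands.add(circ.strand)
        assert extract_internal(circ, genome).sequence == naive_internal(circ, raw[circ.chrom])
    assert strands == {"+", "-"}
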