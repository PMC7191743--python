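"""Strand-aware extraction of circRNA sequences from a genome FASTA.

Three families of sequence are produced from an annotated circRNA:

* ``internal`` — the concatenated exonic sequence between the two BSJ
  coordinates, read 5'->3' around the circle (circular topology);
* ``across_bsj`` — the sequence reading through the junction: the last
  *w* nt of the internal sequence joined to its first *w* nt;
* flanks — the full flanking introns, a biogenesis window (intron tail
  plus exon head anchored at each junction side), or the full
  back-spliced exons.

All sequences are DNA (T, not U) in transcript orientation; minus-strand
records are reverse-complemented so strings always read 5'->3' of the
circRNA.  An RNA flag at FASTA-writing time converts T->U for display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio.Seq import reverse_complement
from pyfaidx import Fasta

from .annotation import AnnotatedCirc

log = logging.getLogger(__name__)

SEQ_TYPES = (
    "internal",
    "across_bsj",
    "flank_intron_up",
    "flank_intron_down",
    "window_up",
    "window_down",
    "bse_up",
    "bse_down",
)


@dataclass
class SeqRecordC:
    """A sequence tied to one circRNA, with circular-topology metadata."""

    circ_id: str
    seq_type: str
    sequence: str
    circular: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


class Genome:
    """Thin wrapper over an indexed FASTA; 1-based inclusive fetches,
    soft-masking uppercased on read."""

    def __init__(self, path: str | Path):
        self._fa = Fasta(str(path), sequence_always_upper=True)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fa

    def length(self, chrom: str) -> int:
        return len(self._fa[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fa:
            raise KeyError(f"contig {chrom!r} not in genome")
        if start < 1 or end > len(self._fa[chrom]) or start > end:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside contig bounds "
                f"(1-{len(self._fa[chrom])})"
            )
        return str(self._fa[chrom][start - 1 : end])

    def fetch_oriented(self, chrom: str, start: int, end: int, strand: str) -> str:
        seq = self.fetch(chrom, start, end)
        return reverse_complement(seq) if strand == "-" else seq


def _head_interval(start: int, end: int, k: int, strand: str) -> tuple[int, int]:
    """First k bases of a genomic interval in transcript orientation."""
    if strand == "+":
        return start, min(end, start + k - 1)
    return max(start, end - k + 1), end


def _tail_interval(start: int, end: int, k: int, strand: str) -> tuple[int, int]:
    """Last k bases of a genomic interval in transcript orientation."""
    if strand == "+":
        return max(start, end - k + 1), end
    return start, min(end, start + k - 1)


def extract_internal(circ: AnnotatedCirc, genome: Genome) -> SeqRecordC:
    """Concatenated internal exon sequence, 5'->3' around the circle."""
    if not circ.matched:
        raise ValueError(f"{circ.circ_id}: unmatched circ has no internal sequence")
    parts = [
        genome.fetch(circ.chrom, e.start, e.end)
        for e in sorted(circ.exons, key=lambda e: e.start)
    ]
    seq = "".join(parts)
    if circ.strand == "-":
        seq = reverse_complement(seq)
    return SeqRecordC(circ_id=circ.circ_id, seq_type="internal", sequence=seq, circular=True)


def extract_across_bsj(circ: AnnotatedCirc, genome: Genome, w: int = 11) -> SeqRecordC:
    """Sequence reading through the BSJ: last min(w, len) nt of the
    internal sequence joined to its first min(w, len) nt."""
    internal = extract_internal(circ, genome).sequence
    m = min(w, len(internal))
    return SeqRecordC(
        circ_id=circ.circ_id,
        seq_type="across_bsj",
        sequence=internal[-m:] + internal[:m],
        circular=False,
    )


def extract_flanks(
    circ: AnnotatedCirc,
    genome: Genome,
    intron_nt: int = 200,
    exon_nt: int = 10,
    mode: str = "introns",
) -> list[SeqRecordC]:
    """Sequences flanking the BSJ.

    ``introns`` — full upstream and downstream flanking introns;
    ``window`` — per junction side, the ``intron_nt`` intron bases
    adjacent to the BSJ joined to the ``exon_nt`` exon bases adjacent to
    the BSJ (clipped at feature boundaries with a warning);
    ``bse`` — the full upstream and downstream back-spliced exons.
    All 5'->3' in transcript orientation.
    """
    if not circ.matched:
        raise ValueError(f"{circ.circ_id}: unmatched circ has no flank sequences")
    if mode not in ("introns", "window", "bse"):
        raise ValueError(f"unknown flank mode {mode!r}")
    strand = circ.strand
    out: list[SeqRecordC] = []

    if mode == "bse":
        up_exon = circ.exons[0]
        down_exon = circ.exons[-1]
        out.append(
            SeqRecordC(
                circ.circ_id,
                "bse_up",
                genome.fetch_oriented(circ.chrom, up_exon.start, up_exon.end, strand),
            )
        )
        out.append(
            SeqRecordC(
                circ.circ_id,
                "bse_down",
                genome.fetch_oriented(circ.chrom, down_exon.start, down_exon.end, strand),
            )
        )
        return out

    for side, intron in (("up", circ.intron_up), ("down", circ.intron_down)):
        if intron is None:
            log.warning("%s: no %sstream flanking intron; side omitted", circ.circ_id, side)
            continue
        if mode == "introns":
            seq = genome.fetch_oriented(circ.chrom, intron[0], intron[1], strand)
            out.append(SeqRecordC(circ.circ_id, f"flank_intron_{side}", seq))
            continue
        # window mode: intron segment and exon segment anchored at the BSJ
        intron_len = intron[1] - intron[0] + 1
        if intron_len < intron_nt:
            log.warning(
                "%s: %sstream intron (%d nt) shorter than window %d; clipped",
                circ.circ_id,
                side,
                intron_len,
                intron_nt,
            )
        if side == "up":
            exon = circ.exons[0]
            iv_i = _tail_interval(intron[0], intron[1], intron_nt, strand)
            iv_e = _head_interval(exon.start, exon.end, exon_nt, strand)
            seq = genome.fetch_oriented(
                circ.chrom, *iv_i, strand
            ) + genome.fetch_oriented(circ.chrom, *iv_e, strand)
        else:
            exon = circ.exons[-1]
            iv_e = _tail_interval(exon.start, exon.end, exon_nt, strand)
            iv_i = _head_interval(intron[0], intron[1], intron_nt, strand)
            seq = genome.fetch_oriented(
                circ.chrom, *iv_e, strand
            ) + genome.fetch_oriented(circ.chrom, *iv_i, strand)
        out.append(SeqRecordC(circ.circ_id, f"window_{side}", seq))
    return out


def window_intervals(
    circ: AnnotatedCirc, intron_nt: int = 200, exon_nt: int = 10
) -> dict[str, tuple[int, int]]:
    """Genomic intervals covered by the biogenesis windows (both the
    intron and exon segments are BSJ-adjacent, hence contiguous)."""
    strand = circ.strand
    out: dict[str, tuple[int, int]] = {}
    if circ.intron_up is not None:
        iv_i = _tail_interval(*circ.intron_up, intron_nt, strand)
        iv_e = _head_interval(circ.exons[0].start, circ.exons[0].end, exon_nt, strand)
        out["up"] = (min(iv_i[0], iv_e[0]), max(iv_i[1], iv_e[1]))
    if circ.intron_down is not None:
        iv_e = _tail_interval(circ.exons[-1].start, circ.exons[-1].end, exon_nt, strand)
        iv_i = _head_interval(*circ.intron_down, intron_nt, strand)
        out["down"] = (min(iv_i[0], iv_e[0]), max(iv_i[1], iv_e[1]))
    return out


def write_fasta(records: list[SeqRecordC], path: str | Path, rna: bool = False) -> None:
    """Write sequences with headers ``circ_id|seq_type|length``; the RNA
    flag converts T->U for display only."""
    with open(path, "w") as fh:
        for r in records:
            seq = r.sequence.replace("T", "U") if rna else r.sequence
            fh.write(f">{r.circ_id}|{r.seq_type}|{r.length}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fasta(path: str | Path) -> list[SeqRecordC]:
    """Read back sequences written by :func:`write_fasta`."""
    out: list[SeqRecordC] = []
    header: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        parts = header.rsplit("|", 2)
        if len(parts) != 3:
            raise ValueError(f"unexpected FASTA header {header!r}")
        circ_id, seq_type, _ = parts
        seq = "".join(chunks).upper().replace("U", "T")
        out.append(
            SeqRecordC(circ_id, seq_type, seq, circular=(seq_type == "internal"))
        )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:]
                chunks = []
            else:
                chunks.append(line)
        _flush()
    return out
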