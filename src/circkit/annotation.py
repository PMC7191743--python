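"""Gene-model loading and exon-level annotation of back-splice junctions.

The gene model is read from an Ensembl/GENCODE-style GTF.  Each BSJ is
matched against the model by *exact* exon-boundary coincidence: the
upstream coordinate must equal the transcribed start of some exon *i*
and the downstream coordinate the transcribed end of some exon *j >= i*
of the same transcript.  The matched circ carries its internal exon
composition and the introns flanking the two back-spliced exons, the
inputs to all sequence-based screens.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import gffutils

from .records import BsjRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Exon:
    """Genomic 1-based inclusive exon interval."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Transcript:
    tx_id: str
    gene: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]  # transcription order: index 0 is the 5'-most exon

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> int:
        lo = min(e.start for e in self.exons)
        hi = max(e.end for e in self.exons)
        return hi - lo + 1

    def transcribed_start(self, i: int) -> int:
        """First transcribed base of exon i (0-based transcript index)."""
        e = self.exons[i]
        return e.start if self.strand == "+" else e.end

    def transcribed_end(self, i: int) -> int:
        e = self.exons[i]
        return e.end if self.strand == "+" else e.start


@dataclass
class Gene:
    name: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def exon_boundaries(self) -> set[int]:
        out: set[int] = set()
        for tx in self.transcripts.values():
            for e in tx.exons:
                out.add(e.start)
                out.add(e.end)
        return out


@dataclass
class GeneModel:
    genes: dict[str, Gene]

    @property
    def transcripts(self) -> list[Transcript]:
        out = []
        for g in sorted(self.genes):
            out.extend(self.genes[g].transcripts[t] for t in sorted(self.genes[g].transcripts))
        return out

    def transcripts_on(self, chrom: str, strand: str) -> list[Transcript]:
        return [t for t in self.transcripts if t.chrom == chrom and t.strand == strand]


def load_gtf(path: str | Path) -> GeneModel:
    """Load exon features from a GTF into a :class:`GeneModel`.

    Exons are grouped per transcript and sorted into transcription order
    (descending genomic coordinate on the minus strand).  The gene key
    is the ``gene_name`` attribute when present, else ``gene_id``.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # malformed attributes etc.
        raise ValueError(f"failed to parse GTF {path}: {exc}") from exc

    by_tx: dict[str, list] = defaultdict(list)
    tx_meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.features_of_type("exon"):
        tx_ids = feat.attributes.get("transcript_id")
        if not tx_ids:
            raise ValueError(f"{path}: exon feature without transcript_id at line for {feat}")
        tx_id = tx_ids[0]
        gene_name = (feat.attributes.get("gene_name") or feat.attributes.get("gene_id") or ["."])[0]
        by_tx[tx_id].append(feat)
        tx_meta[tx_id] = (gene_name, feat.seqid, feat.strand)

    # transcripts declared but exon-less are dropped with a warning
    for feat in db.features_of_type("transcript"):
        tx_id = feat.attributes.get("transcript_id", [None])[0]
        if tx_id and tx_id not in by_tx:
            log.warning("%s: transcript %s has no exons; dropped", path, tx_id)

    genes: dict[str, Gene] = {}
    for tx_id in sorted(by_tx):
        gene_name, chrom, strand = tx_meta[tx_id]
        feats = sorted(by_tx[tx_id], key=lambda f: f.start)
        exons = [Exon(f.start, f.end) for f in feats]
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise ValueError(f"{path}: overlapping exons in transcript {tx_id}")
        if strand == "-":
            exons = exons[::-1]
        tx = Transcript(tx_id=tx_id, gene=gene_name, chrom=chrom, strand=strand, exons=tuple(exons))
        gene = genes.setdefault(gene_name, Gene(name=gene_name, chrom=chrom, strand=strand))
        gene.transcripts[tx_id] = tx
    return GeneModel(genes=genes)


@dataclass
class AnnotatedCirc:
    """Exon composition and flanking introns of one matched BSJ."""

    circ_id: str
    gene: str
    chrom: str
    strand: str
    matched: bool
    transcript_used: str | None = None
    exons: tuple[Exon, ...] = ()  # transcript order, internal exons i..j
    intron_up: tuple[int, int] | None = None  # genomic (lo, hi), 1-based inclusive
    intron_down: tuple[int, int] | None = None
    nearest_up: int | None = None  # distances reported when unmatched
    nearest_down: int | None = None

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def len_exonic(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def len_intron_up(self) -> int | None:
        if self.intron_up is None:
            return None
        return self.intron_up[1] - self.intron_up[0] + 1

    @property
    def len_intron_down(self) -> int | None:
        if self.intron_down is None:
            return None
        return self.intron_down[1] - self.intron_down[0] + 1

    @property
    def start_up_bse(self) -> int:
        e = self.exons[0]
        return e.start if self.strand == "+" else e.end

    @property
    def end_down_bse(self) -> int:
        e = self.exons[-1]
        return e.end if self.strand == "+" else e.start


def _intron_between(tx: Transcript, a: int, b: int) -> tuple[int, int]:
    """Genomic interval of the intron between transcript-order exons a < b."""
    ea, eb = tx.exons[a], tx.exons[b]
    lo = min(ea.end, eb.end) + 1
    hi = max(ea.start, eb.start) - 1
    return (lo, hi)


def annotate_circ(
    record: BsjRecord, model: GeneModel, tolerance: int = 0
) -> AnnotatedCirc:
    """Match a BSJ to exon boundaries of one transcript.

    Among transcripts in which ``start_up_bse`` coincides with the
    transcribed start of exon *i* and ``end_down_bse`` with the
    transcribed end of exon *j >= i`` (within ``tolerance`` nt, default
    exact), the transcript with the most exons is used; ties break by
    longest genomic span, then lexicographic transcript id.  Unmatched
    records carry nearest-boundary distances instead.
    """
    if record.gene != "." and record.gene in model.genes:
        candidates = [
            t
            for t in model.genes[record.gene].transcripts.values()
            if t.strand == record.strand and t.chrom == record.chrom
        ]
    else:
        candidates = model.transcripts_on(record.chrom, record.strand)

    hits: list[tuple[Transcript, int, int]] = []
    best_up = best_down = None
    for tx in candidates:
        starts = [tx.transcribed_start(k) for k in range(tx.n_exons)]
        ends = [tx.transcribed_end(k) for k in range(tx.n_exons)]
        for d in (abs(s - record.start_up_bse) for s in starts):
            best_up = d if best_up is None else min(best_up, d)
        for d in (abs(e - record.end_down_bse) for e in ends):
            best_down = d if best_down is None else min(best_down, d)
        i_hits = [k for k, s in enumerate(starts) if abs(s - record.start_up_bse) <= tolerance]
        j_hits = [k for k, e in enumerate(ends) if abs(e - record.end_down_bse) <= tolerance]
        for i in i_hits:
            for j in j_hits:
                if j >= i:
                    hits.append((tx, i, j))

    if not hits:
        return AnnotatedCirc(
            circ_id=record.circ_id,
            gene=record.gene,
            chrom=record.chrom,
            strand=record.strand,
            matched=False,
            nearest_up=best_up,
            nearest_down=best_down,
        )

    hits.sort(key=lambda h: (-h[0].n_exons, -h[0].span, h[0].tx_id))
    tx, i, j = hits[0]
    intron_up = _intron_between(tx, i - 1, i) if i > 0 else None
    intron_down = _intron_between(tx, j, j + 1) if j < tx.n_exons - 1 else None
    return AnnotatedCirc(
        circ_id=record.circ_id,
        gene=tx.gene,
        chrom=record.chrom,
        strand=record.strand,
        matched=True,
        transcript_used=tx.tx_id,
        exons=tuple(tx.exons[i : j + 1]),
        intron_up=intron_up,
        intron_down=intron_down,
    )


def circs_per_gene(annotated: list[AnnotatedCirc]) -> dict[str, int]:
    """Number of distinct circRNAs per host gene."""
    return dict(Counter(a.gene for a in annotated))


def write_annotation_tsv(annotated: list[AnnotatedCirc], path: str | Path) -> None:
    cols = [
        "circ_id",
        "gene",
        "transcript_used",
        "matched",
        "n_exons",
        "len_exonic",
        "len_intron_up",
        "len_intron_down",
        "nearest_up",
        "nearest_down",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for a in annotated:
            row = [
                a.circ_id,
                a.gene,
                a.transcript_used or "NA",
                str(int(a.matched)),
                str(a.n_exons) if a.matched else "NA",
                str(a.len_exonic) if a.matched else "NA",
                str(a.len_intron_up) if a.len_intron_up is not None else "NA",
                str(a.len_intron_down) if a.len_intron_down is not None else "NA",
                str(a.nearest_up) if a.nearest_up is not None else "NA",
                str(a.nearest_down) if a.nearest_down is not None else "NA",
            ]
            fh.write("\t".join(row) + "\n")
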