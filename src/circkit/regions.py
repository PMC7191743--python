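"""GWAS SNP and repeat annotation of BSJ-flanking regions.

Features (GWAS-catalog SNPs, RepeatMasker repeats) are assigned to the
upstream/downstream flank of each circRNA by >= 1 base interval overlap
(inclusive boundaries).  Complementary repeat pairs — one repeat of the
same family in each flanking intron, on opposite strands — mark the
inverted-repeat biogenesis configuration (classically inverted Alu
elements whose base pairing brings the two splice sites together).
"""

from __future__ import annotations

import csv
import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from intervaltree import IntervalTree

from .annotation import AnnotatedCirc
from .sequences import window_intervals

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicFeature:
    kind: str  # snp | repeat
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # +/-/na
    name: str  # rsID or repeat name
    family: str  # repeat family/class or GWAS trait string

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.name}: start > end")
        if self.kind == "snp" and self.end != self.start:
            raise ValueError(f"SNP {self.name} must have length 1")


@dataclass
class FlankAnnotation:
    circ_id: str
    up: list[GenomicFeature] = field(default_factory=list)
    down: list[GenomicFeature] = field(default_factory=list)
    complementary_pairs: list[tuple[GenomicFeature, GenomicFeature]] = field(
        default_factory=list
    )


def load_gwas(
    path: str | Path, traits: str | None = None
) -> list[GenomicFeature]:
    """Read a GWAS-catalog-style TSV (CHR_ID, CHR_POS, SNPS,
    DISEASE/TRAIT); ``traits`` is an optional substring/regex filter on
    the trait field."""
    pattern = re.compile(traits, re.IGNORECASE) if traits else None
    out: list[GenomicFeature] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            trait = row.get("DISEASE/TRAIT", "")
            if pattern and not pattern.search(trait):
                continue
            try:
                pos = int(row["CHR_POS"])
            except (KeyError, ValueError):
                log.warning("skipping GWAS row without usable CHR_POS: %s", row)
                continue
            chrom = row["CHR_ID"]
            if not chrom.startswith("chr"):
                chrom = "chr" + chrom
            out.append(
                GenomicFeature(
                    kind="snp",
                    chrom=chrom,
                    start=pos,
                    end=pos,
                    strand="na",
                    name=row.get("SNPS", "."),
                    family=trait,
                )
            )
    return out


def load_repeatmasker(path: str | Path) -> list[GenomicFeature]:
    """Read a UCSC rmsk-style TSV (genoName, genoStart 0-based,
    genoEnd, strand, repName, repClass, repFamily)."""
    out: list[GenomicFeature] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                GenomicFeature(
                    kind="repeat",
                    chrom=row["genoName"],
                    start=int(row["genoStart"]) + 1,  # 0-based to 1-based
                    end=int(row["genoEnd"]),
                    strand=row["strand"],
                    name=row["repName"],
                    family=row.get("repFamily") or row.get("repClass") or ".",
                )
            )
    return out


def _feature_trees(features: list[GenomicFeature]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for f in features:
        # IntervalTree is half-open; +1 makes the inclusive end queryable
        trees[f.chrom].addi(f.start, f.end + 1, f)
    return trees


def alu_predicate(feature: GenomicFeature) -> bool:
    """Default family predicate: Alu elements by name prefix or family."""
    return feature.name.startswith("Alu") or feature.family == "Alu"


def annotate_flanks(
    circs: list[AnnotatedCirc],
    features: list[GenomicFeature],
    region: str = "introns",
    intron_nt: int = 200,
    exon_nt: int = 10,
    family_predicate: Callable[[GenomicFeature], bool] = alu_predicate,
) -> list[FlankAnnotation]:
    """Assign features to the flanks of each circ and detect
    complementary repeat pairs.

    ``region`` is ``introns`` (full flanking introns) or ``window``
    (the biogenesis windows of ``intron_nt``/``exon_nt`` around each
    junction side).  A feature belongs to a flank when the intervals
    overlap by at least one base.
    """
    if region not in ("introns", "window"):
        raise ValueError(f"unknown region {region!r}")
    trees = _feature_trees(features)
    out: list[FlankAnnotation] = []
    for circ in circs:
        ann = FlankAnnotation(circ_id=circ.circ_id)
        if not circ.matched:
            out.append(ann)
            continue
        if region == "introns":
            intervals = {}
            if circ.intron_up is not None:
                intervals["up"] = circ.intron_up
            if circ.intron_down is not None:
                intervals["down"] = circ.intron_down
        else:
            intervals = window_intervals(circ, intron_nt=intron_nt, exon_nt=exon_nt)
        tree = trees.get(circ.chrom)
        for side, (lo, hi) in intervals.items():
            if tree is None:
                continue
            found = sorted(
                (iv.data for iv in tree.overlap(lo, hi + 1)),
                key=lambda f: (f.start, f.end, f.name),
            )
            getattr(ann, side).extend(found)
        ann.complementary_pairs = complementary_pairs(ann, family_predicate)
        out.append(ann)
    return out


def complementary_pairs(
    annot: FlankAnnotation,
    family_predicate: Callable[[GenomicFeature], bool] = alu_predicate,
) -> list[tuple[GenomicFeature, GenomicFeature]]:
    """All (upstream, downstream) repeat pairs satisfying the family
    predicate with opposite strands; a circ "contains complementary
    repeats" iff this list is non-empty."""
    ups = [f for f in annot.up if f.kind == "repeat" and family_predicate(f)]
    downs = [f for f in annot.down if f.kind == "repeat" and family_predicate(f)]
    pairs = []
    for u in ups:
        for d in downs:
            if {u.strand, d.strand} == {"+", "-"}:
                pairs.append((u, d))
    return pairs


def summarize(annotations: list[FlankAnnotation]) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for a in annotations:
        feats = a.up + a.down
        rows.append(
            {
                "circ_id": a.circ_id,
                "n_snps": sum(1 for f in feats if f.kind == "snp"),
                "n_repeats": sum(1 for f in feats if f.kind == "repeat"),
                "has_complementary_pair": bool(a.complementary_pairs),
            }
        )
    return pd.DataFrame(rows)


def write_regions_tsv(annotations: list[FlankAnnotation], path: str | Path) -> None:
    cols = ["circ_id", "side", "kind", "name", "family", "start", "end", "strand"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for a in annotations:
            for side, feats in (("up", a.up), ("down", a.down)):
                for f in feats:
                    fh.write(
                        f"{a.circ_id}\t{side}\t{f.kind}\t{f.name}\t{f.family}\t"
                        f"{f.start}\t{f.end}\t{f.strand}\n"
                    )
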