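"""Canonical back-splice junction (BSJ) records and experiment design.

A circRNA is identified by its back-splice junction: the non-colinear
exon-exon junction joining the 3' end of a downstream exon to the 5'
start of an upstream exon.  Every detection tool reports this junction
in its own coordinate convention; :class:`BsjRecord` is the canonical
form all of them are normalised to.

Canonical coordinates are 1-based, inclusive, and stored in
*transcription order*: ``start_up_bse`` is the first transcribed base of
the upstream back-spliced exon and ``end_down_bse`` the last transcribed
base of the downstream back-spliced exon.  On the plus strand
``start_up_bse <= end_down_bse``; on the minus strand the inequality is
reversed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

STRANDS = ("+", "-")


def orient(strand: str, genomic_low: int, genomic_high: int) -> tuple[int, int]:
    """Return (start_up_bse, end_down_bse) for a genomically ordered pair."""
    if strand == "+":
        return genomic_low, genomic_high
    return genomic_high, genomic_low


@dataclass
class BsjRecord:
    """One back-splice junction with per-(tool, sample) read counts."""

    gene: str
    strand: str
    chrom: str
    start_up_bse: int
    end_down_bse: int
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    antisense: bool = False
    unannotated: bool = False

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene}")
        if self.strand == "+" and self.start_up_bse > self.end_down_bse:
            raise ValueError(
                f"plus-strand record {self.gene} has start_up_bse > end_down_bse"
            )
        if self.strand == "-" and self.start_up_bse < self.end_down_bse:
            raise ValueError(
                f"minus-strand record {self.gene} has start_up_bse < end_down_bse"
            )

    @property
    def circ_id(self) -> str:
        return "|".join(
            (
                self.gene,
                self.strand,
                self.chrom,
                str(self.start_up_bse),
                str(self.end_down_bse),
            )
        )

    @property
    def key(self) -> tuple[str, str, str, int, int]:
        return (self.gene, self.strand, self.chrom, self.start_up_bse, self.end_down_bse)

    @property
    def coord_key(self) -> tuple[str, str, int, int]:
        """Coordinates-only key, used to reconcile gene-less predictions."""
        return (self.strand, self.chrom, self.start_up_bse, self.end_down_bse)

    @property
    def genomic_start(self) -> int:
        return min(self.start_up_bse, self.end_down_bse)

    @property
    def genomic_end(self) -> int:
        return max(self.start_up_bse, self.end_down_bse)

    @property
    def n_tools(self) -> int:
        return len({tool for tool, _ in self.counts})

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def count(self, tool: str, sample: str) -> int:
        return self.counts.get((tool, sample), 0)


@dataclass
class ExperimentDesign:
    """Ordered samples and their condition labels."""

    samples: list[str]
    condition: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.samples if s not in self.condition]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        extra = [s for s in self.condition if s not in self.samples]
        if extra:
            raise ValueError(f"condition labels for unknown samples: {extra}")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            c = self.condition[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.condition[s] == condition]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExperimentDesign":
        """Read a two-column sample<TAB>condition table (no header)."""
        samples: list[str] = []
        condition: dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                if len(row) < 2:
                    raise ValueError(f"design row needs 2 columns: {row}")
                samples.append(row[0])
                condition[row[0]] = row[1]
        return cls(samples=samples, condition=condition)
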