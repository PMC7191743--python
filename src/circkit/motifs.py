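"""IUPAC motif scanning and foreground/background enrichment.

RBP binding motifs (ATtRACT-style IUPAC consensus strings) are scanned
position-wise with full degeneracy expansion; overlapping matches are
all counted, since motif occurrences are not mutually exclusive binding
events at scan time.  Circular internal sequences are extended by their
first (pattern length - 1) bases so a junction-spanning match is found
exactly once.

Enrichment compares match rates per kilobase between a foreground and a
background sequence set, with a Fisher exact test on matched versus
unmatched scan positions and Benjamini-Hochberg correction across
motifs.  De novo discovery is a k-mer over-representation ranking under
the same statistic.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sequences import SeqRecordC

log = logging.getLogger(__name__)

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

MIN_PATTERN_LENGTH = 4


@dataclass(frozen=True)
class Motif:
    motif_id: str
    rbp_name: str
    pattern: str  # IUPAC, U normalised to T
    source: str = "user"

    def __post_init__(self) -> None:
        pat = self.pattern.upper().replace("U", "T")
        object.__setattr__(self, "pattern", pat)
        if len(pat) < MIN_PATTERN_LENGTH:
            raise ValueError(
                f"motif {self.motif_id}: pattern shorter than {MIN_PATTERN_LENGTH} nt"
            )
        bad = [c for c in pat if c not in IUPAC]
        if bad:
            raise ValueError(f"motif {self.motif_id}: invalid IUPAC characters {bad}")


def load_motif_table(path: str | Path, source: str = "user") -> list[Motif]:
    """Read a motif TSV.

    Two layouts are recognised by header: the package's own
    (motif_id, rbp_name, pattern) and ATtRACT-style tables carrying
    Gene_name and Motif columns.
    """
    motifs: list[Motif] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty motif table")
        cols = set(reader.fieldnames)
        for i, row in enumerate(reader):
            if {"motif_id", "rbp_name", "pattern"} <= cols:
                motifs.append(
                    Motif(row["motif_id"], row["rbp_name"], row["pattern"], source)
                )
            elif {"Gene_name", "Motif"} <= cols:
                motifs.append(
                    Motif(
                        row.get("Matrix_id") or f"attract_{i + 1}",
                        row["Gene_name"],
                        row["Motif"],
                        "attract",
                    )
                )
            else:
                raise ValueError(
                    f"{path}: unrecognised motif table columns {sorted(cols)}"
                )
    return motifs


def _compiled(pattern: str) -> tuple[frozenset[str], ...]:
    return tuple(IUPAC[c] for c in pattern)


def scan_motif(seq: SeqRecordC | str, motif: Motif) -> list[int]:
    """All 1-based match positions of the motif in the sequence.

    Overlapping matches are all reported.  For circular sequences the
    scan extends over the sequence plus its first (pattern length - 1)
    bases, so junction-spanning matches are found exactly once; start
    positions stay in 1..len.
    """
    if isinstance(seq, SeqRecordC):
        s = seq.sequence
        circular = seq.circular
    else:
        s = seq
        circular = False
    s = s.upper()
    pat = _compiled(motif.pattern)
    L = len(pat)
    if circular and len(s) >= 1:
        ext = s + s[: L - 1]
        n_starts = len(s)
    else:
        ext = s
        n_starts = len(s) - L + 1
    positions: list[int] = []
    for p in range(max(0, n_starts)):
        if all(ext[p + k] in pat[k] for k in range(L)):
            positions.append(p + 1)
    return positions


def scan_positions(seq: SeqRecordC, pattern_length: int) -> int:
    """Number of windows scanned in one sequence (denominator of the
    Fisher table)."""
    if seq.circular:
        return seq.length
    return max(0, seq.length - pattern_length + 1)


def enrichment(
    fg: list[SeqRecordC], bg: list[SeqRecordC], motifs: list[Motif]
) -> pd.DataFrame:
    """Fold enrichment (per-kb match rate ratio) of each motif in the
    foreground versus the background set, Fisher exact p on match
    counts versus scanned positions, BH across motifs."""
    if not fg or not bg:
        raise ValueError("foreground and background sets must be non-empty")
    fg_nt = sum(r.length for r in fg)
    bg_nt = sum(r.length for r in bg)
    if bg_nt == 0:
        raise ValueError("zero total background length")
    rows = []
    for m in motifs:
        L = len(m.pattern)
        fg_count = sum(len(scan_motif(r, m)) for r in fg)
        bg_count = sum(len(scan_motif(r, m)) for r in bg)
        fg_pos = sum(scan_positions(r, L) for r in fg)
        bg_pos = sum(scan_positions(r, L) for r in bg)
        fg_rate = 1000.0 * fg_count / fg_nt
        bg_rate = 1000.0 * bg_count / bg_nt
        if bg_rate > 0:
            fold = fg_rate / bg_rate
            infinite = False
        elif fg_rate > 0:
            fold = math.inf
            infinite = True
        else:
            fold = math.nan
            infinite = False
        if fg_count == 0 and bg_count == 0:
            p = 1.0
        else:
            table = [[fg_count, max(0, fg_pos - fg_count)], [bg_count, max(0, bg_pos - bg_count)]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        rows.append(
            {
                "motif_id": m.motif_id,
                "rbp_name": m.rbp_name,
                "fg_count": fg_count,
                "fg_rate": fg_rate,
                "bg_count": bg_count,
                "bg_rate": bg_rate,
                "fold": fold,
                "fold_infinite": infinite,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["padj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1] if len(df) else []
    return df


def _count_kmers(seqs: list[SeqRecordC], k: int) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    positions = 0
    for r in seqs:
        s = r.sequence.upper()
        if r.circular:
            ext = s + s[: k - 1]
            n = len(s)
        else:
            ext = s
            n = len(s) - k + 1
        positions += max(0, n)
        for p in range(max(0, n)):
            kmer = ext[p : p + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts, positions


def kmer_overrepresentation(
    fg: list[SeqRecordC],
    bg: list[SeqRecordC],
    k: int = 6,
    top: int | None = None,
) -> pd.DataFrame:
    """Rank k-mers by foreground over-representation (Fisher exact p,
    ties by fold descending then lexicographic)."""
    shortest = min(r.length for r in fg + bg)
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest sequence length {shortest}")
    fg_counts, fg_pos = _count_kmers(fg, k)
    bg_counts, bg_pos = _count_kmers(bg, k)
    fg_nt = sum(r.length for r in fg)
    bg_nt = sum(r.length for r in bg)
    rows = []
    for kmer in sorted(set(fg_counts) | set(bg_counts)):
        a = fg_counts.get(kmer, 0)
        b = bg_counts.get(kmer, 0)
        fg_rate = 1000.0 * a / fg_nt
        bg_rate = 1000.0 * b / bg_nt
        fold = fg_rate / bg_rate if bg_rate > 0 else (math.inf if fg_rate > 0 else math.nan)
        p = float(
            stats.fisher_exact(
                [[a, max(0, fg_pos - a)], [b, max(0, bg_pos - b)]],
                alternative="greater",
            )[1]
        )
        rows.append({"kmer": kmer, "fg_count": a, "bg_count": b, "fold": fold, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["padj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(
            by=["p", "fold", "kmer"], ascending=[True, False, True]
        ).reset_index(drop=True)
    if top is not None:
        df = df.head(top)
    return df
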