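"""Junction-aware miRNA seed-site scanning with G:U wobble pairing.

The seed of a mature miRNA (positions 2-8, a 7-mer) nucleates target
recognition.  A 7-nt window of the circRNA sequence is scored by
pairing it antiparallel with the seed: reverse the window, then pair
position-wise.  (seed, target) pairs (A,T), (U,A), (G,C), (C,G) are
canonical Watson-Crick matches; (G,T) and (U,G) are G:U wobbles (the
target is DNA, so U appears only on the miRNA side).  A site is
accepted when total matches >= 6 of which >= 5 are Watson-Crick and at
most 1 is a wobble, by default.

Scanning is circular: the internal sequence is extended by its first
six bases so seed sites spanning the back-splice junction are found.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .sequences import SeqRecordC

log = logging.getLogger(__name__)

SEED_LENGTH = 7
SEED_OFFSET = 1  # mature positions 2..8 (0-based slice [1:8])

#: (seed base, target base) canonical Watson-Crick pairs; seed is RNA, target DNA
PAIR_WC = frozenset({("A", "T"), ("U", "A"), ("G", "C"), ("C", "G")})
#: non-canonical G:U wobble pairs
PAIR_WOBBLE = frozenset({("G", "T"), ("U", "G")})


@dataclass(frozen=True)
class MirnaSeed:
    mirna_id: str
    mature: str  # RNA 5'->3', uppercase

    def __post_init__(self) -> None:
        seq = self.mature.upper().replace("T", "U")
        object.__setattr__(self, "mature", seq)
        if len(seq) < SEED_OFFSET + SEED_LENGTH:
            raise ValueError(f"{self.mirna_id}: mature sequence shorter than 8 nt")

    @property
    def seed(self) -> str:
        return self.mature[SEED_OFFSET : SEED_OFFSET + SEED_LENGTH]


@dataclass(frozen=True)
class MirnaSite:
    circ_id: str
    mirna_id: str
    pos: int  # 1-based start of the 7-nt site in the circular sequence
    wc: int
    wobble: int
    spans_junction: bool

    @property
    def total(self) -> int:
        return self.wc + self.wobble


def load_mirna_fasta(path: str | Path) -> list[MirnaSeed]:
    """Read mature miRNA sequences; entries shorter than 8 nt are
    skipped with a warning."""
    out: list[MirnaSeed] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        if len(seq) < SEED_OFFSET + SEED_LENGTH:
            log.warning("%s: mature sequence too short (%d nt); skipped", rec.id, len(seq))
            continue
        out.append(MirnaSeed(mirna_id=rec.id, mature=seq))
    return out


def score_window(seed: str, window: str) -> tuple[int, int]:
    """(Watson-Crick, wobble) match counts of a 7-nt seed against a
    7-nt DNA target window, both given 5'->3' (antiparallel duplex)."""
    if len(seed) != SEED_LENGTH or len(window) != SEED_LENGTH:
        raise ValueError("seed and window must both be 7 nt")
    rev = window[::-1].upper()
    seed = seed.upper().replace("T", "U")
    wc = wobble = 0
    for s, t in zip(seed, rev):
        if (s, t) in PAIR_WC:
            wc += 1
        elif (s, t) in PAIR_WOBBLE:
            wobble += 1
    return wc, wobble


def find_sites(
    circ_seq: SeqRecordC,
    mirnas: list[MirnaSeed],
    min_total: int = 6,
    min_wc: int = 5,
    max_wobble: int = 1,
    circular: bool | None = None,
) -> list[MirnaSite]:
    """Scan a circular internal sequence for seed sites.

    Windows start at positions 1..len over the sequence extended with
    its first 6 nt; a site spans the junction when its start position
    exceeds len - 6.  ``circular=False`` forces a linear scan (no
    extension), mainly useful to demonstrate what a junction-naive
    scanner misses.
    """
    s = circ_seq.sequence.upper()
    L = len(s)
    if L < SEED_LENGTH:
        log.warning("%s: sequence shorter than 7 nt; no scan", circ_seq.circ_id)
        return []
    if circular is None:
        circular = circ_seq.circular
    ext = s + s[: SEED_LENGTH - 1] if circular else s
    n_starts = L if circular else L - SEED_LENGTH + 1
    sites: list[MirnaSite] = []
    for m in mirnas:
        seed = m.seed
        for p0 in range(n_starts):
            wc, wobble = score_window(seed, ext[p0 : p0 + SEED_LENGTH])
            if wc + wobble >= min_total and wc >= min_wc and wobble <= max_wobble:
                sites.append(
                    MirnaSite(
                        circ_id=circ_seq.circ_id,
                        mirna_id=m.mirna_id,
                        pos=p0 + 1,
                        wc=wc,
                        wobble=wobble,
                        spans_junction=(p0 + 1 > L - (SEED_LENGTH - 1)),
                    )
                )
    return sites


def filter_mirnas(
    mirnas: list[MirnaSeed],
    expression: pd.DataFrame,
    samples: list[str] | None = None,
    min_mean: float = 10.0,
) -> list[MirnaSeed]:
    """Keep miRNAs whose mean read count over the designated samples is
    at least ``min_mean``; miRNAs absent from the table are excluded
    with a warning."""
    if samples is None:
        samples = [c for c in expression.columns]
    means = expression[samples].mean(axis=1)
    out: list[MirnaSeed] = []
    for m in mirnas:
        if m.mirna_id not in means.index:
            log.warning("%s absent from expression table; excluded", m.mirna_id)
            continue
        if means[m.mirna_id] >= min_mean:
            out.append(m)
    return out


def write_sites_tsv(sites: list[MirnaSite], path: str | Path) -> None:
    cols = ["circ_id", "mirna_id", "pos", "wc", "wobble", "total", "spans_junction"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in sites:
            fh.write(
                f"{s.circ_id}\t{s.mirna_id}\t{s.pos}\t{s.wc}\t{s.wobble}\t"
                f"{s.total}\t{int(s.spans_junction)}\n"
            )
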