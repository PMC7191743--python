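"""UCSC chain-file parsing and point liftover of BSJ coordinates.

A chain describes a gapped alignment between a target assembly (the
coordinates being lifted *from*) and a query assembly (the destination).
Coordinates inside a chain header are 0-based half-open; query
coordinates of minus-strand chains count from the reversed query
sequence, per the UCSC chain specification.  BSJ ends are lifted as
exact points: a junction base that falls in an alignment gap is
unmapped, with no fractional-region rescue.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .records import BsjRecord, orient

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChainBlock:
    size: int
    dt: int = 0  # gap on target after this block
    dq: int = 0  # gap on query after this block


@dataclass
class ChainAlignment:
    score: int
    t_name: str
    t_size: int
    t_strand: str  # always '+'
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: tuple[ChainBlock, ...] = field(default_factory=tuple)
    chain_id: str = "0"

    def validate(self) -> None:
        sizes = sum(b.size for b in self.blocks)
        dts = sum(b.dt for b in self.blocks)
        dqs = sum(b.dq for b in self.blocks)
        if sizes + dts != self.t_end - self.t_start:
            raise ValueError(f"chain {self.chain_id}: target block sum mismatch")
        if sizes + dqs != self.q_end - self.q_start:
            raise ValueError(f"chain {self.chain_id}: query block sum mismatch")
        if any(b.size <= 0 for b in self.blocks):
            raise ValueError(f"chain {self.chain_id}: non-positive block size")


def parse_chain(path: str | Path) -> list[ChainAlignment]:
    """Parse a UCSC .chain file (plain or gzip); block-sum invariants
    are verified on load."""
    opener = gzip.open if str(path).endswith(".gz") else open
    chains: list[ChainAlignment] = []
    with opener(path, "rt") as fh:
        current: ChainAlignment | None = None
        blocks: list[ChainBlock] = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("chain"):
                if current is not None:
                    current.blocks = tuple(blocks)
                    current.validate()
                    chains.append(current)
                f = line.split()
                if len(f) != 13:
                    raise ValueError(f"{path}: malformed chain header: {line}")
                current = ChainAlignment(
                    score=int(f[1]),
                    t_name=f[2],
                    t_size=int(f[3]),
                    t_strand=f[4],
                    t_start=int(f[5]),
                    t_end=int(f[6]),
                    q_name=f[7],
                    q_size=int(f[8]),
                    q_strand=f[9],
                    q_start=int(f[10]),
                    q_end=int(f[11]),
                    chain_id=f[12],
                )
                blocks = []
            else:
                f = line.split()
                if len(f) == 3:
                    blocks.append(ChainBlock(int(f[0]), int(f[1]), int(f[2])))
                elif len(f) == 1:
                    blocks.append(ChainBlock(int(f[0])))
                else:
                    raise ValueError(f"{path}: malformed block line: {line}")
        if current is not None:
            current.blocks = tuple(blocks)
            current.validate()
            chains.append(current)
    return chains


def serialize_chain(chains: list[ChainAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(
                f"chain {c.score} {c.t_name} {c.t_size} {c.t_strand} {c.t_start} "
                f"{c.t_end} {c.q_name} {c.q_size} {c.q_strand} {c.q_start} "
                f"{c.q_end} {c.chain_id}\n"
            )
            for b in c.blocks[:-1]:
                fh.write(f"{b.size} {b.dt} {b.dq}\n")
            fh.write(f"{c.blocks[-1].size}\n\n")


def invert_chain(chain: ChainAlignment) -> ChainAlignment:
    """Swap target and query of a plus-strand chain (dt and dq trade
    places).  Minus-strand chains are not invertible this way."""
    if chain.q_strand != "+":
        raise ValueError("only plus-strand chains can be inverted directly")
    inv = ChainAlignment(
        score=chain.score,
        t_name=chain.q_name,
        t_size=chain.q_size,
        t_strand="+",
        t_start=chain.q_start,
        t_end=chain.q_end,
        q_name=chain.t_name,
        q_size=chain.t_size,
        q_strand="+",
        q_start=chain.t_start,
        q_end=chain.t_end,
        blocks=tuple(ChainBlock(b.size, b.dq, b.dt) for b in chain.blocks),
        chain_id=chain.chain_id,
    )
    inv.validate()
    return inv


def lift_point(
    chains: list[ChainAlignment], chrom: str, pos: int
) -> tuple[str, int, str] | None:
    """Lift a 1-based position; returns (chrom, pos, strand) or None.

    Chains covering the position are tried in descending score order;
    the first chain whose aligned blocks contain the position wins.
    Positions falling only in alignment gaps are unmapped.
    """
    p0 = pos - 1
    covering = [c for c in chains if c.t_name == chrom and c.t_start <= p0 < c.t_end]
    for chain in sorted(covering, key=lambda c: (-c.score, c.chain_id)):
        t = chain.t_start
        q = chain.q_start
        for b in chain.blocks:
            if t <= p0 < t + b.size:
                q0 = q + (p0 - t)
                if chain.q_strand == "+":
                    return (chain.q_name, q0 + 1, "+")
                return (chain.q_name, chain.q_size - q0, "-")
            t += b.size + b.dt
            q += b.size + b.dq
    return None


@dataclass
class LiftResult:
    circ_id: str
    lifted: bool
    dest_chrom: str | None = None
    dest_strand: str | None = None
    dest_start_up_bse: int | None = None
    dest_end_down_bse: int | None = None
    failure_reason: str | None = None  # unmapped | split | strand_conflict


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def lift_bsj(record: BsjRecord, chains: list[ChainAlignment]) -> LiftResult:
    """Lift both BSJ ends; success requires both to map to the same
    destination chromosome with consistent orientation."""
    up = lift_point(chains, record.chrom, record.start_up_bse)
    down = lift_point(chains, record.chrom, record.end_down_bse)
    if up is None or down is None:
        return LiftResult(record.circ_id, False, failure_reason="unmapped")
    (c1, p1, s1), (c2, p2, s2) = up, down
    if c1 != c2:
        return LiftResult(record.circ_id, False, failure_reason="split")
    if s1 != s2:
        return LiftResult(record.circ_id, False, failure_reason="strand_conflict")
    dest_strand = record.strand if s1 == "+" else _flip(record.strand)
    lo, hi = min(p1, p2), max(p1, p2)
    start_up, end_down = orient(dest_strand, lo, hi)
    return LiftResult(
        circ_id=record.circ_id,
        lifted=True,
        dest_chrom=c1,
        dest_strand=dest_strand,
        dest_start_up_bse=start_up,
        dest_end_down_bse=end_down,
    )


def write_lift_tsv(results: list[LiftResult], path: str | Path) -> None:
    cols = [
        "circ_id",
        "lifted",
        "dest_chrom",
        "dest_strand",
        "dest_startUpBSE",
        "dest_endDownBSE",
        "failure_reason",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.circ_id,
                        str(int(r.lifted)),
                        r.dest_chrom or "NA",
                        r.dest_strand or "NA",
                        str(r.dest_start_up_bse) if r.dest_start_up_bse else "NA",
                        str(r.dest_end_down_bse) if r.dest_end_down_bse else "NA",
                        r.failure_reason or "NA",
                    ]
                )
                + "\n"
            )
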