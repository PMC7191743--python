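"""Import, merge and antisense-flag circRNA predictions.

Per-tool tables are parsed into canonical :class:`~circkit.records.BsjRecord`
objects, merged across tools and samples into one record per unique
junction, and flagged when the reported strand contradicts the annotated
strand of the host gene (antisense circRNAs, excluded downstream by
default).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path

import pandas as pd

from .dialects import KNIFE_JUNCTION_RE, ToolDialect
from .records import BsjRecord, orient

log = logging.getLogger(__name__)


def _split_row(line: str, dialect: ToolDialect) -> list[str]:
    if dialect.sep is None:
        return line.split()
    return line.rstrip("\n").split(dialect.sep)


def parse_tool_output(
    path: str | Path, dialect: ToolDialect, sample: str
) -> list[BsjRecord]:
    """Parse one tool output file for one sample into canonical records.

    Coordinates are normalised to 1-based inclusive transcription order;
    counts are keyed by ``(dialect.tool_name, sample)``.  Rows with a
    read count of zero are retained (filtering is a separate stage).
    """
    records: list[BsjRecord] = []
    missing_gene_warned = False
    with open(path) as fh:
        first = True
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(dialect.comment):
                continue
            if first and dialect.has_header:
                first = False
                continue
            first = False
            fields = _split_row(line, dialect)
            try:
                if dialect.junction_column is not None:
                    m = KNIFE_JUNCTION_RE.match(fields[dialect.junction_column])
                    if m is None:
                        raise ValueError(
                            f"unparseable junction id {fields[dialect.junction_column]!r}"
                        )
                    chrom = m.group("chrom")
                    strand = m.group("strand")
                    start = int(m.group("start"))
                    end = int(m.group("end"))
                    gene = m.group("gene")
                else:
                    cm = dialect.column_map
                    chrom = fields[cm["chrom"]]
                    strand = fields[cm["strand"]]
                    start = int(fields[cm["start"]])
                    end = int(fields[cm["end"]])
                    if "gene" in cm:
                        gene = fields[cm["gene"]]
                    else:
                        gene = "."
                        if not missing_gene_warned:
                            log.warning(
                                "%s: dialect %s has no gene column; gene set to '.'",
                                path,
                                dialect.tool_name,
                            )
                            missing_gene_warned = True
                count = int(fields[dialect.column_map["count"]])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative read count {count}")
            s1, e1 = dialect.to_one_based_inclusive(start, end)
            lo, hi = min(s1, e1), max(s1, e1)
            up, down = orient(strand, lo, hi)
            records.append(
                BsjRecord(
                    gene=gene,
                    strand=strand,
                    chrom=chrom,
                    start_up_bse=up,
                    end_down_bse=down,
                    counts={(dialect.tool_name, sample): count},
                )
            )
    return records


def merge_predictions(
    sets: list[tuple[str, str, list[BsjRecord]]],
) -> list[BsjRecord]:
    """Merge per-(tool, sample) record lists into one record per junction.

    Records are keyed by (gene, strand, chrom, start_up_bse,
    end_down_bse); counts are unioned across tools and samples.  Records
    reported without a gene symbol (gene ".") are reconciled with a
    gene-named record at identical coordinates when that match is
    unambiguous; otherwise they stay as their own record.  Two records
    with identical coordinates but conflicting gene symbols are kept as
    distinct records with a warning.
    """
    merged: dict[tuple, BsjRecord] = {}
    for tool, sample, records in sets:
        for rec in records:
            existing = merged.get(rec.key)
            if existing is None:
                merged[rec.key] = BsjRecord(
                    gene=rec.gene,
                    strand=rec.strand,
                    chrom=rec.chrom,
                    start_up_bse=rec.start_up_bse,
                    end_down_bse=rec.end_down_bse,
                    counts=dict(rec.counts),
                )
            else:
                for k, v in rec.counts.items():
                    existing.counts[k] = existing.counts.get(k, 0) + v

    # second pass: attach gene-less records to a unique gene-named
    # record sharing the exact coordinates
    by_coord: dict[tuple, list[BsjRecord]] = defaultdict(list)
    for rec in merged.values():
        if rec.gene != ".":
            by_coord[rec.coord_key].append(rec)
    for key in list(merged):
        rec = merged[key]
        if rec.gene != ".":
            continue
        candidates = by_coord.get(rec.coord_key, [])
        if len(candidates) == 1:
            target = candidates[0]
            for k, v in rec.counts.items():
                target.counts[k] = target.counts.get(k, 0) + v
            del merged[key]
        elif len(candidates) > 1:
            log.warning(
                "coordinates %s claimed by multiple genes %s; keeping gene-less "
                "record separate",
                rec.coord_key,
                sorted(c.gene for c in candidates),
            )

    # warn on coordinate collisions between distinct gene symbols
    for coord, recs in by_coord.items():
        if len(recs) > 1:
            log.warning(
                "junction %s reported under conflicting gene symbols %s; "
                "keeping both records",
                coord,
                sorted(r.gene for r in recs),
            )

    out = sorted(
        merged.values(),
        key=lambda r: (r.chrom, r.genomic_start, r.genomic_end, r.strand, r.gene),
    )
    return out


def flag_antisense(records: list[BsjRecord], model) -> list[BsjRecord]:
    """Flag records whose strand contradicts the annotated gene strand.

    A record is antisense when its strand differs from the annotated
    strand of its gene while both BSJ coordinates coincide with
    annotated exon boundaries of that gene.  Records whose gene is
    absent from the annotation are flagged ``unannotated`` instead.
    Flags are set in place; the list is returned for chaining.
    """
    for rec in records:
        gene = model.genes.get(rec.gene)
        if gene is None:
            rec.unannotated = True
            continue
        if gene.strand == rec.strand:
            continue
        boundaries = gene.exon_boundaries()
        if rec.start_up_bse in boundaries and rec.end_down_bse in boundaries:
            rec.antisense = True
        else:
            rec.unannotated = True
    return records


# ---------------------------------------------------------------------------
# canonical TSV round trip

FIXED_COLUMNS = ["circ_id", "gene", "strand", "chrom", "startUpBSE", "endDownBSE", "n_tools"]


def write_merged_tsv(records: list[BsjRecord], path: str | Path) -> None:
    """Write the canonical merged table: fixed columns plus one count
    column per (tool, sample) named ``tool.sample``.

    Cells for (tool, sample) pairs that never reported the junction are
    written as ``NA`` so that a genuinely reported zero count survives a
    round trip (a tool may report a junction with zero BSJ reads).
    """
    pairs = sorted({k for r in records for k in r.counts})
    with open(path, "w") as fh:
        header = FIXED_COLUMNS + [f"{t}.{s}" for t, s in pairs] + ["antisense", "unannotated"]
        fh.write("\t".join(header) + "\n")
        for r in records:
            row = [
                r.circ_id,
                r.gene,
                r.strand,
                r.chrom,
                str(r.start_up_bse),
                str(r.end_down_bse),
                str(r.n_tools),
            ]
            row += [str(r.counts[p]) if p in r.counts else "NA" for p in pairs]
            row += [str(int(r.antisense)), str(int(r.unannotated))]
            fh.write("\t".join(row) + "\n")


def read_merged_tsv(path: str | Path) -> list[BsjRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
    count_cols = [
        c
        for c in df.columns
        if c not in FIXED_COLUMNS and c not in ("antisense", "unannotated")
    ]
    records = []
    for _, row in df.iterrows():
        counts = {}
        for c in count_cols:
            if pd.isna(row[c]):
                continue
            tool, sample = c.split(".", 1)
            counts[(tool, sample)] = int(row[c])
        rec = BsjRecord(
            gene=str(row["gene"]),
            strand=row["strand"],
            chrom=str(row["chrom"]),
            start_up_bse=int(row["startUpBSE"]),
            end_down_bse=int(row["endDownBSE"]),
            counts=counts,
            antisense=bool(row.get("antisense", False)),
            unannotated=bool(row.get("unannotated", False)),
        )
        records.append(rec)
    return records
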