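"""Table dialects of the supported circRNA detection tools.

The upstream detectors (MapSplice2, NCLscan, CircMarker, CircExplorer2,
KNIFE, UROBORUS) each write their own table layout and coordinate
convention.  None of them documents a frozen schema, so the adapters
here are table-driven best-effort defaults: a :class:`ToolDialect` names
the column holding each canonical field plus the coordinate base and
end convention, and the parser does the rest.  A ``generic`` dialect
(chrom, strand, start, end, gene, count) is provided for any other
tool whose output the user reshapes.

KNIFE is the one non-tabular case: its junction id packs chromosome,
positions and strand into a single pipe-delimited string, declared via
``junction_column``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

#: canonical fields a column map may provide
CANONICAL_FIELDS = ("chrom", "strand", "start", "end", "count", "gene")

#: fields that must be resolvable (directly or via a junction column)
REQUIRED_FIELDS = ("chrom", "strand", "start", "end", "count")

KNIFE_JUNCTION_RE = re.compile(
    r"^(?P<chrom>[^|]+)\|(?P<gene>[^:|]+):(?P<start>\d+)\|[^:|]+:(?P<end>\d+)"
    r"\|[^|]+\|(?P<strand>[+-])$"
)


@dataclass(frozen=True)
class ToolDialect:
    tool_name: str
    column_map: dict[str, int] = field(default_factory=dict)
    coordinate_base: int = 1
    end_convention: str = "inclusive"  # or "half_open"
    sep: str | None = "\t"  # None = any whitespace
    comment: str = "#"
    has_header: bool = False
    junction_column: int | None = None  # KNIFE-style compound field

    def __post_init__(self) -> None:
        if self.coordinate_base not in (0, 1):
            raise ValueError("coordinate_base must be 0 or 1")
        if self.end_convention not in ("inclusive", "half_open"):
            raise ValueError("end_convention must be inclusive|half_open")
        provided = set(self.column_map)
        if self.junction_column is not None:
            provided |= {"chrom", "strand", "start", "end", "gene"}
        missing = [f for f in REQUIRED_FIELDS if f not in provided]
        if missing:
            raise ValueError(f"dialect {self.tool_name}: missing columns {missing}")

    def to_one_based_inclusive(self, start: int, end: int) -> tuple[int, int]:
        """Normalise a genomic (start, end) pair to 1-based inclusive."""
        s = start + (1 - self.coordinate_base)
        if self.end_convention == "half_open":
            e = end - self.coordinate_base
        else:
            e = end + (1 - self.coordinate_base)
        return s, e


# Best-effort default layouts for the six supported tools.  Column
# indices are 0-based positions in the tool's output table.
DEFAULT_DIALECTS: dict[str, ToolDialect] = {
    "generic": ToolDialect(
        tool_name="generic",
        column_map={"chrom": 0, "strand": 1, "start": 2, "end": 3, "gene": 4, "count": 5},
        coordinate_base=1,
        end_convention="inclusive",
        sep=None,
    ),
    "mapsplice2": ToolDialect(
        tool_name="mapsplice2",
        column_map={"chrom": 0, "start": 1, "end": 2, "gene": 3, "count": 4, "strand": 5},
        coordinate_base=1,
        end_convention="inclusive",
    ),
    "nclscan": ToolDialect(
        tool_name="nclscan",
        column_map={"chrom": 0, "start": 1, "end": 2, "strand": 3, "gene": 4, "count": 5},
        coordinate_base=1,
        end_convention="inclusive",
    ),
    # CircMarker reports junction coordinates and read support only; no
    # gene attribution (records get gene "." and are reconciled by
    # coordinate match at merge time).
    "circmarker": ToolDialect(
        tool_name="circmarker",
        column_map={"chrom": 0, "start": 1, "end": 2, "strand": 3, "count": 4},
        coordinate_base=1,
        end_convention="inclusive",
    ),
    # CircExplorer2 "annotate" writes a BED12+ table: 0-based half-open
    # with strand in column 5, BSJ read number in column 12 and the
    # host-gene symbol in column 14.
    "circexplorer2": ToolDialect(
        tool_name="circexplorer2",
        column_map={"chrom": 0, "start": 1, "end": 2, "strand": 5, "count": 12, "gene": 14},
        coordinate_base=0,
        end_convention="half_open",
    ),
    # KNIFE packs "chrom|gene:pos|gene:pos|class|strand" into one id.
    "knife": ToolDialect(
        tool_name="knife",
        column_map={"count": 1},
        coordinate_base=1,
        end_convention="inclusive",
        junction_column=0,
    ),
    "uroborus": ToolDialect(
        tool_name="uroborus",
        column_map={"chrom": 0, "start": 1, "end": 2, "strand": 3, "gene": 5, "count": 6},
        coordinate_base=0,
        end_convention="half_open",
    ),
}


def get_dialect(name: str) -> ToolDialect:
    try:
        return DEFAULT_DIALECTS[name]
    except KeyError:
        raise KeyError(
            f"unknown tool dialect {name!r}; known: {sorted(DEFAULT_DIALECTS)}"
        ) from None
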