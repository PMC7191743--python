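"""Count-matrix construction and read-count prevalence filtering.

Several detection tools report BSJ-spanning reads for the same junction
in the same library; those reads largely overlap, so the default
collapse across tools takes the per-sample maximum rather than the sum.
The prevalence filter then keeps a circRNA only when at least one
condition has enough samples supporting it at the required depth — the
standard guard against low-count false positives.
"""

from __future__ import annotations

import logging

import pandas as pd

from .records import BsjRecord, ExperimentDesign

log = logging.getLogger(__name__)


def collapse_counts(
    records: list[BsjRecord], design: ExperimentDesign, mode: str = "max"
) -> pd.DataFrame:
    """Collapse per-(tool, sample) counts into one circ x sample matrix.

    ``mode`` is ``sum`` (add across tools), ``max`` (per-sample maximum,
    the default, conservative against double-counting the same junction
    reads) or ``tool:<name>`` (a single tool's counts).
    """
    tool_only: str | None = None
    if mode.startswith("tool:"):
        tool_only = mode.split(":", 1)[1]
        tools_present = {t for r in records for (t, _) in r.counts}
        if tool_only not in tools_present:
            raise ValueError(f"unknown tool {tool_only!r}; present: {sorted(tools_present)}")
    elif mode not in ("sum", "max"):
        raise ValueError(f"unknown collapse mode {mode!r}")

    data = []
    index = []
    for rec in records:
        row = {}
        for sample in design.samples:
            vals = [
                c
                for (tool, s), c in rec.counts.items()
                if s == sample and (tool_only is None or tool == tool_only)
            ]
            if tool_only is not None or mode == "sum":
                row[sample] = sum(vals)
            else:
                row[sample] = max(vals) if vals else 0
        data.append(row)
        index.append(rec.circ_id)
    matrix = pd.DataFrame(data, index=index, columns=design.samples, dtype=int)
    matrix.index.name = "circ_id"
    return matrix


def filter_circs(
    matrix: pd.DataFrame,
    design: ExperimentDesign,
    min_count: int = 5,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Keep circRNAs with >= ``min_count`` reads in >= ``min_samples``
    samples of at least one condition.  Row order is preserved."""
    if min_count < 0 or min_samples < 1:
        raise ValueError("min_count must be >= 0 and min_samples >= 1")
    sizes = {c: len(design.samples_for(c)) for c in design.conditions}
    if all(min_samples > n for n in sizes.values()):
        raise ValueError(
            f"min_samples={min_samples} exceeds every condition size {sizes}: "
            "filter unsatisfiable"
        )
    keep = pd.Series(False, index=matrix.index)
    for cond in design.conditions:
        cols = [s for s in design.samples_for(cond) if s in matrix.columns]
        if not cols:
            continue
        n_ok = (matrix[cols] >= min_count).sum(axis=1)
        keep |= n_ok >= min_samples
    return matrix.loc[keep]
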