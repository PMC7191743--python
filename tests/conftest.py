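"""Shared fixtures: one synthetic dataset per session plus small helpers."""

from __future__ import annotations

import pytest

from circkit.annotation import Exon, Gene, GeneModel, Transcript, annotate_circ, load_gtf
from circkit.dialects import get_dialect
from circkit.fixtures import TOOLS, FixtureSpec, build_fixture
from circkit.importer import flag_antisense, merge_predictions, parse_tool_output
from circkit.records import ExperimentDesign
from circkit.sequences import Genome


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fx")
    manifest = build_fixture(FixtureSpec(seed=7), d)
    return d, manifest


@pytest.fixture(scope="session")
def manifest(fixture_dir):
    return fixture_dir[1]


@pytest.fixture(scope="session")
def gene_model(fixture_dir):
    return load_gtf(fixture_dir[0] / "annotation.gtf")


@pytest.fixture(scope="session")
def genome(fixture_dir):
    return Genome(fixture_dir[0] / "genome.fa")


@pytest.fixture(scope="session")
def design(fixture_dir):
    return ExperimentDesign.from_tsv(fixture_dir[0] / "design.tsv")


def parse_all_tools(fixture_dir, manifest):
    """Parse every per-tool per-sample fixture file into record sets."""
    sets = []
    for tool in TOOLS:
        dialect = get_dialect(tool)
        for sample, rel in sorted(manifest["files"]["tools"][tool].items()):
            sets.append((tool, sample, parse_tool_output(fixture_dir / rel, dialect, sample)))
    return sets


@pytest.fixture(scope="session")
def merged_records(fixture_dir, manifest, gene_model):
    d, m = fixture_dir, manifest
    merged = merge_predictions(parse_all_tools(d[0], m))
    flag_antisense(merged, gene_model)
    return merged


@pytest.fixture(scope="session")
def annotated_truth(merged_records, manifest, gene_model):
    truth_ids = {c["circ_id"] for c in manifest["truth_circs"]}
    return {
        r.circ_id: annotate_circ(r, gene_model)
        for r in merged_records
        if r.circ_id in truth_ids
    }


def make_model(
    strand: str = "+",
    exons: list[tuple[int, int]] | None = None,
    gene: str = "geneA",
    chrom: str = "chr1",
    tx_id: str = "tx1",
) -> GeneModel:
    """One-gene one-transcript model from genomic-ascending exon tuples."""
    exon_objs = [Exon(s, e) for s, e in (exons or [(101, 200), (301, 400), (501, 600)])]
    if strand == "-":
        exon_objs = exon_objs[::-1]
    tx = Transcript(tx_id=tx_id, gene=gene, chrom=chrom, strand=strand, exons=tuple(exon_objs))
    g = Gene(name=gene, chrom=chrom, strand=strand, transcripts={tx_id: tx})
    return GeneModel(genes={gene: g})
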