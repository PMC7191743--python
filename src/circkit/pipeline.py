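"""The full ordered analysis pipeline driven by one run configuration.

Stages: import and merge tool predictions, flag antisense records,
annotate exon composition, prevalence-filter counts, differential
expression, liftover conservation, random-BSJ background, sequence
extraction, motif enrichment, miRNA seed-site scanning, and flank
region annotation.  Every stage writes a stable, header-first TSV/FASTA
into the output directory; ``summary.json`` collects the headline
numbers.  Given identical inputs and seed the output tree is
byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .annotation import AnnotatedCirc, annotate_circ, circs_per_gene, load_gtf, write_annotation_tsv
from .background import generate_random_bsjs
from .config import RunConfig, echo_resolved
from .counts import collapse_counts, filter_circs
from .de import fit_and_test
from .dialects import get_dialect
from .importer import flag_antisense, merge_predictions, parse_tool_output, write_merged_tsv
from .liftover import lift_bsj, parse_chain, write_lift_tsv
from .mirna import filter_mirnas, find_sites, load_mirna_fasta, write_sites_tsv
from .motifs import enrichment, load_motif_table
from .records import BsjRecord, ExperimentDesign
from .regions import annotate_flanks, load_gwas, load_repeatmasker, summarize, write_regions_tsv
from .sequences import Genome, SeqRecordC, extract_across_bsj, extract_flanks, extract_internal, write_fasta

log = logging.getLogger(__name__)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage; returns the summary dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    echo_resolved(config, out / "config_resolved.yml")

    design = ExperimentDesign.from_tsv(config.design)
    summary: dict = {"version": __version__, "seed": config.seed}

    # ---- import + merge + antisense ---------------------------------
    sets = []
    n_imported: dict[str, int] = {}
    for tool in sorted(config.tools):
        dialect = get_dialect(config.tools[tool]["dialect"])
        n_rows = 0
        for sample in design.samples:
            fp = config.tools[tool]["files"].get(sample)
            if fp is None:
                continue
            records = parse_tool_output(fp, dialect, sample)
            n_rows += len(records)
            sets.append((tool, sample, records))
        n_imported[tool] = n_rows
    merged = merge_predictions(sets)
    model = load_gtf(config.gtf)
    flag_antisense(merged, model)
    write_merged_tsv(merged, out / "merged.tsv")
    summary["n_imported"] = n_imported
    summary["n_merged"] = len(merged)
    summary["n_antisense"] = sum(r.antisense for r in merged)
    summary["n_unannotated"] = sum(r.unannotated for r in merged)

    sense = [r for r in merged if not r.antisense]

    # ---- annotation --------------------------------------------------
    annotated: dict[str, AnnotatedCirc] = {
        r.circ_id: annotate_circ(r, model) for r in sense
    }
    write_annotation_tsv(list(annotated.values()), out / "annotated.tsv")
    matched = {cid: a for cid, a in annotated.items() if a.matched}
    per_gene = circs_per_gene(list(matched.values()))
    summary["n_matched"] = len(matched)
    summary["n_single_circ_genes"] = sum(1 for v in per_gene.values() if v == 1)

    # ---- counts + filter --------------------------------------------
    matrix = collapse_counts(sense, design, mode=str(config.threshold("collapse_mode")))
    matrix.to_csv(out / "counts.tsv", sep="\t")
    filtered = filter_circs(
        matrix,
        design,
        min_count=int(config.threshold("min_count")),
        min_samples=int(config.threshold("min_samples")),
    )
    filtered.to_csv(out / "filtered.tsv", sep="\t")
    summary["n_filtered"] = len(filtered)
    by_id = {r.circ_id: r for r in sense}
    filtered_records: list[BsjRecord] = [by_id[c] for c in filtered.index]

    # ---- differential expression ------------------------------------
    if config.contrast is not None and len(filtered):
        cond_a, cond_b = config.contrast
        _, de_res = fit_and_test(
            filtered,
            design,
            cond_a,
            cond_b,
            lfc_cut=float(config.threshold("lfc_cut")),
            alpha=float(config.threshold("alpha")),
        )
        de_res.index.name = "circ_id"
        de_res.to_csv(out / "de.tsv", sep="\t", float_format="%.6g")
        summary["n_de_significant"] = int(de_res["significant"].sum())

    # ---- liftover ----------------------------------------------------
    if config.chain is not None:
        chains = parse_chain(config.chain)
        lifts = [lift_bsj(r, chains) for r in filtered_records]
        write_lift_tsv(lifts, out / "liftover.tsv")
        if lifts:
            summary["conserved_fraction"] = sum(r.lifted for r in lifts) / len(lifts)

    # ---- random BSJ background --------------------------------------
    n_random = int(config.threshold("n_random"))
    random_set = generate_random_bsjs(
        model,
        n=n_random,
        exclude={r.circ_id for r in merged},
        seed=config.seed,
    )
    write_merged_tsv(random_set, out / "random_bsjs.tsv")
    random_annot = [annotate_circ(r, model) for r in random_set]

    # ---- sequences ---------------------------------------------------
    genome = Genome(config.genome)
    intron_nt = int(config.threshold("intron_nt"))
    exon_nt = int(config.threshold("exon_nt"))
    w = int(config.threshold("across_bsj_w"))
    internal = [extract_internal(matched[c], genome) for c in filtered.index if c in matched]
    across = [extract_across_bsj(matched[c], genome, w=w) for c in filtered.index if c in matched]
    windows: list[SeqRecordC] = []
    for c in filtered.index:
        if c in matched:
            windows.extend(
                extract_flanks(matched[c], genome, intron_nt=intron_nt, exon_nt=exon_nt, mode="window")
            )
    random_windows: list[SeqRecordC] = []
    for a in random_annot:
        if a.matched:
            random_windows.extend(
                extract_flanks(a, genome, intron_nt=intron_nt, exon_nt=exon_nt, mode="window")
            )
    write_fasta(internal, out / "internal.fa")
    write_fasta(across, out / "across_bsj.fa")
    write_fasta(windows, out / "windows.fa")
    write_fasta(random_windows, out / "random_windows.fa")

    # ---- motif enrichment -------------------------------------------
    if config.motif_db is not None and windows and random_windows:
        motifs = load_motif_table(config.motif_db)
        enr = enrichment(windows, random_windows, motifs)
        enr.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False, float_format="%.6g")

    # ---- miRNA seed sites -------------------------------------------
    if config.mirna_fasta is not None and internal:
        mirnas = load_mirna_fasta(config.mirna_fasta)
        if config.mirna_expression is not None:
            import pandas as pd

            expr = pd.read_csv(config.mirna_expression, sep="\t", index_col=0)
            mirnas = filter_mirnas(mirnas, expr, min_mean=float(config.threshold("mirna_min_mean")))
        summary["n_mirnas_used"] = len(mirnas)
        sites = []
        for rec in internal:
            sites.extend(
                find_sites(
                    rec,
                    mirnas,
                    min_total=int(config.threshold("mirna_min_total")),
                    min_wc=int(config.threshold("mirna_min_wc")),
                    max_wobble=int(config.threshold("mirna_max_wobble")),
                )
            )
        write_sites_tsv(sites, out / "mirna_sites.tsv")
        summary["n_mirna_sites"] = len(sites)

    # ---- flank regions ----------------------------------------------
    features = []
    if config.gwas is not None:
        features.extend(load_gwas(config.gwas, traits=config.gwas_traits))
    if config.repeats is not None:
        features.extend(load_repeatmasker(config.repeats))
    if features:
        flank_circs = [matched[c] for c in filtered.index if c in matched]
        regions = annotate_flanks(flank_circs, features, region="introns")
        write_regions_tsv(regions, out / "regions.tsv")
        reg_summary = summarize(regions)
        reg_summary.to_csv(out / "regions_summary.tsv", sep="\t", index=False)
        summary["n_flank_snps"] = int(reg_summary["n_snps"].sum())
        both = [
            a
            for a, circ in zip(regions, flank_circs)
            if circ.intron_up is not None and circ.intron_down is not None
        ]
        if both:
            summary["complementary_fraction"] = sum(
                bool(a.complementary_pairs) for a in both
            ) / len(both)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
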