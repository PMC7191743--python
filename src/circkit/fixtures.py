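"""Synthetic mini-dataset generator with known ground truth.

Builds a fully consistent fixture: a random mini-genome (~100 kb), a
matching GTF, per-tool circRNA prediction files in all six supported
dialects (sharing one ground-truth circ set plus tool-specific decoys),
negative-binomial read counts with planted fold changes, a motif
database plus foreground/background sequence sets with a planted
enrichment, mature miRNAs with planted seed sites (one spanning the
back-splice junction), GWAS-style SNPs and RepeatMasker-style repeats
planted in flanking introns (half the eligible circs get an inverted
Alu pair), and UCSC chain files (identity, shift, gapped, inversion).
A manifest JSON records every planted truth so tests can compare
module output against it.  Output is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from Bio.Seq import reverse_complement

from .liftover import ChainAlignment, ChainBlock, invert_chain, serialize_chain
from .records import orient

BASES = np.array(list("ACGT"))

#: fixed motif database; the first entry is the planted one
MOTIF_DB = [
    ("M001", "RBM24", "TGCATGC"),
    ("M002", "QKI", "ACTAACG"),
    ("M003", "SRSF1", "GGAGGAC"),
    ("M004", "PTBP1", "TCTTCTC"),
    ("M005", "MBNL1", "YGCKGCW"),  # degenerate, exercises IUPAC expansion
]

ANTISENSE_TOOLS = ("mapsplice2", "nclscan")


@dataclass
class FixtureSpec:
    """Study conditions emulated by the fixture (sizes, noise, effects)."""

    seed: int = 7
    n_genes: int = 12
    n_chroms: int = 2
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_len: tuple[int, int] = (120, 280)
    intron_len: tuple[int, int] = (260, 420)
    intergenic: int = 800
    n_circs: int = 24
    n_decoys_per_tool: int = 3
    n_antisense: int = 2
    conditions: tuple[str, str] = ("control", "disease")
    n_samples_per_condition: int = 3
    mean_range: tuple[float, float] = (30.0, 300.0)
    dispersion: float = 0.2
    n_de: int = 6
    de_log2fc: float = 2.0
    n_mirnas: int = 8
    n_interior_sites: int = 3
    mirna_expr_samples: int = 4
    mirna_min_mean: float = 10.0
    enrich_n_seqs: int = 100
    enrich_seq_len: int = 500
    enrich_bg_per_seq: int = 2
    enrich_fold: int = 4
    n_snps_in_flanks: int = 6
    n_snps_outside: int = 3
    n_snps_offtrait: int = 3


TOOLS = ("mapsplice2", "nclscan", "circmarker", "circexplorer2", "knife", "uroborus")


# ---------------------------------------------------------------------------
# gene layout


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genomic ascending
    alt_exons: list[tuple[int, int]] | None = None  # optional second transcript

    def tx_exons(self) -> list[tuple[int, int]]:
        """Primary-transcript exons in transcription order."""
        return self.exons if self.strand == "+" else self.exons[::-1]


def _layout_genes(spec: FixtureSpec, rng: np.random.Generator) -> tuple[list[_Gene], dict[str, int]]:
    cursors = {f"chr{i + 1}": spec.intergenic for i in range(spec.n_chroms)}
    genes: list[_Gene] = []
    for g in range(spec.n_genes):
        chrom = f"chr{g % spec.n_chroms + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        pos = cursors[chrom]
        exons = []
        for k in range(n_ex):
            el = int(rng.integers(spec.exon_len[0], spec.exon_len[1] + 1))
            exons.append((pos + 1, pos + el))
            pos += el
            if k < n_ex - 1:
                pos += int(rng.integers(spec.intron_len[0], spec.intron_len[1] + 1))
        cursors[chrom] = pos + spec.intergenic
        genes.append(_Gene(gene_id=f"gene{g + 1}", chrom=chrom, strand=strand, exons=exons))
    # two alternative transcripts (one exon dropped) to exercise the
    # most-exons transcript-choice rule
    picked = 0
    for gene in genes:
        if len(gene.exons) >= 5 and picked < 2:
            gene.alt_exons = gene.exons[:2] + gene.exons[3:]
            picked += 1
    sizes = {c: cursors[c] + spec.intergenic for c in cursors}
    return genes, sizes


# ---------------------------------------------------------------------------
# circ selection


@dataclass
class _Circ:
    gene: _Gene
    i: int  # transcript-order index of the upstream BSE (0-based)
    j: int

    @property
    def start_up_bse(self) -> int:
        ex = self.gene.tx_exons()[self.i]
        return ex[0] if self.gene.strand == "+" else ex[1]

    @property
    def end_down_bse(self) -> int:
        ex = self.gene.tx_exons()[self.j]
        return ex[1] if self.gene.strand == "+" else ex[0]

    @property
    def circ_id(self) -> str:
        return "|".join(
            (
                self.gene.gene_id,
                self.gene.strand,
                self.gene.chrom,
                str(self.start_up_bse),
                str(self.end_down_bse),
            )
        )

    @property
    def has_intron_up(self) -> bool:
        return self.i > 0

    @property
    def has_intron_down(self) -> bool:
        return self.j < len(self.gene.exons) - 1


def _select_circs(
    spec: FixtureSpec, genes: list[_Gene], rng: np.random.Generator
) -> tuple[list[_Circ], _Circ]:
    """Pick ground-truth circs; returns (all circs, the miRNA-site circ)."""
    plus_genes = [g for g in genes if g.strand == "+" and len(g.exons) >= 4]
    site_gene = plus_genes[0]
    site_circ = _Circ(gene=site_gene, i=1, j=2)  # both flanking introns exist
    chosen: dict[str, _Circ] = {site_circ.circ_id: site_circ}

    # guaranteed boundary cases: a single-exon circ and a full-span circ
    single_gene = next(g for g in genes if len(g.exons) >= 3 and g is not site_gene)
    single = _Circ(gene=single_gene, i=1, j=1)
    chosen.setdefault(single.circ_id, single)
    full_gene = next(g for g in genes if g is not site_gene and g is not single_gene)
    full = _Circ(gene=full_gene, i=0, j=len(full_gene.exons) - 1)
    chosen.setdefault(full.circ_id, full)

    attempts = 0
    while len(chosen) < spec.n_circs and attempts < spec.n_circs * 200:
        attempts += 1
        gene = genes[int(rng.integers(len(genes)))]
        n = len(gene.exons)
        # favour interior exon pairs so flanking introns usually exist
        if n >= 3 and rng.random() < 0.8:
            i = int(rng.integers(1, n - 1))
            j = int(rng.integers(i, n - 1))
        else:
            i = int(rng.integers(0, n))
            j = int(rng.integers(i, n))
        c = _Circ(gene=gene, i=i, j=j)
        chosen.setdefault(c.circ_id, c)
    return list(chosen.values()), site_circ


def _pick_decoys(
    genes: list[_Gene], taken: set[str], rng: np.random.Generator, k: int
) -> list[_Circ]:
    out: list[_Circ] = []
    while len(out) < k:
        gene = genes[int(rng.integers(len(genes)))]
        n = len(gene.exons)
        i = int(rng.integers(0, n))
        j = int(rng.integers(i, n))
        c = _Circ(gene=gene, i=i, j=j)
        if c.circ_id in taken:
            continue
        taken.add(c.circ_id)
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# tool-dialect writers (the mirror image of circkit.dialects)


def _tool_row(tool: str, chrom: str, strand: str, gs: int, ge: int, gene: str, count: int, idx: int) -> str:
    if tool == "generic":
        return f"{chrom}\t{strand}\t{gs}\t{ge}\t{gene}\t{count}"
    if tool == "mapsplice2":
        return f"{chrom}\t{gs}\t{ge}\t{gene}\t{count}\t{strand}"
    if tool == "nclscan":
        return f"{chrom}\t{gs}\t{ge}\t{strand}\t{gene}\t{count}"
    if tool == "circmarker":
        return f"{chrom}\t{gs}\t{ge}\t{strand}\t{count}"
    if tool == "circexplorer2":
        return "\t".join(
            [
                chrom,
                str(gs - 1),
                str(ge),
                f"circ_{idx}",
                "0",
                strand,
                str(gs - 1),
                str(ge),
                "0,0,0",
                "1",
                "0",
                "0",
                str(count),
                "circRNA",
                gene,
                "NA",
            ]
        )
    if tool == "knife":
        return f"{chrom}|{gene}:{gs}|{gene}:{ge}|reg|{strand}\t{count}"
    if tool == "uroborus":
        return f"{chrom}\t{gs - 1}\t{ge}\t{strand}\tx\t{gene}\t{count}"
    raise ValueError(tool)


# ---------------------------------------------------------------------------
# chains


def _fixture_chains(sizes: dict[str, int]) -> dict[str, list[ChainAlignment]]:
    chains: dict[str, list[ChainAlignment]] = {}
    ident = []
    for k, (chrom, L) in enumerate(sorted(sizes.items())):
        ident.append(
            ChainAlignment(
                score=1000,
                t_name=chrom,
                t_size=L,
                t_strand="+",
                t_start=0,
                t_end=L,
                q_name=f"m_{chrom}",
                q_size=L,
                q_strand="+",
                q_start=0,
                q_end=L,
                blocks=(ChainBlock(L),),
                chain_id=str(k + 1),
            )
        )
    chains["identity"] = ident

    L1 = sizes["chr1"]
    shift = ChainAlignment(
        score=900,
        t_name="chr1",
        t_size=L1,
        t_strand="+",
        t_start=0,
        t_end=L1,
        q_name="m_chr1",
        q_size=L1 + 2000,
        q_strand="+",
        q_start=1000,
        q_end=1000 + L1,
        blocks=(ChainBlock(L1),),
        chain_id="1",
    )
    chains["shift"] = [shift]
    chains["shift_inverse"] = [invert_chain(shift)]

    chains["inversion"] = [
        ChainAlignment(
            score=850,
            t_name="chr1",
            t_size=L1,
            t_strand="+",
            t_start=0,
            t_end=L1,
            q_name="m_chr1_inv",
            q_size=L1,
            q_strand="-",
            q_start=0,
            q_end=L1,
            blocks=(ChainBlock(L1),),
            chain_id="1",
        )
    ]

    gapped = ChainAlignment(
        score=800,
        t_name="chr1",
        t_size=L1,
        t_strand="+",
        t_start=2000,
        t_end=7000,
        q_name="m_chr1_g",
        q_size=20000,
        q_strand="+",
        q_start=3000,
        q_end=7600,
        blocks=(
            ChainBlock(800, 200, 100),
            ChainBlock(1000, 300, 0),
            ChainBlock(700, 0, 250),
            ChainBlock(1500, 400, 150),
            ChainBlock(100),
        ),
        chain_id="1",
    )
    chains["gapped"] = [gapped]
    chains["gapped_inverse"] = [invert_chain(gapped)]

    # 10-kb oracle target: shift block, gapped chain, inverted chain on
    # disjoint regions of a dedicated pseudo-chromosome
    oracle = [
        ChainAlignment(
            score=900,
            t_name="t_oracle",
            t_size=10000,
            t_strand="+",
            t_start=0,
            t_end=3000,
            q_name="q_oracle",
            q_size=20000,
            q_strand="+",
            q_start=500,
            q_end=3500,
            blocks=(ChainBlock(3000),),
            chain_id="1",
        ),
        ChainAlignment(
            score=800,
            t_name="t_oracle",
            t_size=10000,
            t_strand="+",
            t_start=3000,
            t_end=8000,
            q_name="q_oracle",
            q_size=20000,
            q_strand="+",
            q_start=4000,
            q_end=8600,
            blocks=(
                ChainBlock(800, 200, 100),
                ChainBlock(1000, 300, 0),
                ChainBlock(700, 0, 250),
                ChainBlock(1500, 400, 150),
                ChainBlock(100),
            ),
            chain_id="2",
        ),
        ChainAlignment(
            score=700,
            t_name="t_oracle",
            t_size=10000,
            t_strand="+",
            t_start=8000,
            t_end=10000,
            q_name="q_oracle",
            q_size=20000,
            q_strand="-",
            q_start=1000,
            q_end=3000,
            blocks=(ChainBlock(2000),),
            chain_id="3",
        ),
    ]
    chains["oracle"] = oracle

    # the pipeline chain: chr1 lifts, chr2 does not -> about half the
    # junctions are "conserved", mirroring a cross-species lift
    chains["to_mouse"] = [ident[0]]
    return chains


# ---------------------------------------------------------------------------
# main entry


def build_fixture(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Write the full fixture tree under ``outdir``; returns the
    manifest (also written to ``manifest.json``)."""
    outdir = Path(outdir)
    (outdir / "tools").mkdir(parents=True, exist_ok=True)
    (outdir / "chains").mkdir(exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    genes, sizes = _layout_genes(spec, rng)
    seqs = {c: rng.choice(BASES, size=L) for c, L in sorted(sizes.items())}

    circs, site_circ = _select_circs(spec, genes, rng)
    circs.sort(key=lambda c: c.circ_id)
    truth_ids = {c.circ_id for c in circs}

    # ----- miRNAs and planted seed sites ------------------------------
    mirnas = []
    for k in range(spec.n_mirnas):
        mat = "".join(rng.choice(BASES, size=22)).replace("T", "U")
        mirnas.append((f"mir-{k + 1}", mat))
    planted_mirna_id, planted_mature = mirnas[0]
    seed7 = planted_mature[1:8]
    perfect_window = reverse_complement(seed7.replace("U", "T"))

    # genomic map of the site circ's internal sequence ('+' strand gene)
    site_exons = site_circ.gene.tx_exons()[site_circ.i : site_circ.j + 1]
    pos_map: list[int] = []
    for s, e in site_exons:
        pos_map.extend(range(s, e + 1))
    L_int = len(pos_map)
    chrom_arr = seqs[site_circ.gene.chrom]

    def plant(p0: int) -> None:  # p0 is a 0-based internal position
        for k, ch in enumerate(perfect_window):
            gpos = pos_map[(p0 + k) % L_int]
            chrom_arr[gpos - 1] = ch

    interior = [20 + 40 * k for k in range(spec.n_interior_sites)]
    for p0 in interior:
        plant(p0)
    junction_p0 = L_int - 3  # window wraps: 3 nt at the end, 4 at the start
    plant(junction_p0)

    # ----- counts -----------------------------------------------------
    samples = [
        f"{cond}{i + 1}"
        for cond in spec.conditions
        for i in range(spec.n_samples_per_condition)
    ]
    cond_of = {
        s: spec.conditions[0] if s.startswith(spec.conditions[0]) else spec.conditions[1]
        for s in samples
    }
    base_mean = {
        c.circ_id: float(
            np.exp(rng.uniform(np.log(spec.mean_range[0]), np.log(spec.mean_range[1])))
        )
        for c in circs
    }
    de_ids = [c.circ_id for c in circs[: spec.n_de]]
    planted_de = {cid: (spec.de_log2fc if k % 2 == 0 else -spec.de_log2fc) for k, cid in enumerate(de_ids)}

    r = 1.0 / spec.dispersion

    def nb(mean: float) -> int:
        return int(rng.negative_binomial(r, r / (r + mean)))

    counts: dict[tuple[str, str, str], int] = {}  # (circ_id, tool, sample)
    for c in circs:
        for tool in TOOLS:
            for s in samples:
                m = base_mean[c.circ_id]
                if c.circ_id in planted_de and cond_of[s] == spec.conditions[1]:
                    m *= 2.0 ** planted_de[c.circ_id]
                counts[(c.circ_id, tool, s)] = nb(m)

    # tool-specific decoys: low counts, single tool, removed by the
    # prevalence filter
    taken = set(truth_ids)
    decoys: dict[str, list[_Circ]] = {}
    for tool in TOOLS:
        decoys[tool] = _pick_decoys(genes, taken, rng, spec.n_decoys_per_tool)
        for d in decoys[tool]:
            for s in samples:
                counts[(d.circ_id, tool, s)] = int(rng.integers(0, 5))

    # antisense records: strand flipped relative to the gene, on exact
    # exon boundaries, reported by two tools
    anti: list[dict] = []
    for c in _pick_decoys(genes, taken, rng, spec.n_antisense):
        flip = "-" if c.gene.strand == "+" else "+"
        lo = min(c.start_up_bse, c.end_down_bse)
        hi = max(c.start_up_bse, c.end_down_bse)
        up, down = orient(flip, lo, hi)
        cid = f"{c.gene.gene_id}|{flip}|{c.gene.chrom}|{up}|{down}"
        anti.append(
            {
                "circ_id": cid,
                "gene": c.gene.gene_id,
                "strand": flip,
                "chrom": c.gene.chrom,
                "startUpBSE": up,
                "endDownBSE": down,
            }
        )
        for tool in ANTISENSE_TOOLS:
            for s in samples:
                counts[(cid, tool, s)] = int(rng.integers(2, 9))

    # ----- tool files -------------------------------------------------
    files: dict[str, dict[str, str]] = {}
    for tool in TOOLS:
        tdir = outdir / "tools" / tool
        tdir.mkdir(exist_ok=True)
        files[tool] = {}
        for s in samples:
            rows = []
            idx = 0
            for c in circs + decoys[tool]:
                key = (c.circ_id, tool, s)
                if key not in counts:
                    continue
                idx += 1
                lo = min(c.start_up_bse, c.end_down_bse)
                hi = max(c.start_up_bse, c.end_down_bse)
                rows.append(
                    _tool_row(
                        tool, c.gene.chrom, c.gene.strand, lo, hi, c.gene.gene_id, counts[key], idx
                    )
                )
            if tool in ANTISENSE_TOOLS:
                for a in anti:
                    idx += 1
                    lo = min(a["startUpBSE"], a["endDownBSE"])
                    hi = max(a["startUpBSE"], a["endDownBSE"])
                    rows.append(
                        _tool_row(tool, a["chrom"], a["strand"], lo, hi, a["gene"], counts[(a["circ_id"], tool, s)], idx)
                    )
            path = tdir / f"{s}.tsv"
            path.write_text("\n".join(rows) + "\n")
            files[tool][s] = str(path.relative_to(outdir))

    # ----- genome + GTF ----------------------------------------------
    with open(outdir / "genome.fa", "w") as fh:
        for chrom in sorted(seqs):
            fh.write(f">{chrom}\n")
            s = "".join(seqs[chrom])
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")

    with open(outdir / "annotation.gtf", "w") as fh:
        for gene in genes:
            gstart = gene.exons[0][0]
            gend = gene.exons[-1][1]
            attrs = f'gene_id "{gene.gene_id}"; gene_name "{gene.gene_id}";'
            fh.write(
                f"{gene.chrom}\tfixture\tgene\t{gstart}\t{gend}\t.\t{gene.strand}\t.\t{attrs}\n"
            )
            tx_sets = [(f"{gene.gene_id}.t1", gene.exons)]
            if gene.alt_exons is not None:
                tx_sets.append((f"{gene.gene_id}.t2", gene.alt_exons))
            for tx_id, exons in tx_sets:
                tattrs = attrs + f' transcript_id "{tx_id}";'
                fh.write(
                    f"{gene.chrom}\tfixture\ttranscript\t{exons[0][0]}\t{exons[-1][1]}\t.\t"
                    f"{gene.strand}\t.\t{tattrs}\n"
                )
                for es, ee in exons:
                    fh.write(
                        f"{gene.chrom}\tfixture\texon\t{es}\t{ee}\t.\t{gene.strand}\t.\t{tattrs}\n"
                    )

    # ----- design -----------------------------------------------------
    with open(outdir / "design.tsv", "w") as fh:
        for s in samples:
            fh.write(f"{s}\t{cond_of[s]}\n")

    # ----- miRNA fasta + expression ----------------------------------
    with open(outdir / "mirnas.fa", "w") as fh:
        for mid, mat in mirnas:
            fh.write(f">{mid}\n{mat}\n")
    n_pass = max(1, int(round(spec.n_mirnas * 0.6)))
    expr_cols = [f"c{i + 1}" for i in range(spec.mirna_expr_samples)]
    surviving = []
    with open(outdir / "mirna_expression.tsv", "w") as fh:
        fh.write("mirna_id\t" + "\t".join(expr_cols) + "\n")
        for k, (mid, _) in enumerate(mirnas):
            if k < n_pass:
                vals = rng.integers(
                    int(spec.mirna_min_mean), int(spec.mirna_min_mean * 10), size=spec.mirna_expr_samples
                )
                surviving.append(mid)
            else:
                vals = rng.integers(0, int(spec.mirna_min_mean) - 1, size=spec.mirna_expr_samples)
            fh.write(mid + "\t" + "\t".join(str(int(v)) for v in vals) + "\n")

    # ----- motif database + planted enrichment sets ------------------
    with open(outdir / "motifs.tsv", "w") as fh:
        fh.write("motif_id\trbp_name\tpattern\n")
        for mid, rbp, pat in MOTIF_DB:
            fh.write(f"{mid}\t{rbp}\t{pat}\n")
    planted_pattern = MOTIF_DB[0][2]

    def _enrich_set(per_seq: int, prefix: str, path: Path) -> None:
        with open(path, "w") as fh:
            for i in range(spec.enrich_n_seqs):
                arr = rng.choice(BASES, size=spec.enrich_seq_len)
                seg = spec.enrich_seq_len // per_seq
                for k in range(per_seq):
                    off = int(rng.integers(0, seg - len(planted_pattern)))
                    p = seg * k + off
                    arr[p : p + len(planted_pattern)] = list(planted_pattern)
                fh.write(f">{prefix}{i + 1}|window_up|{spec.enrich_seq_len}\n")
                s = "".join(arr)
                for a in range(0, len(s), 60):
                    fh.write(s[a : a + 60] + "\n")

    _enrich_set(spec.enrich_bg_per_seq * spec.enrich_fold, "fg", outdir / "enrichment_fg.fa")
    _enrich_set(spec.enrich_bg_per_seq, "bg", outdir / "enrichment_bg.fa")

    # ----- repeats: inverted Alu pairs in half the eligible circs -----

    def _intron_intervals(c: _Circ) -> tuple[tuple[int, int], tuple[int, int]]:
        tx = c.gene.tx_exons()
        up_pair = sorted([tx[c.i - 1], tx[c.i]], key=lambda e: e[0])
        down_pair = sorted([tx[c.j], tx[c.j + 1]], key=lambda e: e[0])
        up = (up_pair[0][1] + 1, up_pair[1][0] - 1)
        down = (down_pair[0][1] + 1, down_pair[1][0] - 1)
        return up, down

    # eligible circs have both flanking introns AND introns disjoint
    # from every other eligible circ's introns, so planted repeats are
    # visible to exactly one circ and the planted fraction is exact
    eligible: list[_Circ] = []
    used_introns: list[tuple[str, int, int]] = []
    for c in circs:
        if not (c.has_intron_up and c.has_intron_down):
            continue
        up, down = _intron_intervals(c)
        ivs = [(c.gene.chrom, *up), (c.gene.chrom, *down)]
        clash = any(
            ch == uch and lo <= uhi and ulo <= hi
            for (ch, lo, hi) in ivs
            for (uch, ulo, uhi) in used_introns
        )
        if clash:
            continue
        eligible.append(c)
        used_introns.extend(ivs)
    n_pair = len(eligible) // 2
    order = [eligible[int(k)] for k in rng.permutation(len(eligible))]
    pair_circs = order[:n_pair]
    neg_circs = order[n_pair:]

    repeat_rows = []
    for c in pair_circs:
        up, down = _intron_intervals(c)
        s1 = "+" if rng.random() < 0.5 else "-"
        s2 = "-" if s1 == "+" else "+"
        repeat_rows.append((c.gene.chrom, up[0] + 4, up[0] + 54, s1, "AluSx", "SINE", "Alu"))
        repeat_rows.append((c.gene.chrom, down[0] + 4, down[0] + 54, s2, "AluJb", "SINE", "Alu"))
    for k, c in enumerate(neg_circs):
        up, down = _intron_intervals(c)
        if k % 3 == 0:  # same-strand Alu pair: not complementary
            repeat_rows.append((c.gene.chrom, up[0] + 4, up[0] + 54, "+", "AluSx", "SINE", "Alu"))
            repeat_rows.append((c.gene.chrom, down[0] + 4, down[0] + 54, "+", "AluY", "SINE", "Alu"))
        elif k % 3 == 1:  # opposite strands but not Alu
            repeat_rows.append((c.gene.chrom, up[0] + 4, up[0] + 54, "+", "L1MC4", "LINE", "L1"))
            repeat_rows.append((c.gene.chrom, down[0] + 4, down[0] + 54, "-", "MIRb", "SINE", "MIR"))
        # k % 3 == 2: no repeats at all
    with open(outdir / "rmsk.tsv", "w") as fh:
        fh.write("genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass\trepFamily\n")
        for chrom, s1, e1, st, name, cls, fam in repeat_rows:
            fh.write(f"{chrom}\t{s1 - 1}\t{e1}\t{st}\t{name}\t{cls}\t{fam}\n")

    # ----- GWAS SNPs --------------------------------------------------
    snp_rows = []
    planted_snps = []
    traits_in = ["Atrial fibrillation", "Coronary artery disease", "Vascular stiffness"]
    rs = 1000
    for k, c in enumerate(order[: min(spec.n_snps_in_flanks, len(order))]):
        up, down = _intron_intervals(c)
        side = "up" if k % 2 == 0 else "down"
        iv = up if side == "up" else down
        pos = iv[0] if k == 0 else int((iv[0] + iv[1]) // 2)  # one boundary case
        rs += 1
        trait = traits_in[k % len(traits_in)]
        snp_rows.append((c.gene.chrom, pos, f"rs{rs}", trait))
        planted_snps.append({"circ_id": c.circ_id, "side": side, "rsid": f"rs{rs}", "pos": pos})
    for k in range(spec.n_snps_outside):  # cardiac trait, intergenic: outside all flanks
        rs += 1
        snp_rows.append((f"chr{k % spec.n_chroms + 1}", 50 + k, f"rs{rs}", traits_in[k % 3]))
    for k, c in enumerate(order[: min(spec.n_snps_offtrait, len(order))]):
        # in flanks but a non-cardiac trait: removed by the trait filter
        up, _ = _intron_intervals(c)
        rs += 1
        snp_rows.append((c.gene.chrom, up[0] + 20 + k, f"rs{rs}", "Educational attainment"))
    with open(outdir / "gwas.tsv", "w") as fh:
        fh.write("CHR_ID\tCHR_POS\tSNPS\tDISEASE/TRAIT\n")
        for chrom, pos, rsid, trait in snp_rows:
            fh.write(f"{chrom.removeprefix('chr')}\t{pos}\t{rsid}\t{trait}\n")

    # ----- chains -----------------------------------------------------
    chain_files = {}
    for name, chains in _fixture_chains(sizes).items():
        path = outdir / "chains" / f"{name}.chain"
        serialize_chain(chains, path)
        chain_files[name] = str(path.relative_to(outdir))

    # ----- run config -------------------------------------------------
    config = {
        "seed": spec.seed,
        "outdir": "results",
        "genome": "genome.fa",
        "gtf": "annotation.gtf",
        "design": "design.tsv",
        "chain": chain_files["to_mouse"],
        "motif_db": "motifs.tsv",
        "mirna_fasta": "mirnas.fa",
        "mirna_expression": "mirna_expression.tsv",
        "gwas": "gwas.tsv",
        "repeats": "rmsk.tsv",
        "gwas_traits": "cardiac|coronary|vascular|atrial",
        "tools": {t: {"dialect": t, "files": files[t]} for t in TOOLS},
        "contrast": [spec.conditions[0], spec.conditions[1]],
    }
    import yaml

    with open(outdir / "config.yml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)

    manifest = {
        "spec": asdict(spec),
        "chrom_sizes": sizes,
        "samples": samples,
        "conditions": list(spec.conditions),
        "files": {
            "genome": "genome.fa",
            "gtf": "annotation.gtf",
            "design": "design.tsv",
            "config": "config.yml",
            "tools": files,
            "chains": chain_files,
            "mirna_fasta": "mirnas.fa",
            "mirna_expression": "mirna_expression.tsv",
            "motif_db": "motifs.tsv",
            "enrichment_fg": "enrichment_fg.fa",
            "enrichment_bg": "enrichment_bg.fa",
            "gwas": "gwas.tsv",
            "repeats": "rmsk.tsv",
        },
        "genes": {
            g.gene_id: {
                "chrom": g.chrom,
                "strand": g.strand,
                "n_exons": len(g.exons),
                "has_alt_transcript": g.alt_exons is not None,
            }
            for g in genes
        },
        "truth_circs": [
            {
                "circ_id": c.circ_id,
                "gene": c.gene.gene_id,
                "strand": c.gene.strand,
                "chrom": c.gene.chrom,
                "startUpBSE": c.start_up_bse,
                "endDownBSE": c.end_down_bse,
                "n_exons": c.j - c.i + 1,
                "has_intron_up": c.has_intron_up,
                "has_intron_down": c.has_intron_down,
            }
            for c in circs
        ],
        # circmarker has no gene column, so its decoys surface with gene
        # "." after merging (no gene-named record shares their coordinates)
        "decoys": {
            t: [
                d.circ_id
                if t != "circmarker"
                else "|".join(
                    (
                        ".",
                        d.gene.strand,
                        d.gene.chrom,
                        str(d.start_up_bse),
                        str(d.end_down_bse),
                    )
                )
                for d in decoys[t]
            ]
            for t in TOOLS
        },
        "antisense": anti,
        "planted_de": planted_de,
        "base_means": base_mean,
        "total_reads": int(sum(counts.values())),
        "mirna_sites": {
            "mirna_id": planted_mirna_id,
            "circ_id": site_circ.circ_id,
            "internal_length": L_int,
            "interior_positions": [p + 1 for p in interior],
            "junction_position": junction_p0 + 1,
        },
        "mirna_surviving": surviving,
        "motif_planted": {
            "motif_id": MOTIF_DB[0][0],
            "pattern": planted_pattern,
            "fold": spec.enrich_fold,
        },
        "repeat_pairs": {
            "eligible": [c.circ_id for c in eligible],
            "planted": sorted(c.circ_id for c in pair_circs),
            "fraction": n_pair / len(eligible) if eligible else 0.0,
        },
        "gwas_snps": {
            "in_flank_cardiac": planted_snps,
            "n_outside": spec.n_snps_outside,
            "n_offtrait": spec.n_snps_offtrait,
        },
        "liftable_chroms": ["chr1"],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
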