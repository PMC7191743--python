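"""Run configuration: one YAML file naming inputs, tools and thresholds.

Defaults mirror the package's reference analysis settings: prevalence
filter >= 5 reads in >= 3 samples of one condition, differential
expression cutoffs |log2FC| >= 1 at BH-adjusted p <= 0.05, biogenesis
windows of 200 intronic + 10 exonic nt, and miRNA seed stringency of
>= 6 total matches with >= 5 Watson-Crick and at most 1 G:U wobble.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import yaml

THRESHOLD_DEFAULTS: dict[str, float | int | str] = {
    "min_count": 5,
    "min_samples": 3,
    "lfc_cut": 1.0,
    "alpha": 0.05,
    "intron_nt": 200,
    "exon_nt": 10,
    "across_bsj_w": 11,
    "mirna_min_total": 6,
    "mirna_min_wc": 5,
    "mirna_max_wobble": 1,
    "mirna_min_mean": 10.0,
    "collapse_mode": "max",
    "n_random": 50,
}


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    genome: Path
    gtf: Path
    design: Path
    tools: dict[str, dict]  # tool -> {"dialect": name, "files": {sample: Path}}
    contrast: tuple[str, str] | None = None
    chain: Path | None = None
    motif_db: Path | None = None
    mirna_fasta: Path | None = None
    mirna_expression: Path | None = None
    gwas: Path | None = None
    repeats: Path | None = None
    gwas_traits: str | None = None
    thresholds: dict = dc_field(default_factory=dict)

    def threshold(self, key: str):
        return self.thresholds.get(key, THRESHOLD_DEFAULTS[key])


REQUIRED_KEYS = ("genome", "gtf", "design", "tools")
OPTIONAL_PATH_KEYS = ("chain", "motif_db", "mirna_fasta", "mirna_expression", "gwas", "repeats")


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a run configuration.

    Relative paths resolve against the config file's directory.  All
    problems (missing keys, absent files) are reported in one error.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    base = path.parent
    problems: list[str] = []

    def resolve(p: str | None) -> Path | None:
        if p is None:
            return None
        q = Path(p)
        return q if q.is_absolute() else base / q

    for key in REQUIRED_KEYS:
        if key not in raw:
            problems.append(f"missing required key: {key}")

    paths: dict[str, Path | None] = {}
    for key in ("genome", "gtf", "design") + OPTIONAL_PATH_KEYS:
        p = resolve(raw.get(key))
        paths[key] = p
        if p is not None and not p.exists():
            problems.append(f"{key}: file not found: {p}")

    tools: dict[str, dict] = {}
    for tool, tc in sorted((raw.get("tools") or {}).items()):
        files = {}
        for sample, fp in sorted((tc.get("files") or {}).items()):
            rp = resolve(fp)
            if not rp.exists():
                problems.append(f"tools.{tool}.files.{sample}: file not found: {rp}")
            files[sample] = rp
        tools[tool] = {"dialect": tc.get("dialect", tool), "files": files}
    if not tools and "tools" in raw:
        problems.append("tools: at least one tool with files is required")

    thresholds = dict(raw.get("thresholds") or {})
    unknown = [k for k in thresholds if k not in THRESHOLD_DEFAULTS]
    if unknown:
        problems.append(f"unknown threshold keys: {unknown}")

    if problems:
        raise ValueError(f"invalid config {path}:\n  " + "\n  ".join(problems))

    contrast = raw.get("contrast")
    if contrast is not None:
        if isinstance(contrast, str):
            contrast = contrast.split(":")
        if len(contrast) != 2:
            raise ValueError(f"{path}: contrast must name exactly two conditions")
        contrast = (contrast[0], contrast[1])

    return RunConfig(
        seed=int(raw.get("seed", 0)),
        outdir=resolve(raw.get("outdir", "results")),
        genome=paths["genome"],
        gtf=paths["gtf"],
        design=paths["design"],
        tools=tools,
        contrast=contrast,
        chain=paths["chain"],
        motif_db=paths["motif_db"],
        mirna_fasta=paths["mirna_fasta"],
        mirna_expression=paths["mirna_expression"],
        gwas=paths["gwas"],
        repeats=paths["repeats"],
        gwas_traits=raw.get("gwas_traits"),
        thresholds=thresholds,
    )


def echo_resolved(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration (defaults injected) for
    provenance; the echo revalidates to an identical RunConfig."""
    out = {
        "seed": config.seed,
        "outdir": str(config.outdir),
        "genome": str(config.genome),
        "gtf": str(config.gtf),
        "design": str(config.design),
        "tools": {
            t: {"dialect": tc["dialect"], "files": {s: str(p) for s, p in tc["files"].items()}}
            for t, tc in config.tools.items()
        },
        "contrast": list(config.contrast) if config.contrast else None,
        "gwas_traits": config.gwas_traits,
        "thresholds": {k: config.threshold(k) for k in sorted(THRESHOLD_DEFAULTS)},
    }
    for key in OPTIONAL_PATH_KEYS:
        val = getattr(config, key)
        out[key] = str(val) if val is not None else None
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
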