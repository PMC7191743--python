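"""Random back-splice junction background sets.

Enrichment questions (are RBP motifs or miRNA sites denser around real
BSJs?) need a null: exon pairs drawn from the same annotation that are
not observed circRNAs.  Sampling is uniform over transcripts, then
uniform over exon index pairs i <= j of the drawn transcript; draws
matching an observed circ or a previous draw are rejected.  Every
accepted record therefore sits on exact annotated exon boundaries and
is a valid input to every downstream module.
"""

from __future__ import annotations

import numpy as np

from .annotation import GeneModel
from .records import BsjRecord, orient

MAX_ATTEMPTS_PER_RECORD = 1000


def generate_random_bsjs(
    model: GeneModel,
    n: int,
    exclude: set[str] | None = None,
    seed: int = 0,
) -> list[BsjRecord]:
    """Draw ``n`` distinct random BSJs from the gene model.

    ``exclude`` holds circ_ids of the observed (foreground) set; drawn
    records colliding with it or with each other are rejected.
    Deterministic given ``seed``.  Raises after ``n * 1000`` attempts if
    the annotation cannot supply enough distinct records.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    transcripts = model.transcripts
    if not transcripts:
        raise ValueError("gene model has no transcripts")
    exclude = exclude or set()
    rng = np.random.default_rng(seed)
    out: list[BsjRecord] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = n * MAX_ATTEMPTS_PER_RECORD
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not draw {n} distinct random BSJs in {max_attempts} "
                "attempts; annotation too small or exclusion set too large"
            )
        tx = transcripts[int(rng.integers(len(transcripts)))]
        a = int(rng.integers(tx.n_exons))
        b = int(rng.integers(tx.n_exons))
        i, j = min(a, b), max(a, b)
        start_up = tx.transcribed_start(i)
        end_down = tx.transcribed_end(j)
        up, down = orient(tx.strand, min(start_up, end_down), max(start_up, end_down))
        rec = BsjRecord(
            gene=tx.gene,
            strand=tx.strand,
            chrom=tx.chrom,
            start_up_bse=up,
            end_down_bse=down,
        )
        if rec.circ_id in exclude or rec.circ_id in seen:
            continue
        seen.add(rec.circ_id)
        out.append(rec)
    return out
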