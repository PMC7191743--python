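"""Seed pairing with G:U wobble and junction-aware site scanning."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import reverse_complement

from circkit.mirna import (
    MirnaSeed,
    filter_mirnas,
    find_sites,
    load_mirna_fasta,
    score_window,
)
from circkit.sequences import SeqRecordC


def brute_pair(seed: str, window: str) -> tuple[int, int]:
    """Independent pairing oracle: pair seed 5'->3' against the window
    read 3'->5', case by case."""
    wc = wob = 0
    for s, t in zip(seed, reversed(window)):
        if (s, t) in {("A", "T"), ("U", "A"), ("G", "C"), ("C", "G")}:
            wc += 1
        elif (s, t) in {("G", "T"), ("U", "G")}:
            wob += 1
    return wc, wob


def perfect_site(seed: str) -> str:
    """The 7-nt DNA window pairing the seed with 7 Watson-Crick matches."""
    return reverse_complement(seed.replace("U", "T"))


class TestScoreWindow:
    def test_perfect_complement_scores_seven_wc(self):
        seed = "AGCUUAU"
        assert perfect_site(seed) == "ATAAGCT"
        assert score_window(seed, "ATAAGCT") == (7, 0)

    def test_single_gu_substitution(self):
        # seed[1] == 'G' pairs reversed(window)[1] == window[5] == 'C';
        # turning that C into T converts one WC match into a G:U wobble
        seed = "AGCUUAU"
        window = list("ATAAGCT")
        window[5] = "T"
        assert score_window(seed, "".join(window)) == (6, 1)

    def test_n_counts_as_mismatch(self):
        seed = "AGCUUAU"
        window = list("ATAAGCT")
        window[0] = "N"
        assert score_window(seed, "".join(window)) == (6, 0)

    def test_agrees_with_brute_force_on_random_windows(self):
        rng = np.random.default_rng(0)
        seed = "GAUCGUA"
        for _ in range(500):
            window = "".join(rng.choice(list("ACGT"), size=7))
            assert score_window(seed, window) == brute_pair(seed, window)

    def test_wrong_length_is_error(self):
        with pytest.raises(ValueError):
            score_window("AGCUUA", "ATAAGCT")


def _circ(seq):
    return SeqRecordC("circX", "internal", seq, circular=True)


MIRNA = MirnaSeed("mir-t", "UAGCUUAUCAGACUGAUGUUGA")  # seed AGCUUAU


class TestFindSites:
    def test_perfect_interior_site_found(self):
        site = perfect_site(MIRNA.seed)
        seq = "GGGGGG" + site + "GGGGGGG"
        sites = find_sites(_circ(seq), [MIRNA])
        perfect = [s for s in sites if s.wc == 7]
        assert len(perfect) == 1
        assert perfect[0].pos == 7 and not perfect[0].spans_junction

    def test_junction_spanning_site_found_only_by_circular_scan(self):
        site = perfect_site(MIRNA.seed)
        # split 3 + 4: last 3 nt at the sequence end, first 4 at the start
        seq = site[3:] + "GGGGGGGGGGGG" + site[:3]
        circ = _circ(seq)
        circular_hits = [s for s in find_sites(circ, [MIRNA]) if s.wc == 7]
        assert len(circular_hits) == 1
        hit = circular_hits[0]
        assert hit.spans_junction and hit.pos == len(seq) - 2
        linear_hits = [s for s in find_sites(circ, [MIRNA], circular=False) if s.wc == 7]
        assert linear_hits == []

    def test_rotation_invariance_of_score_multiset(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        mirnas = [MirnaSeed(f"m{i}", "".join(rng.choice(list("ACGU"), size=22))) for i in range(4)]
        base = sorted(
            (s.mirna_id, s.wc, s.wobble) for s in find_sites(_circ(seq), mirnas, min_total=5, min_wc=4)
        )
        for shift in (1, 17, 150, 299):
            rotated = seq[shift:] + seq[:shift]
            got = sorted(
                (s.mirna_id, s.wc, s.wobble)
                for s in find_sites(_circ(rotated), mirnas, min_total=5, min_wc=4)
            )
            assert got == base

    def test_matches_rotation_dedup_oracle(self):
        """Site starts agree with a scanner that rotates the sequence
        through every phase and deduplicates positions."""
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        got = {(s.mirna_id, s.pos) for s in find_sites(_circ(seq), [MIRNA])}
        expected = set()
        for phase in range(len(seq)):
            rotated = seq[phase:] + seq[:phase]
            window = rotated[:7]
            wc, wob = brute_pair(MIRNA.seed, window)
            if wc + wob >= 6 and wc >= 5 and wob <= 1:
                expected.add((MIRNA.mirna_id, phase + 1))
        assert got == expected

    def test_tightening_thresholds_never_adds_sites(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        loose = {(s.mirna_id, s.pos) for s in find_sites(_circ(seq), [MIRNA], 5, 4, 2)}
        tight = {(s.mirna_id, s.pos) for s in find_sites(_circ(seq), [MIRNA], 6, 5, 1)}
        assert tight <= loose

    def test_short_sequence_returns_empty_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert find_sites(_circ("ACGT"), [MIRNA]) == []
        assert "shorter" in caplog.text

    def test_planted_fixture_sites_recovered(self, fixture_dir, manifest, annotated_truth, genome):
        from circkit.mirna import load_mirna_fasta
        from circkit.sequences import extract_internal

        d = fixture_dir[0]
        info = manifest["mirna_sites"]
        mirnas = [m for m in load_mirna_fasta(d / manifest["files"]["mirna_fasta"]) if m.mirna_id == info["mirna_id"]]
        circ = annotated_truth[info["circ_id"]]
        internal = extract_internal(circ, genome)
        assert internal.length == info["internal_length"]
        sites = find_sites(internal, mirnas)
        perfect_positions = {s.pos for s in sites if s.wc == 7}
        assert set(info["interior_positions"]) <= perfect_positions
        junction = [s for s in sites if s.pos == info["junction_position"]]
        assert junction and junction[0].spans_junction and junction[0].wc == 7


class TestFilterMirnas:
    EXPR = pd.DataFrame(
        {"c1": [10, 9, 50], "c2": [10, 10, 50], "c3": [10, 10, 50], "c4": [10, 10, 50]},
        index=["mir-a", "mir-b", "mir-c"],
    )

    def _mirnas(self, ids):
        return [MirnaSeed(i, "UAGCUUAUCAGACUGAUGUUGA") for i in ids]

    def test_mean_at_threshold_kept_below_dropped(self):
        kept = filter_mirnas(self._mirnas(["mir-a", "mir-b", "mir-c"]), self.EXPR, min_mean=10)
        assert [m.mirna_id for m in kept] == ["mir-a", "mir-c"]  # mir-b mean 9.75

    def test_absent_mirna_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            kept = filter_mirnas(self._mirnas(["mir-zz"]), self.EXPR, min_mean=0)
        assert kept == [] and "absent" in caplog.text

    def test_matches_brute_force_mean_predicate(self):
        rng = np.random.default_rng(4)
        ids = [f"m{i}" for i in range(30)]
        expr = pd.DataFrame(rng.integers(0, 30, size=(30, 4)), index=ids, columns=["c1", "c2", "c3", "c4"])
        kept = {m.mirna_id for m in filter_mirnas(self._mirnas(ids), expr, min_mean=10)}
        expected = {i for i in ids if expr.loc[i].mean() >= 10}
        assert kept == expected


def test_load_mirna_fasta_skips_short_entries(tmp_path, caplog):
    p = tmp_path / "m.fa"
    p.write_text(">ok\nUAGCUUAUCAGACUGAUGUUGA\n>short\nACGU\n")
    with caplog.at_level("WARNING"):
        mirnas = load_mirna_fasta(p)
    assert [m.mirna_id for m in mirnas] == ["ok"]
    assert "too short" in caplog.text
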