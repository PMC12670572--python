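"""Planted-element recovery, strand symmetry, merging, and reporting."""

import numpy as np
import pytest

from prnascreen import (
    ScreenConfig,
    SeqRecord,
    merge_candidates,
    naive_sequence_search,
    recall,
    scan_genome,
    screen_report,
)
from prnascreen.genome_screen import dinucleotide_shuffle, read_report, write_report
from prnascreen.io_formats import reverse_complement
from prnascreen.synthetic_data import (
    diverge,
    make_family,
    plant_in_genome,
    random_background,
    sample_prna,
)

TEMPLATE_LEN = sample_prna(seed=0).record.residues.__len__()


def _screen(genome, **kwargs):
    return merge_candidates(scan_genome(genome, TEMPLATE_LEN, ScreenConfig(**kwargs)))


class TestScanGenome:
    def test_planted_element_recovered_at_zero_divergence(self):
        fam = [sample_prna(seed=5, name="p0")]
        planted = plant_in_genome(fam, 2000, seed=6)
        cands = _screen(planted.genome)
        assert recall(cands, planted.truth) == 1.0

    def test_short_genome_returns_empty(self, caplog):
        g = SeqRecord(id="tiny", residues="ACGU" * 10)
        with caplog.at_level("WARNING"):
            assert scan_genome(g, TEMPLATE_LEN) == []

    def test_candidates_revalidate_against_thresholds(self):
        fam = make_family(2, rate=0.2, seed=8)
        planted = plant_in_genome(fam, 2500, seed=9)
        cfg = ScreenConfig()
        for c in scan_genome(planted.genome, TEMPLATE_LEN, cfg):
            assert c.has_3wj
            assert c.fold_score.pair_energy_total <= cfg.score_threshold
            assert c.coverage >= cfg.min_coverage
            assert c.loop_pair.length >= cfg.min_block_len

    def test_one_sided_loop_destruction_removes_candidate(self):
        # destroying LH/RH complementarity one-sidedly must kill the locus
        p = sample_prna(seed=12, name="intact")
        seq = p.record.residues
        ann = p.annotation
        b0, b1 = ann.rh_block
        # replace the RH block with pyrimidines: no partner change applied
        broken_seq = seq[:b0] + "C" * (b1 - b0) + seq[b1:]
        from dataclasses import replace

        broken = replace(p, record=SeqRecord(id="broken", residues=broken_seq))
        bg = random_background(1200, seed=13)
        genome_ok = SeqRecord(id="g1", residues=bg[:500] + seq + bg[500:])
        genome_ko = SeqRecord(id="g2", residues=bg[:500] + broken_seq + bg[500:])
        truth = ((500, 500 + len(seq), "+", "x"),)
        assert recall(_screen(genome_ok), truth) == 1.0
        assert recall(_screen(genome_ko), truth) == 0.0

    def test_reverse_complement_symmetry(self):
        fam = [sample_prna(seed=21, name="p0")]
        planted = plant_in_genome(fam, 1500, seed=22)
        fwd = scan_genome(planted.genome, TEMPLATE_LEN)
        rc = SeqRecord(
            id=planted.genome.id,
            residues=reverse_complement(planted.genome.residues),
        )
        rev = scan_genome(rc, TEMPLATE_LEN)
        n = len(planted.genome.residues)
        fwd_set = {(c.start, c.end, c.strand, c.fold_score.pair_energy_total) for c in fwd}
        rev_set = {
            (n - c.end, n - c.start, "+" if c.strand == "-" else "-",
             c.fold_score.pair_energy_total)
            for c in rev
        }
        assert fwd_set == rev_set

    def test_minus_strand_plant_detected(self):
        fam = [sample_prna(seed=31, name="p0")]
        planted = plant_in_genome(fam, 1500, strand_policy="minus", seed=32)
        assert planted.truth[0][2] == "-"
        cands = _screen(planted.genome)
        assert recall(cands, planted.truth) == 1.0


class TestMergeCandidates:
    def _fake(self, start, end, score=-50):
        from prnascreen.genome_screen import PRNACandidate
        from prnascreen.loop_pairing import PairBlock, PatternClass
        from prnascreen.structure_fold import FoldScore, SecondaryStructure

        return PRNACandidate(
            genome_id="g",
            start=start,
            end=end,
            strand="+",
            structure=SecondaryStructure(seq="GGGAAACCC", pairs=(-1,) * 9),
            has_3wj=True,
            loop_pair=PairBlock("GG", "CC", 2, 2, 0, 0, 0),
            pattern=PatternClass(True, 0),
            fold_score=FoldScore(pair_energy_total=score, n_pairs=20),
            coverage=1.0,
        )

    def test_identical_intervals_merge(self):
        cands = [self._fake(10, 100), self._fake(10, 100)]
        assert len(merge_candidates(cands)) == 1

    def test_disjoint_unchanged(self):
        cands = [self._fake(0, 90), self._fake(500, 590)]
        assert len(merge_candidates(cands)) == 2

    def test_chain_merges_to_best_score(self):
        cands = [
            self._fake(0, 100, -40),
            self._fake(30, 130, -80),
            self._fake(60, 160, -50),
        ]
        merged = merge_candidates(cands, min_overlap=0.5)
        assert len(merged) == 1
        assert merged[0].fold_score.pair_energy_total == -80


class TestReport:
    def test_empty_report_has_header_only(self, tmp_path):
        out = tmp_path / "r.tsv"
        write_report([], out)
        df = read_report(out)
        assert len(df) == 0 and "genome_id" in df.columns

    def test_interval_round_trip(self, tmp_path):
        fam = [sample_prna(seed=41, name="p0")]
        planted = plant_in_genome(fam, 1500, seed=42)
        cands = _screen(planted.genome)
        out = tmp_path / "r.tsv"
        write_report(cands, out, bed_path=tmp_path / "r.bed")
        df = read_report(out)
        assert [(r.start, r.end) for r in df.itertuples()] == [
            (c.start, c.end) for c in cands
        ]
        bed_lines = (tmp_path / "r.bed").read_text().strip().splitlines()
        assert len(bed_lines) == len(cands)


class TestNullAndNaive:
    def test_dinucleotide_shuffle_preserves_counts(self, rng):
        seq = random_background(200, gc=0.4, seed=1)
        shuf = dinucleotide_shuffle(seq, rng)
        def dinucs(s):
            from collections import Counter
            return Counter(zip(s, s[1:]))
        assert shuf != seq
        assert dinucs(shuf) == dinucs(seq)
        assert shuf[0] == seq[0] and shuf[-1] == seq[-1]

    def test_naive_search_finds_exact_copy_only(self):
        p = sample_prna(seed=51, name="p0")
        bg = random_background(800, seed=52)
        genome = SeqRecord(id="g", residues=bg[:300] + p.record.residues + bg[300:])
        hits = naive_sequence_search(genome, p.record)
        assert hits == [(300, 300 + len(p.record.residues), "+")]
        div = diverge(p, rate=0.3, compensatory=True, seed=53)
        genome2 = SeqRecord(id="g2", residues=bg[:300] + div.record.residues + bg[300:])
        assert naive_sequence_search(genome2, p.record) == []

    def test_naive_search_finds_minus_strand(self):
        p = sample_prna(seed=61, name="p0")
        bg = random_background(600, seed=62)
        ins = reverse_complement(p.record.residues)
        genome = SeqRecord(id="g", residues=bg[:200] + ins + bg[200:])
        assert naive_sequence_search(genome, p.record) == [
            (200, 200 + len(ins), "-")
        ]
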