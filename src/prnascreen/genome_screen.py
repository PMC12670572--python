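"""Structure-based genome screen for pRNA-like elements.

Windows are slid over both strands of a genome; each window is folded by
no-lonely-pair base-pair maximization and kept only if it shows the pRNA
architecture: a three-way junction whose own two arms carry hairpin loops
forming an active complementary block, no oversized interior/bulge loop, a
fold score under the stability threshold, and sufficient coverage of the
template length. Candidate coordinates are the junction's enclosing helix
span. This is the desk-scale stand-in for a covariance-model homology
search: the significance filter of such a search (a database-calibrated
E-value) is replaced by the deterministic fold-score threshold plus an
optional empirical null — the score percentile against dinucleotide-shuffled
windows — because the screen's defining property, sequence-blind
structure-driven detection, lives in the structural criteria, not in the
significance machinery.

A naive exact-substring search is provided as the primary-sequence
comparator: it finds only near-identical copies of the template and loses
the diverged family members the structural screen retains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import SeqRecord, reverse_complement
from .loop_pairing import PairBlock, PatternClass, classify_pattern, max_complementary_block, predict_activity
from .structure_fold import (
    FoldScore,
    SecondaryStructure,
    enclosing_helix_span,
    fold_max_pairing,
    parse_junctions,
    score_structure,
    threeway_arm_hairpins,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Filter thresholds for the structural screen.

    ``min_coverage`` is the matched span over the template length (the
    screen's reading of "sequence coverage > 0.8"); ``score_threshold`` is
    the maximal admissible fold score (stand-in significance filter);
    ``max_bulge_span`` rejects structures with an interior/bulge loop span
    over 30 nt.
    """

    window_len: int = 120
    step: int = 10
    min_coverage: float = 0.8
    min_block_len: int = 3
    score_threshold: int = -20
    max_bulge_span: int = 30
    min_hairpin: int = 3
    min_helix: int = 2
    min_loop: int = 3
    max_loop: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")
        if self.step < 1 or self.window_len <= 0:
            raise ValueError("step >= 1 and window_len > 0 required")


@dataclass(frozen=True)
class PRNACandidate:
    """A genomic window passing all structural criteria.

    ``start``/``end`` are 0-based half-open plus-strand coordinates of the
    paired (structured) span; ``strand`` is "+" or "-".
    """

    genome_id: str
    start: int
    end: int
    strand: str
    structure: SecondaryStructure
    has_3wj: bool
    loop_pair: PairBlock
    pattern: PatternClass
    fold_score: FoldScore
    coverage: float


def _evaluate_window(seq: str, cfg: ScreenConfig):
    """Fold one window and test the structural criteria.

    Returns (structure, block, score, paired_span) or None; the paired span
    is relative to the window.
    """
    structure = fold_max_pairing(seq, min_hairpin=cfg.min_hairpin, min_helix=cfg.min_helix)
    report = parse_junctions(structure)
    if not report.has_3wj:
        return None
    if report.max_internal_span > cfg.max_bulge_span:
        return None
    # the LH/RH loops must be the hairpins of the 3WJ's own two arms
    best = None
    best_m = None
    for m, hp_a, hp_b in threeway_arm_hairpins(structure, report):
        for rh, lh in ((hp_a, hp_b), (hp_b, hp_a)):
            if not (cfg.min_loop <= rh.length <= cfg.max_loop):
                continue
            if not (cfg.min_loop <= lh.length <= cfg.max_loop):
                continue
            block = max_complementary_block(rh.seq, lh.seq)
            if block.length < cfg.min_block_len:
                continue
            if not predict_activity(block).active:
                continue
            if best is None or (block.length, block.n_gc) > (best.length, best.n_gc):
                best = block
                best_m = m
    if best is None:
        return None
    score = score_structure(structure)
    if score.pair_energy_total > cfg.score_threshold:
        return None
    span = enclosing_helix_span(structure, best_m.closing)
    return structure, best, score, span


def scan_genome(
    genome: SeqRecord,
    template_len: int = 120,
    cfg: ScreenConfig = ScreenConfig(),
) -> list[PRNACandidate]:
    """Scan both strands of a genome for pRNA-like windows.

    Every returned candidate satisfies all :class:`ScreenConfig` criteria;
    coverage is the structured-span length over ``template_len``, capped at
    1. A genome shorter than the window yields an empty list with a warning.
    """
    seq = genome.residues
    n = len(seq)
    if n < cfg.window_len:
        logger.warning(
            "genome %s (%d nt) shorter than window (%d nt): no scan",
            genome.id, n, cfg.window_len,
        )
        return []
    out: list[PRNACandidate] = []
    rc = reverse_complement(seq)
    starts = list(range(0, n - cfg.window_len + 1, cfg.step))
    if starts[-1] != n - cfg.window_len:
        starts.append(n - cfg.window_len)
    for w in starts:
        for strand in "+-":
            if strand == "+":
                window = seq[w : w + cfg.window_len]
            else:
                window = rc[n - w - cfg.window_len : n - w]
            hit = _evaluate_window(window, cfg)
            if hit is None:
                continue
            structure, block, score, (s0, s1) = hit
            if strand == "+":
                start, end = w + s0, w + s1
            else:
                start, end = w + cfg.window_len - s1, w + cfg.window_len - s0
            coverage = min(1.0, (s1 - s0) / template_len)
            if coverage < cfg.min_coverage:
                continue
            out.append(
                PRNACandidate(
                    genome_id=genome.id,
                    start=start,
                    end=end,
                    strand=strand,
                    structure=structure,
                    has_3wj=True,
                    loop_pair=block,
                    pattern=classify_pattern(block),
                    fold_score=score,
                    coverage=coverage,
                )
            )
    return sorted(out, key=lambda c: (c.start, c.end, c.strand))


def merge_candidates(
    cands: list[PRNACandidate], min_overlap: float = 0.5
) -> list[PRNACandidate]:
    """Merge overlapping candidates (interval Jaccard >= min_overlap).

    Merging is transitive within a chain of pairwise-overlapping candidates;
    the representative with the best (lowest) fold score is kept. Output is
    sorted by start. All candidates must come from one genome.
    """
    if not cands:
        return []
    if len({c.genome_id for c in cands}) > 1:
        raise ValueError("merge_candidates expects candidates from one genome")
    order = sorted(cands, key=lambda c: (c.start, c.end))
    clusters: list[list[PRNACandidate]] = [[order[0]]]
    for c in order[1:]:
        placed = False
        for cl in clusters:
            if any(_jaccard(c, o) >= min_overlap for o in cl):
                cl.append(c)
                placed = True
                break
        if not placed:
            clusters.append([c])
    merged = [
        min(cl, key=lambda c: (c.fold_score.pair_energy_total, c.start))
        for cl in clusters
    ]
    return sorted(merged, key=lambda c: c.start)


def _jaccard(a: PRNACandidate, b: PRNACandidate) -> float:
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    union = (a.end - a.start) + (b.end - b.start) - inter
    return inter / union if union else 0.0


REPORT_COLUMNS = [
    "genome_id", "start", "end", "strand", "fold_score", "n_pairs",
    "coverage", "block_len", "block_n_gc", "has_gg_cc_core", "dotbracket",
]


def screen_report(cands: list[PRNACandidate]) -> pd.DataFrame:
    """Tabular report; the first columns are BED6-compatible."""
    rows = [
        {
            "genome_id": c.genome_id,
            "start": c.start,
            "end": c.end,
            "strand": c.strand,
            "fold_score": c.fold_score.pair_energy_total,
            "n_pairs": c.fold_score.n_pairs,
            "coverage": round(c.coverage, 4),
            "block_len": c.loop_pair.length,
            "block_n_gc": c.loop_pair.n_gc,
            "has_gg_cc_core": c.pattern.has_gg_cc_core,
            "dotbracket": c.structure.dotbracket,
        }
        for c in cands
    ]
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(cands: list[PRNACandidate], path, bed_path=None) -> None:
    df = screen_report(cands)
    df.to_csv(path, sep="\t", index=False)
    if bed_path is not None:
        bed = pd.DataFrame(
            {
                "chrom": df["genome_id"],
                "chromStart": df["start"],
                "chromEnd": df["end"],
                "name": [f"prna_candidate_{i}" for i in range(len(df))],
                "score": (-df["fold_score"]).clip(0, 1000),
                "strand": df["strand"],
            }
        )
        bed.to_csv(bed_path, sep="\t", index=False, header=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"genome_id": str})


# ---------------------------------------------------------------------------
# empirical null and the primary-sequence comparator
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle (Altschul–Erickson, seeded).

    Edge multisets of the dinucleotide transition graph are permuted and a
    random Eulerian arrangement drawn; first and last residues are fixed.
    """
    if len(seq) <= 2:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    # draw a uniform arborescence toward `last` by random last-exit edges
    for _ in range(1000):
        trial = {a: list(rng.permutation(bs)) for a, bs in edges.items()}
        # check connectivity of the Euler path: walk greedily
        pos = {a: 0 for a in trial}
        out = [seq[0]]
        cur = seq[0]
        n_edges = len(seq) - 1
        for _k in range(n_edges):
            if pos[cur] >= len(trial[cur]):
                break
            nxt = trial[cur][pos[cur]]
            pos[cur] += 1
            out.append(nxt)
            cur = nxt
        if len(out) == len(seq) and cur == last:
            return "".join(out)
    logger.warning("dinucleotide shuffle fell back to identity")
    return seq


def null_score_percentile(
    window: str,
    cfg: ScreenConfig = ScreenConfig(),
    n: int = 100,
    seed: int | np.random.Generator = 0,
) -> float:
    """Fraction of shuffled windows scoring at least as low (stable).

    Small values mean the window is more stable than its dinucleotide null.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    obs = score_structure(
        fold_max_pairing(window, min_hairpin=cfg.min_hairpin, min_helix=cfg.min_helix)
    )
    null = []
    for _ in range(n):
        sh = dinucleotide_shuffle(window, rng)
        folded = fold_max_pairing(sh, min_hairpin=cfg.min_hairpin, min_helix=cfg.min_helix)
        null.append(score_structure(folded).pair_energy_total)
    null_arr = np.array(null)
    return float((null_arr <= obs.pair_energy_total).mean())


def naive_sequence_search(genome: SeqRecord, template: SeqRecord) -> list[tuple[int, int, str]]:
    """Exact-substring search for the template on both strands.

    The primary-sequence comparator: recall collapses once family members
    diverge, unlike the structural screen.
    """
    hits = []
    seq, t = genome.residues, template.residues
    for strand, probe in (("+", t), ("-", reverse_complement(t))):
        start = seq.find(probe)
        while start != -1:
            hits.append((start, start + len(t), strand))
            start = seq.find(probe, start + 1)
    return sorted(hits)


def recall(
    cands: list[PRNACandidate] | list[tuple[int, int, str]],
    truth: tuple[tuple[int, int, str, str], ...],
    min_overlap: float = 0.5,
) -> float:
    """Fraction of truth intervals overlapped (Jaccard >= min_overlap)."""
    if not truth:
        raise ValueError("empty truth set")
    found = 0
    for ts, te, _strand, _fam in truth:
        for c in cands:
            cs, ce = (c.start, c.end) if isinstance(c, PRNACandidate) else (c[0], c[1])
            inter = max(0, min(te, ce) - max(ts, cs))
            union = (te - ts) + (ce - cs) - inter
            if union and inter / union >= min_overlap:
                found += 1
                break
    return found / len(truth)
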