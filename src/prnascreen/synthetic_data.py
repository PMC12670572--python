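"""Ground-truth generators for every input the pipeline consumes.

The generated pRNA abstracts the phi29 pRNA domain-1 architecture down to
the features the screen is defined on: a closing helix enclosing a three-way
junction from which two hairpin arms emanate, one carrying the right-hand
(RH) loop and the other the left-hand (LH) loop, with a designed
complementary LH/RH block (length 3–4, GG:CC core, 0–2 A/U additions).
Helix strands are exact reverse complements; the RH loop is purine-only and
the LH loop pyrimidine-only (so neither can fold internally), junction
spacers are all A, and a few helix boundary positions are constrained to
letter classes that remove equal-score refolding alternatives. Each sampled
instance is re-validated by no-lonely-pair base-pair maximization (three-way
junction present, designed loops recovered as hairpins, block active); the
occasional realization that fails — e.g. an accidental alternative helix
pairing — is resampled deterministically from the same seeded stream.

Divergence comes in two modes mirroring the covariation observed between
interacting loops: compensatory divergence substitutes paired positions
together (the partner receives the complementary substitution), preserving
structure and loop activity, while non-compensatory divergence mutates
sites independently and is expected to destroy the hand-in-hand pairing at
sufficient rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .io_formats import FeatureMap, SeqRecord, reverse_complement
from .loop_pairing import max_complementary_block, predict_activity
from .structure_fold import (
    SecondaryStructure,
    fold_max_pairing,
    parse_junctions,
    threeway_arm_hairpins,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_BASES = ("A", "C", "G", "U")

# RH-side block sequences realizing a GG core with 0-2 A additions; the LH
# side is the reverse complement.
_BLOCK_CHOICES = ("GGA", "AGG", "GGAA", "AGGA", "AAGG")

_MAX_RESAMPLE = 200


@dataclass(frozen=True)
class PRNAScaffold:
    """Architecture parameters for the designed pRNA-like element.

    ``h1`` is the closing helix, ``h2`` the RH-loop arm, ``h3`` the LH-loop
    arm; ``s1/s2/s3`` are the unpaired junction spacers between them. Spacer
    lengths must stay below ``min_hairpin + 2`` so spacers cannot fold on
    themselves.
    """

    h1: int = 12
    h2: int = 9
    h3: int = 9
    rh_loop_len: int = 7
    lh_loop_len: int = 7
    s1: int = 4
    s2: int = 4
    s3: int = 4
    block: str = "AGGA"  # RH-side block; LH side is its reverse complement

    def __post_init__(self) -> None:
        if self.block not in _BLOCK_CHOICES:
            raise ValueError(
                f"block {self.block!r} must be one of {_BLOCK_CHOICES} "
                "(GG:CC core with 0-2 A/U additions)"
            )
        if len(self.block) > min(self.rh_loop_len, self.lh_loop_len):
            raise ValueError("designed block longer than a loop")
        if min(self.h1, self.h2, self.h3) < 3:
            raise ValueError("helices must be >= 3 bp")
        if max(self.s1, self.s2, self.s3) > 4:
            raise ValueError("junction spacers must be <= 4 nt (no self-folding)")

    @property
    def length(self) -> int:
        return (
            2 * (self.h1 + self.h2 + self.h3)
            + self.rh_loop_len
            + self.lh_loop_len
            + self.s1
            + self.s2
            + self.s3
        )


@dataclass(frozen=True)
class LoopAnnotation:
    """0-based half-open spans of the designed features within the element."""

    rh_loop: tuple[int, int]
    lh_loop: tuple[int, int]
    rh_block: tuple[int, int]
    lh_block: tuple[int, int]
    junction_spacers: tuple[tuple[int, int], ...]
    critical_g: int

    def rh_seq(self, seq: str) -> str:
        return seq[self.rh_loop[0] : self.rh_loop[1]]

    def lh_seq(self, seq: str) -> str:
        return seq[self.lh_loop[0] : self.lh_loop[1]]


@dataclass(frozen=True)
class PRNAInstance:
    record: SeqRecord
    structure: SecondaryStructure
    annotation: LoopAnnotation


@dataclass(frozen=True)
class PlantedGenome:
    genome: SeqRecord
    truth: tuple[tuple[int, int, str, str], ...]  # (start, end, strand, family_id)


def _rand_string(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def _design(scaffold: PRNAScaffold, rng: np.random.Generator):
    """One candidate realization of the scaffold (before validation).

    Helix strands are random over the full alphabet except at a few boundary
    positions where specific letter classes prevent equal-score refolding
    alternatives (a helix-terminal base re-targeting into an adjacent loop):
    the 5' bases flanking the junction are purines (no pairing with the
    all-A spacers), the RH arm's loop-proximal 5' base is a purine (no
    pairing with the purine RH loop), and the LH arm's loop-proximal 5'
    base is a pyrimidine (no pairing with the pyrimidine LH loop). Loops
    are purine-only (RH) and pyrimidine-only (LH) so they cannot fold
    internally, and junction spacers are all A.
    """

    def _strand(length, first=None, last=None, mid=None):
        chars = list(_rand_string(rng, "ACGU", length))
        if first is not None:
            chars[0] = first[int(rng.integers(0, len(first)))]
        if last is not None:
            chars[-1] = last[int(rng.integers(0, len(last)))]
        if mid is not None:
            chars[length // 2] = mid
        return "".join(chars)

    h1_5 = _strand(scaffold.h1, last="AG")           # junction-proximal purine
    h2_5 = _strand(scaffold.h2, first="AG", last="AG")
    # mid position C puts the conserved critical G on the 3' strand
    h3_5 = _strand(scaffold.h3, first="AG", last="CU", mid="C")
    blk = scaffold.block
    rh_fill = scaffold.rh_loop_len - len(blk)
    lh_fill = scaffold.lh_loop_len - len(blk)
    rh_off = int(rng.integers(0, rh_fill + 1))
    lh_off = int(rng.integers(0, lh_fill + 1))
    rh_loop = "A" * rh_off + blk + "A" * (rh_fill - rh_off)
    lh_blk = reverse_complement(blk)
    lh_loop = "C" * lh_off + lh_blk + "C" * (lh_fill - lh_off)

    parts = [
        h1_5,
        "A" * scaffold.s1,
        h2_5,
        rh_loop,
        reverse_complement(h2_5),
        "A" * scaffold.s2,
        h3_5,
        lh_loop,
        reverse_complement(h3_5),
        "A" * scaffold.s3,
        reverse_complement(h1_5),
    ]
    seq = "".join(parts)

    # coordinates
    pos = 0
    spans = []
    for p in parts:
        spans.append((pos, pos + len(p)))
        pos += len(p)
    (sp_h1, sp_s1, sp_h2, sp_rh, sp_h2r, sp_s2, sp_h3, sp_lh, sp_h3r, sp_s3, sp_h1r) = spans

    pairs = [-1] * scaffold.length

    def _pair_helix(five: tuple[int, int], three: tuple[int, int]) -> None:
        a0, a1 = five
        b0, b1 = three
        for k in range(a1 - a0):
            i, j = a0 + k, b1 - 1 - k
            pairs[i], pairs[j] = j, i

    _pair_helix(sp_h1, sp_h1r)
    _pair_helix(sp_h2, sp_h2r)
    _pair_helix(sp_h3, sp_h3r)
    structure = SecondaryStructure(seq=seq, pairs=tuple(pairs))

    # the conserved ATP-binding G: partner of the C fixed mid-strand in h3_5p
    critical_g = sp_h3r[0] + (scaffold.h3 - 1 - scaffold.h3 // 2)

    ann = LoopAnnotation(
        rh_loop=sp_rh,
        lh_loop=sp_lh,
        rh_block=(sp_rh[0] + rh_off, sp_rh[0] + rh_off + len(blk)),
        lh_block=(sp_lh[0] + lh_off, sp_lh[0] + lh_off + len(lh_blk)),
        junction_spacers=(sp_s1, sp_s2, sp_s3),
        critical_g=critical_g,
    )
    return seq, structure, ann


def validate_instance(
    seq: str, annotation: LoopAnnotation, min_hairpin: int = 3
) -> bool:
    """Does max-pairing folding recover the designed architecture?

    Checks: some three-way junction carries both designed loops as its two
    unbranched arm hairpins at their designed coordinates, and their maximal
    complementary block is active — the same architecture criterion the
    genome screen applies.
    """
    folded = fold_max_pairing(seq, min_hairpin=min_hairpin, min_helix=2)
    report = parse_junctions(folded)
    want = {annotation.rh_loop, annotation.lh_loop}
    for _m, hp_a, hp_b in threeway_arm_hairpins(folded, report):
        if {(hp_a.start, hp_a.end), (hp_b.start, hp_b.end)} == want:
            break
    else:
        return False
    block = max_complementary_block(annotation.rh_seq(seq), annotation.lh_seq(seq))
    return predict_activity(block).active


def sample_prna(
    scaffold: PRNAScaffold = PRNAScaffold(),
    seed: int | np.random.Generator = 0,
    name: str = "prna",
) -> PRNAInstance:
    """Sample one pRNA-like element realizing the scaffold; deterministic.

    The realization is re-validated by folding; invalid draws (or draws whose
    LH-arm 3' strand carries no G to annotate as the conserved ATP-binding G)
    are resampled from the same stream, so every returned instance satisfies
    the designed invariants.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for _ in range(_MAX_RESAMPLE):
        seq, structure, ann = _design(scaffold, rng)
        if ann.critical_g < 0:
            continue
        if validate_instance(seq, ann):
            return PRNAInstance(
                record=SeqRecord(id=name, residues=seq),
                structure=structure,
                annotation=ann,
            )
    raise RuntimeError("could not realize scaffold after bounded resampling")


def diverge(
    prna: PRNAInstance,
    rate: float,
    compensatory: bool = True,
    seed: int | np.random.Generator = 0,
    name: str | None = None,
) -> PRNAInstance:
    """Substitute positions at the given per-site rate.

    With ``compensatory=True`` divergence is structure-preserving
    covariation: every substitution is a transition (A↔G, C↔U, preserving
    purine/pyrimidine classes and hence the scaffold's letter discipline),
    and a substitution at a paired position — helix or designed LH/RH
    block — applies the complementary transition to its partner, the
    covariation in which one loop's mutation is mirrored by the other
    loop. The result is re-validated by folding; a draw that breaks
    recovery or loop activity (e.g. a transition dissolving the block's
    G:C core, or a mutated helix pairing elsewhere) is redrawn from the
    same seeded stream. With ``compensatory=False`` substitutions are
    independent over the full alphabet and no preservation is attempted.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    seq0 = prna.record.residues
    n = len(seq0)
    pairs = list(prna.structure.pairs)
    ann = prna.annotation
    # the designed LH/RH block positions pair intermolecularly; treat them as
    # partners for covariation purposes
    block_partner = {}
    (r0, r1), (l0, l1) = ann.rh_block, ann.lh_block
    for k in range(r1 - r0):
        i, j = r0 + k, l1 - 1 - k
        block_partner[i] = j
        block_partner[j] = i
    _TRANSITION = {"A": "G", "G": "A", "C": "U", "U": "C"}

    def _draw() -> str:
        seq = list(seq0)
        hit = rng.random(n) < rate
        done = set()
        for i in range(n):
            if not hit[i] or i in done:
                continue
            if not compensatory:
                seq[i] = _BASES[(_BASES.index(seq[i]) + 1 + int(rng.integers(0, 3))) % 4]
                done.add(i)
                continue
            new = _TRANSITION[seq[i]]
            seq[i] = new
            done.add(i)
            j = pairs[i] if pairs[i] != -1 else block_partner.get(i, -1)
            if j != -1:
                seq[j] = _COMPLEMENT[new]
                done.add(j)
        return "".join(seq)

    new_name = name or prna.record.id
    if rate == 0.0:
        return replace(prna, record=SeqRecord(id=new_name, residues=seq0))
    if not compensatory:
        seq = _draw()
        return replace(prna, record=SeqRecord(id=new_name, residues=seq))
    for _ in range(_MAX_RESAMPLE):
        seq = _draw()
        if validate_instance(seq, ann):
            return replace(prna, record=SeqRecord(id=new_name, residues=seq))
    raise RuntimeError(
        f"could not draw structure-preserving divergence at rate {rate} "
        f"after {_MAX_RESAMPLE} attempts"
    )


def random_background(
    length: int, gc: float = 0.5, seed: int | np.random.Generator = 0
) -> str:
    """i.i.d. background sequence with the given GC fraction."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(_BASES)[rng.choice(4, size=length, p=p)])


def plant_in_genome(
    prnas: list[PRNAInstance],
    genome_len: int,
    gc: float = 0.5,
    strand_policy: str = "plus",
    seed: int | np.random.Generator = 0,
    genome_id: str = "synthetic_genome",
    max_tries: int = 1000,
) -> PlantedGenome:
    """Embed pRNA elements at uniform-random non-overlapping loci.

    ``strand_policy`` is "plus", "minus", or "both" (random strand per
    element); minus-strand elements are inserted as reverse complements.
    Truth intervals are 0-based half-open on the plus strand.
    """
    if strand_policy not in ("plus", "minus", "both"):
        raise ValueError("strand_policy must be plus/minus/both")
    total = sum(len(p.record.residues) for p in prnas)
    if total >= genome_len:
        raise ValueError("planted elements do not fit in the genome")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    background = list(random_background(genome_len, gc=gc, seed=rng))
    placed: list[tuple[int, int, str, str]] = []
    for p in prnas:
        m = len(p.record.residues)
        for _ in range(max_tries):
            start = int(rng.integers(0, genome_len - m + 1))
            end = start + m
            if all(end <= s or start >= e for s, e, _, _ in placed):
                break
        else:
            raise RuntimeError("could not place element without overlap")
        strand = (
            strand_policy
            if strand_policy != "both"
            else ("plus" if rng.random() < 0.5 else "minus")
        )
        ins = p.record.residues if strand == "plus" else reverse_complement(p.record.residues)
        background[start:end] = list(ins)
        placed.append((start, end, "+" if strand == "plus" else "-", p.record.id))
    placed.sort()
    return PlantedGenome(
        genome=SeqRecord(id=genome_id, residues="".join(background)),
        truth=tuple(placed),
    )


def make_family(
    n: int,
    scaffold: PRNAScaffold = PRNAScaffold(),
    rate: float = 0.2,
    compensatory: bool = True,
    seed: int = 0,
    prefix: str = "prna",
) -> list[PRNAInstance]:
    """A family of n diverged copies of one sampled ancestor."""
    rng = np.random.default_rng(seed)
    ancestor = sample_prna(scaffold, seed=rng, name=f"{prefix}_anc")
    return [
        diverge(ancestor, rate=rate, compensatory=compensatory, seed=rng,
                name=f"{prefix}_{i:03d}")
        for i in range(n)
    ]


def make_alignment(
    family: list[PRNAInstance],
    distinct_bulges: bool = True,
    occupancy: dict[str, int] | None = None,
    critical_g_conserved: int | None = None,
    seed: int = 0,
) -> tuple[list[SeqRecord], FeatureMap]:
    """Gap-free alignment of a scaffold family with the Fig-2-style features.

    All family members share the scaffold, so columns align by construction.
    Features: Bulge1 (RH loop), Bulge3 (LH loop), Bulge2 (an annotated
    unpaired junction tract, the CCA-relevant bulge stand-in), 3WJ (junction
    spacer columns), critical_G (the conserved ATP-binding G column).

    ``distinct_bulges`` redraws family members until Bulge1/Bulge3 strings
    are pairwise distinct across rows. ``occupancy`` maps a feature name to
    the number of rows k in which it is occupied; the remaining n - k rows
    have the feature columns replaced by gaps. ``critical_g_conserved`` = k
    forces the critical-G column to G in exactly k rows (non-G elsewhere).
    """
    if len(family) < 2:
        raise ValueError("need at least 2 family members")
    rng = np.random.default_rng(seed)
    ann = family[0].annotation
    if any(f.annotation != ann for f in family):
        raise ValueError("family members must share one scaffold realization")
    rows = [list(f.record.residues) for f in family]

    if distinct_bulges:
        seen_rh: set[str] = set()
        seen_lh: set[str] = set()
        for ridx, f in enumerate(family):
            for _ in range(_MAX_RESAMPLE):
                s = "".join(rows[ridx])
                rh = s[ann.rh_loop[0] : ann.rh_loop[1]]
                lh = s[ann.lh_loop[0] : ann.lh_loop[1]]
                if rh not in seen_rh and lh not in seen_lh:
                    seen_rh.add(rh)
                    seen_lh.add(lh)
                    break
                try:
                    redrawn = diverge(f, rate=0.3, compensatory=True, seed=rng)
                except RuntimeError:
                    continue  # unlucky covariation draw; try another
                rows[ridx] = list(redrawn.record.residues)
            else:
                raise RuntimeError("could not make bulge strings pairwise distinct")

    if critical_g_conserved is not None:
        k = critical_g_conserved
        if not 0 <= k <= len(rows):
            raise ValueError("critical_g_conserved out of range")
        col = ann.critical_g
        partner = family[0].structure.pairs[col]
        for ridx, row in enumerate(rows):
            if ridx < k:
                row[col] = "G"
                if partner != -1:
                    row[partner] = "C"
            else:
                row[col] = "A"
                if partner != -1:
                    row[partner] = "U"

    features = {
        "Bulge1": frozenset(range(*ann.rh_loop)),
        "Bulge3": frozenset(range(*ann.lh_loop)),
        "Bulge2": frozenset(range(*ann.junction_spacers[1])),
        "3WJ": frozenset(
            c for span in ann.junction_spacers for c in range(*span)
        ),
        "critical_G": frozenset({ann.critical_g}),
    }
    if occupancy:
        for fname, k in occupancy.items():
            if fname not in features:
                raise ValueError(f"unknown feature {fname!r}")
            if not 0 <= k <= len(rows):
                raise ValueError(f"occupancy for {fname!r} out of range")
            for ridx in range(k, len(rows)):
                for c in features[fname]:
                    rows[ridx][c] = "-"

    recs = [
        SeqRecord(id=f.record.id, residues="".join(row))
        for f, row in zip(family, rows)
    ]
    return recs, FeatureMap(features)


# ---------------------------------------------------------------------------
# Fig-3-style loop-variant panels
# ---------------------------------------------------------------------------

PANEL_TAGS = (
    "self_complementary",
    "cross_pair",
    "cross_triplet",
    "unpaired",
    "gc_only",
    "au_only",
)

# Loop identity -> RH-side interaction block (uppercase identity). The
# matching lowercase LH identity presents the reverse complement. The three
# blocks are chosen so that mismatched RH x LH combinations form no active
# block (no adjacent G:C,G:C run and no isolated G:C,G:C 2-mer) while each
# identity pairs its own complement through a 4-nt block with a G:C core.
_LOOP_IDENT = {"A": "AACC", "I": "AACG", "J": "AAGC"}
_RH_FILLER = "AA"
_LH_FILLER = "CC"


def _cross_cycle_species(rh_ids: list[str], lh_ids: list[str]):
    """Species ``X/y``: RH identity X, LH identity y (accepts species with
    RH identity Y). Edge u→v exists iff v's LH identity matches u's RH."""
    from .ring_assembly import LoopSpecies

    out = []
    for rid, lid in zip(rh_ids, lh_ids):
        rh_block = _LOOP_IDENT[rid]
        lh_block = reverse_complement(_LOOP_IDENT[lid.upper()])
        out.append(
            LoopSpecies(
                name=f"{rid}/{lid}",
                rh=_RH_FILLER + rh_block + _RH_FILLER,
                lh=_LH_FILLER + lh_block + _LH_FILLER,
            )
        )
    return out


def make_loop_panel(tag: str):
    """Loop-variant species realizing a Fig-3-style configuration.

    Returns ``(species, labels)`` where ``labels["jointly_active"]`` is
    whether the full mixture closes a ring and
    ``labels["individually_active"]`` gives each species' activity alone.
    """
    from .ring_assembly import LoopSpecies

    if tag == "self_complementary":
        sp = _cross_cycle_species(["A"], ["a"])
        return sp, {"jointly_active": True, "individually_active": [True]}
    if tag == "cross_pair":
        sp = _cross_cycle_species(["A", "I"], ["i", "a"])
        return sp, {"jointly_active": True, "individually_active": [False, False]}
    if tag == "cross_triplet":
        sp = _cross_cycle_species(["A", "I", "J"], ["i", "j", "a"])
        return sp, {
            "jointly_active": True,
            "individually_active": [False, False, False],
        }
    if tag == "unpaired":
        # RH carries a GG run but the LH presents no complementary run:
        # the best block is a mixed 2-mer, below the activity rules
        sp = [LoopSpecies(name="A/x", rh="AAGGAAA", lh="CUCUCUC")]
        return sp, {"jointly_active": False, "individually_active": [False]}
    if tag == "gc_only":
        # exactly one GG:CC 2-mer and nothing longer: sufficient for activity
        sp = [LoopSpecies(name="GG/cc", rh="AAGGAAA", lh="CCCCCCC")]
        return sp, {"jointly_active": True, "individually_active": [True]}
    if tag == "au_only":
        # a pure AA:UU 2-mer: below the threshold, both pairs must be G:C
        sp = [LoopSpecies(name="AU/au", rh="CCAACCC", lh="CCUUCCC")]
        return sp, {"jointly_active": False, "individually_active": [False]}
    raise ValueError(f"unknown panel tag {tag!r}; choose from {PANEL_TAGS}")
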