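"""Secondary-structure prediction and structural-feature detection.

The folder is a deterministic base-pair maximization (Nussinov-style dynamic
program) with a stability tie-break: among structures with the maximal number
of pairs, the one with the lowest additive pair energy (G:C = -3, A:U = -2,
G:U = -1; a dimensionless stand-in for ΔG) is chosen, and remaining ties are
broken in the traceback toward the smallest 5' pairing partner. Full
nearest-neighbor thermodynamics are deliberately out of scope: the screening
criteria downstream are defined on structures (a three-way junction plus two
complementary hairpin loops), not on physical free energies, and externally
predicted structures can be supplied as dot-bracket wherever a fold is an
input.

`parse_junctions` decomposes a structure into its loops (exterior, hairpin,
internal/bulge, multiloop) and reports whether a three-way junction — a
multiloop with exactly three emanating helices — is present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .io_formats import canonical_rna

logger = logging.getLogger(__name__)

# pair strengths; energy contribution is the negative of these
_STRENGTH = {("G", "C"): 3, ("C", "G"): 3, ("A", "U"): 2, ("U", "A"): 2,
             ("G", "U"): 1, ("U", "G"): 1}

PAIR_ENERGY = {k: -v for k, v in _STRENGTH.items()}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


def pair_strength(a: str, b: str, allow_gu: bool = True) -> int:
    """Pairing strength of bases ``a``/``b`` (0 when they cannot pair)."""
    s = _STRENGTH.get((a, b), 0)
    if s == 1 and not allow_gu:
        return 0
    return s


@dataclass(frozen=True)
class SecondaryStructure:
    """A sequence plus a pseudoknot-free pair table.

    ``pairs[i] = j`` when position ``i`` pairs with ``j`` (involutive),
    ``-1`` when unpaired. The dot-bracket string is derived.
    """

    seq: str
    pairs: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.seq)
        if len(self.pairs) != n:
            raise ValueError("pair table length != sequence length")
        for i, j in enumerate(self.pairs):
            if j == -1:
                continue
            if not (0 <= j < n) or j == i or self.pairs[j] != i:
                raise ValueError(f"pair table not involutive at position {i}")
        # pseudoknot check: opened pairs must nest
        stack: list[int] = []
        for i, j in enumerate(self.pairs):
            if j > i:
                stack.append(j)
            elif j != -1 and j < i:
                if not stack or stack[-1] != i:
                    raise ValueError(f"pseudoknot involving pair ({j}, {i})")
                stack.pop()

    @property
    def dotbracket(self) -> str:
        return "".join(
            "." if j == -1 else ("(" if j > i else ")") for i, j in enumerate(self.pairs)
        )

    @property
    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.pairs) if j > i)

    @classmethod
    def from_dotbracket(cls, seq: str, db: str) -> "SecondaryStructure":
        seq = canonical_rna(seq)
        if len(db) != len(seq):
            raise ValueError("structure length != sequence length")
        pairs = [-1] * len(seq)
        stack: list[int] = []
        for i, ch in enumerate(db):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                if not stack:
                    raise ValueError(f"unbalanced ')' at position {i}")
                j = stack.pop()
                pairs[j], pairs[i] = i, j
            elif ch != ".":
                raise ValueError(f"illegal structure character {ch!r} at position {i}")
        if stack:
            raise ValueError(f"unbalanced '(' at position {stack[0]}")
        return cls(seq=seq, pairs=tuple(pairs))


@dataclass(frozen=True)
class FoldScore:
    """Additive stand-in stability score (more negative = more stable)."""

    pair_energy_total: int
    n_pairs: int


@dataclass(frozen=True)
class Hairpin:
    """A hairpin loop: unpaired span [start, end) closed by pair (i, j)."""

    start: int
    end: int
    seq: str
    closing: tuple[int, int]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Multiloop:
    degree: int
    closing: tuple[int, int] | None  # None for the exterior loop
    helices: tuple[tuple[int, int], ...]  # closing pairs of member helices
    unpaired: tuple[int, ...]


@dataclass(frozen=True)
class InternalLoop:
    """Internal loop or bulge between two helices; spans are 0-based half-open."""

    span5: tuple[int, int]
    span3: tuple[int, int]
    seq5: str
    seq3: str

    @property
    def max_span(self) -> int:
        return max(self.span5[1] - self.span5[0], self.span3[1] - self.span3[0])


@dataclass(frozen=True)
class JunctionReport:
    multiloops: tuple[Multiloop, ...]
    hairpins: tuple[Hairpin, ...]
    bulges_internal: tuple[InternalLoop, ...]
    exterior_unpaired: tuple[int, ...]

    @property
    def has_3wj(self) -> bool:
        return any(m.degree == 3 for m in self.multiloops)

    @property
    def max_internal_span(self) -> int:
        return max((b.max_span for b in self.bulges_internal), default=0)


# ---------------------------------------------------------------------------
# folding kernel
# ---------------------------------------------------------------------------

try:  # numba accelerates the O(n^3) fill; plain Python remains the fallback
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _fill_dp(codes, strengths, min_hairpin, weight):  # pragma: no cover - numba
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int64)
    for span in range(min_hairpin + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]  # i unpaired
            # i paired with some k
            for k in range(i + min_hairpin + 1, j + 1):
                s = strengths[codes[i], codes[k]]
                if s > 0:
                    inner = dp[i + 1, k - 1] if k - 1 > i + 1 else 0
                    rest = dp[k + 1, j] if k + 1 <= j else 0
                    cand = inner + rest + weight + s
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return dp


@njit(cache=False)
def _fill_dp_nolp(codes, strengths, min_hairpin, weight):  # pragma: no cover
    """No-lonely-pairs variant: every helix has at least 2 stacked pairs.

    H[i, j] is the best score with (i, j) paired as the outermost pair of a
    helix (>= 2 stacked pairs); F[i, j] is the best score over [i, j] with
    no isolated pairs anywhere. -1 marks an undefined H.
    """
    n = codes.shape[0]
    F = np.zeros((n, n), dtype=np.int64)
    H = np.full((n, n), -1, dtype=np.int64)
    for span in range(min_hairpin + 1, n):
        if span >= min_hairpin + 3:
            for i in range(n - span):
                j = i + span
                s0 = strengths[codes[i], codes[j]]
                s1 = strengths[codes[i + 1], codes[j - 1]]
                if s0 > 0 and s1 > 0:
                    # stack of exactly 2 then free interior
                    inner = F[i + 2, j - 2] if i + 2 <= j - 2 else 0
                    best_h = 2 * weight + s0 + s1 + inner
                    # extend the stack
                    if H[i + 1, j - 1] >= 0:
                        cand = weight + s0 + H[i + 1, j - 1]
                        if cand > best_h:
                            best_h = cand
                    H[i, j] = best_h
        for i in range(n - span):
            j = i + span
            best = F[i + 1, j]
            for k in range(i + min_hairpin + 2, j + 1):
                if H[i, k] >= 0:
                    rest = F[k + 1, j] if k + 1 <= j else 0
                    cand = H[i, k] + rest
                    if cand > best:
                        best = cand
            F[i, j] = best
    return F, H


def _strength_table(allow_gu: bool) -> np.ndarray:
    t = np.zeros((4, 4), dtype=np.int64)
    for (a, b), s in _STRENGTH.items():
        if s == 1 and not allow_gu:
            continue
        t[_BASE_INDEX[a], _BASE_INDEX[b]] = s
    return t


def fold_max_pairing(
    seq: str, min_hairpin: int = 3, allow_gu: bool = True, min_helix: int = 1
) -> SecondaryStructure:
    """Fold by base-pair maximization with a stability tie-break.

    Returns the pseudoknot-free structure maximizing the number of pairs;
    among maximizers the total pair energy is minimized; residual ties are
    resolved deterministically in the traceback by pairing the 5'-most
    position with its smallest admissible partner.

    ``min_helix=2`` restricts the structure space to helices of at least
    two stacked pairs (no lonely pairs), the stricter helix-length minimum
    used by the genome screen to suppress spurious 1-bp helices.

    Sequences shorter than ``min_hairpin + 2`` yield the empty structure
    (with a warning) since no pair can form.
    """
    if min_helix not in (1, 2):
        raise ValueError("min_helix must be 1 or 2")
    seq = canonical_rna(seq)
    n = len(seq)
    if n < min_hairpin + 2:
        logger.warning("sequence of length %d cannot form a hairpin; empty structure", n)
        return SecondaryStructure(seq=seq, pairs=tuple([-1] * n))
    codes = np.array([_BASE_INDEX[c] for c in seq], dtype=np.int64)
    strengths = _strength_table(allow_gu)
    # lexicographic (count, strength) packed into one integer: strength sum
    # is bounded by 3 * n/2 pairs, so a weight > 3n/2 keeps count dominant
    weight = 3 * n + 1
    pairs = [-1] * n
    if min_helix == 2:
        F, H = _fill_dp_nolp(codes, strengths, min_hairpin, weight)
        _traceback_nolp(seq, codes, strengths, F, H, pairs, min_hairpin, weight)
        return SecondaryStructure(seq=seq, pairs=tuple(pairs))
    dp = _fill_dp(codes, strengths, min_hairpin, weight)
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_hairpin:
            continue
        target = dp[i, j]
        # prefer pairing i with the smallest admissible partner
        paired = False
        for k in range(i + min_hairpin + 1, j + 1):
            s = strengths[codes[i], codes[k]]
            if s <= 0:
                continue
            inner = dp[i + 1, k - 1] if k - 1 > i + 1 else 0
            rest = dp[k + 1, j] if k + 1 <= j else 0
            if inner + rest + weight + s == target:
                pairs[i], pairs[k] = k, i
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    return SecondaryStructure(seq=seq, pairs=tuple(pairs))


def _traceback_nolp(seq, codes, strengths, F, H, pairs, min_hairpin, weight):
    """Deterministic traceback for the no-lonely-pairs tables."""
    n = len(seq)
    stack = [("F", 0, n - 1)]
    while stack:
        state, i, j = stack.pop()
        if i >= j:
            continue
        if state == "F":
            if j - i <= min_hairpin:
                continue
            target = F[i, j]
            if target == 0:
                continue
            chosen = False
            for k in range(i + min_hairpin + 2, j + 1):
                if H[i, k] < 0:
                    continue
                rest = F[k + 1, j] if k + 1 <= j else 0
                if H[i, k] + rest == target:
                    stack.append(("H", i, k))
                    stack.append(("F", k + 1, j))
                    chosen = True
                    break
            if not chosen:
                stack.append(("F", i + 1, j))
        else:  # H: (i, j) paired, helix continues
            pairs[i], pairs[j] = j, i
            s0 = strengths[codes[i], codes[j]]
            # prefer extending the stack (deterministic)
            if H[i + 1, j - 1] >= 0 and H[i, j] == weight + s0 + H[i + 1, j - 1]:
                stack.append(("H", i + 1, j - 1))
            else:
                s1 = strengths[codes[i + 1], codes[j - 1]]
                pairs[i + 1], pairs[j - 1] = j - 1, i + 1
                assert s1 > 0
                if i + 2 <= j - 2:
                    stack.append(("F", i + 2, j - 2))


def score_structure(s: SecondaryStructure) -> FoldScore:
    """Additive pair-energy score of a structure (G:C -3, A:U -2, G:U -1)."""
    total = 0
    n_pairs = 0
    for i, j in enumerate(s.pairs):
        if j > i:
            e = PAIR_ENERGY.get((s.seq[i], s.seq[j]))
            if e is None:
                raise ValueError(f"non-canonical pair {s.seq[i]}:{s.seq[j]} at ({i},{j})")
            total += e
            n_pairs += 1
    return FoldScore(pair_energy_total=total, n_pairs=n_pairs)


# ---------------------------------------------------------------------------
# loop decomposition
# ---------------------------------------------------------------------------

def _loop_members(s: SecondaryStructure, i: int | None, j: int | None):
    """Walk the loop closed by pair (i, j) (exterior when None).

    Returns (unpaired positions, closing pairs of directly nested helices).
    """
    pairs = s.pairs
    n = len(s.seq)
    pos = 0 if i is None else i + 1
    stop = n if j is None else j
    unpaired: list[int] = []
    nested: list[tuple[int, int]] = []
    while pos < stop:
        p = pairs[pos]
        if p == -1:
            unpaired.append(pos)
            pos += 1
        else:
            nested.append((pos, p))
            pos = p + 1
    return unpaired, nested


def parse_junctions(s: SecondaryStructure) -> JunctionReport:
    """Decompose a structure into its loops and detect three-way junctions.

    Every unpaired position belongs to exactly one loop region; a multiloop's
    degree counts the helices incident on it, including the closing helix.
    """
    hairpins: list[Hairpin] = []
    multiloops: list[Multiloop] = []
    internals: list[InternalLoop] = []

    ext_unpaired, _ext_nested = _loop_members(s, None, None)

    # visit the loop under every closing pair, i.e. every pair (a, b) that is
    # not immediately stacked inside (a-1, b+1) is the closing pair of a helix
    # end; loop regions are read under every pair whose interior is not a
    # simple stack continuation.
    for a, b in ((i, j) for i, j in enumerate(s.pairs) if j > i):
        unpaired, nested = _loop_members(s, a, b)
        if len(nested) == 0:
            hairpins.append(
                Hairpin(
                    start=a + 1,
                    end=b,
                    seq=s.seq[a + 1 : b],
                    closing=(a, b),
                )
            )
        elif len(nested) == 1:
            (c, d) = nested[0]
            if c == a + 1 and d == b - 1:
                continue  # stacked pair, same helix
            internals.append(
                InternalLoop(
                    span5=(a + 1, c),
                    span3=(d + 1, b),
                    seq5=s.seq[a + 1 : c],
                    seq3=s.seq[d + 1 : b],
                )
            )
        else:
            multiloops.append(
                Multiloop(
                    degree=1 + len(nested),
                    closing=(a, b),
                    helices=tuple(nested),
                    unpaired=tuple(unpaired),
                )
            )
    return JunctionReport(
        multiloops=tuple(multiloops),
        hairpins=tuple(hairpins),
        bulges_internal=tuple(internals),
        exterior_unpaired=tuple(ext_unpaired),
    )


def _arm_hairpin(s: SecondaryStructure, closing: tuple[int, int]) -> Hairpin | None:
    """The single hairpin under an unbranched arm helix, else None.

    Walks inward from the arm's closing pair through stacked pairs and
    interior loops; a branching arm (a nested multiloop) disqualifies it.
    """
    a, b = closing
    while True:
        unpaired, nested = _loop_members(s, a, b)
        if len(nested) == 0:
            return Hairpin(start=a + 1, end=b, seq=s.seq[a + 1 : b], closing=(a, b))
        if len(nested) > 1:
            return None
        (a, b) = nested[0]


def threeway_arm_hairpins(
    s: SecondaryStructure, report: JunctionReport
) -> list[tuple[Multiloop, Hairpin, Hairpin]]:
    """Degree-3 multiloops whose two arms are unbranched hairpin-bearing
    helices — the pRNA architecture: a closing helix plus two loop arms.

    Returns one entry per qualifying junction with the 5'-side arm hairpin
    first.
    """
    out = []
    for m in report.multiloops:
        if m.degree != 3 or m.closing is None:
            continue
        hp = [_arm_hairpin(s, h) for h in m.helices]
        if len(hp) == 2 and all(h is not None for h in hp):
            out.append((m, hp[0], hp[1]))
    return out


def enclosing_helix_span(s: SecondaryStructure, closing: tuple[int, int]) -> tuple[int, int]:
    """0-based half-open extent of the helix chain enclosing ``closing``.

    Walks outward through stacked pairs and interior loops/bulges until a
    multiloop or the exterior is reached; the returned span is the
    structural element rooted at the pair (e.g. a 3WJ plus its closing
    helix), excluding unrelated neighbours.
    """
    a, b = closing
    n = len(s.seq)
    while True:
        x = a - 1
        while x >= 0 and s.pairs[x] == -1:
            x -= 1
        if x < 0 or s.pairs[x] < b:
            break
        y = s.pairs[x]
        if any(s.pairs[k] != -1 for k in range(b + 1, y)):
            break  # parent loop is branched: a multiloop, stop
        a, b = x, y
    return a, b + 1


def eligible_loop_pairs(
    s: SecondaryStructure,
    report: JunctionReport,
    min_loop: int = 3,
    max_loop: int = 10,
) -> list[tuple[Hairpin, Hairpin]]:
    """Ordered pairs of distinct hairpin loops within the length bounds.

    These are the candidate (right-hand, left-hand) loop assignments; whether
    a pair is actually complementary is decided by
    :func:`prnascreen.loop_pairing.max_complementary_block`.
    """
    loops = [h for h in report.hairpins if min_loop <= h.length <= max_loop]
    return [(rh, lh) for rh in loops for lh in loops if rh is not lh]
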