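"""Left-hand/right-hand loop complementarity search and activity rules.

pRNA subunits link into a ring by intermolecular "hand-in-hand" base pairing:
one subunit's right-hand (RH) loop pairs with the next subunit's left-hand
(LH) loop. The interaction is a short contiguous antiparallel Watson–Crick
duplex, typically 3–4 nt and built around a GG:CC core with up to two A/U
additions. Two base pairs suffice for biological activity only when both are
G:C — a single CC:GG pairing is sufficient — reflecting the higher melting
temperature of G:C over A:U pairs.

`max_complementary_block` is the string search for the longest such duplex;
`classify_pattern` recognizes the GG/CC-core pattern; `predict_activity`
encodes the activity rules derived from loop-mutant packaging assays.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import canonical_rna

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class PairBlock:
    """The maximal contiguous antiparallel complementary block between loops.

    ``lh_sub`` is the reverse complement of ``rh_sub`` under Watson–Crick
    rules; offsets are 0-based starts of the substrings within their loops.
    """

    rh_sub: str
    lh_sub: str
    length: int
    n_gc: int
    n_au: int
    rh_offset: int
    lh_offset: int

    def __post_init__(self) -> None:
        if self.length != self.n_gc + self.n_au + self._n_gu():
            raise ValueError("block length != pair-type counts")
        if self.length < 0:
            raise ValueError("negative block length")

    def _n_gu(self) -> int:
        return sum(
            1
            for a, b in zip(self.rh_sub, reversed(self.lh_sub))
            if (a, b) in _GU
        )


@dataclass(frozen=True)
class PatternClass:
    """Fig-3-style pattern call: a GG:CC core with n A/U additions."""

    has_gg_cc_core: bool
    n_au_additions: int


@dataclass(frozen=True)
class ActivityCall:
    active: bool
    rule_fired: str  # one of {"block_ge3", "gc_pair_only", "none"}


def _pairs(a: str, b: str, allow_gu: bool) -> bool:
    return (a, b) in _WC or (allow_gu and (a, b) in _GU)


def max_complementary_block(rh: str, lh: str, allow_gu: bool = False) -> PairBlock:
    """Longest contiguous antiparallel complementary block between two loops.

    Position ``rh[i + k]`` pairs with ``lh[j + L - 1 - k]`` for a block of
    length ``L`` starting at offsets ``(i, j)``. Ties are broken by more G:C
    pairs, then smaller ``rh_offset``, then smaller ``lh_offset``. A length-0
    block is returned when no complementary dinucleotide exists.

    Watson–Crick only by default; G:U wobble is an opt-in flag since the
    loop–loop covariation logic is framed in strict complementarity.
    """
    rh = canonical_rna(rh)
    lh = canonical_rna(lh)
    if not rh or not lh:
        raise ValueError("loop sequences must be non-empty")
    best_key = (0, 0, 0, 0)  # (length, n_gc, -rh_offset, -lh_offset), maximized
    best_block = PairBlock("", "", 0, 0, 0, 0, 0)
    n, m = len(rh), len(lh)
    # rh[i + k] pairs lh[e - k]; enumerate every anchor (rh start i, lh end e)
    # and extend greedily — maximal blocks are found at every anchor.
    for i in range(n):
        for e in range(m - 1, -1, -1):
            length = n_gc = n_au = 0
            while (
                i + length < n
                and e - length >= 0
                and _pairs(rh[i + length], lh[e - length], allow_gu)
            ):
                if (rh[i + length], lh[e - length]) in (("G", "C"), ("C", "G")):
                    n_gc += 1
                elif (rh[i + length], lh[e - length]) in _WC:
                    n_au += 1
                length += 1
            if length == 0:
                continue
            lh_off = e - length + 1
            key = (length, n_gc, -i, -lh_off)
            if key > best_key:
                best_key = key
                best_block = PairBlock(
                    rh_sub=rh[i : i + length],
                    lh_sub=lh[lh_off : e + 1],
                    length=length,
                    n_gc=n_gc,
                    n_au=n_au,
                    rh_offset=i,
                    lh_offset=lh_off,
                )
    return best_block


def classify_pattern(block: PairBlock) -> PatternClass:
    """Scan the block for an adjacent G:C,G:C core; count A/U additions."""
    gc_flags = [
        (a, b) in (("G", "C"), ("C", "G"))
        for a, b in zip(block.rh_sub, reversed(block.lh_sub))
    ]
    core = any(gc_flags[k] and gc_flags[k + 1] for k in range(len(gc_flags) - 1))
    return PatternClass(has_gg_cc_core=core, n_au_additions=block.n_au)


def predict_activity(block: PairBlock) -> ActivityCall:
    """Activity rules for a loop–loop block.

    Active iff the block is length ≥ 3 with a GG:CC core, or length exactly 2
    with both pairs G:C. The GG:CC-core requirement for length ≥ 3 blocks is
    a documented assumption: naturally occurring active blocks all follow the
    GG/CC ± 0–2 A/U pattern and an all-A/U block of length ≥ 3 is untested
    experimentally, so it is conservatively called inactive.
    """
    if block.length >= 3 and classify_pattern(block).has_gg_cc_core:
        return ActivityCall(active=True, rule_fired="block_ge3")
    if block.length == 2 and block.n_gc == 2:
        return ActivityCall(active=True, rule_fired="gc_pair_only")
    return ActivityCall(active=False, rule_fired="none")
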