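"""Hand-in-hand multimerization as cycles in a directed pairing graph.

Each pRNA species exposes a right-hand (RH) and a left-hand (LH) loop. A
directed edge u→v is drawn when u's RH loop forms an active block with v's
LH loop, so a closed ring of n subunits is a closed directed walk of length
n. Species in a mixture are present in many copies, hence walks rather than
simple cycles: one species may occupy alternating positions.

The classic complementation experiments follow directly: two individually
inactive species with cross-complementary loops form a 2-cycle (rings of any
even size), three species in a directed triangle form a 3-cycle (multiples
of 3), and the smallest ring size compatible with both mixtures is six —
the stoichiometric argument for the hexameric pRNA ring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .loop_pairing import max_complementary_block, predict_activity


@dataclass(frozen=True)
class LoopSpecies:
    """A named pRNA loop variant (RH and LH loop sequences)."""

    name: str
    rh: str
    lh: str


@dataclass(frozen=True)
class RingVerdict:
    feasible_sizes: frozenset[int]
    minimal_cycle: int | None
    hexamer_active: bool


def build_pairing_graph(panel: Sequence[LoopSpecies]) -> nx.DiGraph:
    """Directed graph with edge u→v iff u.rh forms an active block with v.lh.

    Self-edges are allowed (self-complementary species). Duplicate names are
    an error.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    names = [sp.name for sp in panel]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate species name(s): {dup}")
    g = nx.DiGraph()
    for sp in panel:
        g.add_node(sp.name, species=sp)
    for u in panel:
        for v in panel:
            block = max_complementary_block(u.rh, v.lh)
            if predict_activity(block).active:
                g.add_edge(u.name, v.name, block=block)
    return g


def feasible_ring_sizes(g: nx.DiGraph, max_n: int = 12) -> frozenset[int]:
    """Ring sizes n ≤ max_n for which a closed directed walk of length n exists.

    Computed by boolean adjacency-matrix powers: n is feasible iff the trace
    of A^n is nonzero.
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    nodes = list(g.nodes)
    if not nodes:
        return frozenset()
    a = nx.to_numpy_array(g, nodelist=nodes, dtype=bool)
    sizes = set()
    power = np.eye(len(nodes), dtype=bool)
    for n in range(1, max_n + 1):
        power = (power.astype(np.uint8) @ a.astype(np.uint8)) > 0
        if power.diagonal().any():
            sizes.add(n)
    return frozenset(sizes)


def minimal_cycle_length(g: nx.DiGraph) -> int | None:
    """Length of the shortest directed cycle (girth), or None if acyclic."""
    best: int | None = None
    for u in g.nodes:
        if g.has_edge(u, u):
            return 1
        lengths = nx.single_source_shortest_path_length(g, u)
        for v in g.predecessors(u):
            if v in lengths and v != u:
                cyc = lengths[v] + 1
                if best is None or cyc < best:
                    best = cyc
    return best


def hexamer_verdict(panel: Sequence[LoopSpecies], max_n: int = 12) -> RingVerdict:
    """Can this mixture close a ring, and in particular a hexamer?

    ``max_n`` defaults to 12 (the hexamer plus one harmonic).
    """
    if max_n < 6:
        raise ValueError("max_n must be >= 6 to assess hexamer feasibility")
    g = build_pairing_graph(panel)
    sizes = feasible_ring_sizes(g, max_n=max_n)
    return RingVerdict(
        feasible_sizes=sizes,
        minimal_cycle=minimal_cycle_length(g),
        hexamer_active=6 in sizes,
    )


def smallest_common_ring(
    panels: Iterable[Sequence[LoopSpecies]], max_n: int = 12
) -> int:
    """Smallest ring size feasible for every panel (e.g. 6 for {2,4,6}∩{3,6}).

    Raises ValueError when no common size ≤ max_n exists.
    """
    common: frozenset[int] | None = None
    for panel in panels:
        sizes = feasible_ring_sizes(build_pairing_graph(panel), max_n=max_n)
        common = sizes if common is None else common & sizes
    if common is None:
        raise ValueError("no panels supplied")
    if not common:
        raise ValueError(f"no common ring size <= {max_n}")
    return min(common)
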