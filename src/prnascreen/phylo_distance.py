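"""Distance matrices, neighbor-joining trees, and patristic-distance reports.

The evolutionary-distance analysis works on the substitutions/site scale:
pairwise distances from an alignment (p-distance or its Jukes–Cantor 1969
correction), a neighbor-joining tree over them, and per-leaf patristic
distances (path sums of branch lengths) relative to a reference leaf — the
Table-2-style report. Maximum-likelihood tree inference is out of scope by
design: the distance report is tree algebra, and an externally inferred
tree can be supplied as Newick and fed straight into the report.

Gap handling is pairwise deletion by default (each pair of rows is compared
over their mutually non-gap columns); complete deletion is available.
"""

from __future__ import annotations

import io as _io
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .io_formats import GAP, ParseError, SeqRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distances (substitutions/site) with labels."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diagonal(d) != 0):
            raise ValueError("diagonal must be zero")
        finite = d[np.isfinite(d)]
        if np.any(finite < 0):
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "labels", tuple(self.labels))

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])


def _pairwise_sites(x: str, y: str, mode: str, keep: np.ndarray | None):
    xa = np.frombuffer(x.encode(), dtype="S1")
    ya = np.frombuffer(y.encode(), dtype="S1")
    gap = GAP.encode()
    if mode == "pairwise":
        mask = (xa != gap) & (ya != gap)
    else:
        mask = keep
    return xa[mask], ya[mask]


def distance_matrix(
    rows: list[SeqRecord],
    model: str = "p",
    gap_mode: str = "pairwise",
    strict: bool = False,
) -> DistanceMatrix:
    """Pairwise distances over mutually non-gap columns.

    ``model="p"`` is the raw mismatch proportion; ``model="jc69"`` applies
    d = -(3/4) ln(1 - 4p/3), which diverges (flagged infinite, or an error
    in strict mode) when p >= 3/4.
    """
    if len(rows) < 2:
        raise ValueError("need at least 2 rows")
    if model not in ("p", "jc69"):
        raise ValueError("model must be 'p' or 'jc69'")
    if gap_mode not in ("pairwise", "complete"):
        raise ValueError("gap_mode must be 'pairwise' or 'complete'")
    n = len(rows)
    keep = None
    if gap_mode == "complete":
        arr = np.array([np.frombuffer(r.residues.encode(), dtype="S1") for r in rows])
        keep = (arr != GAP.encode()).all(axis=0)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            xa, ya = _pairwise_sites(rows[i].residues, rows[j].residues, gap_mode, keep)
            if len(xa) == 0:
                raise ValueError(
                    f"rows {rows[i].id!r} and {rows[j].id!r} share no compared columns"
                )
            p = float((xa != ya).mean())
            if model == "p":
                dij = p
            else:
                if p >= 0.75:
                    if strict:
                        raise ValueError(
                            f"JC69 distance undefined (p={p:.3f} >= 3/4) for "
                            f"{rows[i].id!r} vs {rows[j].id!r}"
                        )
                    logger.warning(
                        "JC69 distance infinite for %s vs %s (p=%.3f)",
                        rows[i].id, rows[j].id, p,
                    )
                    dij = math.inf
                else:
                    dij = -0.75 * math.log1p(-4.0 * p / 3.0)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels=tuple(r.id for r in rows), d=d)


def nj_tree(m: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree; negative branch lengths are clamped to zero.

    On an additive matrix the realized patristic distances equal the input
    exactly. Requires at least 3 taxa and finite distances.
    """
    if len(m.labels) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if not np.all(np.isfinite(m.d)):
        raise ValueError("neighbor joining requires finite distances")
    buf = _io.StringIO()
    buf.write("." + "," + ",".join(m.labels) + "\n")
    for lab, row in zip(m.labels, m.d):
        buf.write(lab + "," + ",".join(repr(float(v)) for v in row) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=buf, taxon_namespace=dendropy.TaxonNamespace(), delimiter=","
    )
    tree = pdm.nj_tree()
    clamped = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            clamped += 1
    if clamped:
        logger.info("clamped %d negative NJ branch length(s) to 0", clamped)
    return tree


def load_newick(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree; unnamed leaves are an error, missing branch
    lengths default to 0 with a warning."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ParseError(f"{path}: not a valid Newick tree ({exc})") from None
    missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            edge.length = 0.0
            missing += 1
    if missing:
        logger.warning("%s: %d branch length(s) missing, defaulted to 0", path, missing)
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ParseError(f"{path}: unnamed leaf in tree")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick")


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """All pairwise leaf-to-leaf path-length sums."""
    pdc = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = tuple(t.label for t in taxa)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdc.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(labels=labels, d=d)


def patristic_report(tree: dendropy.Tree, reference_leaf: str) -> pd.DataFrame:
    """Substitutions/site distance from every leaf to the reference leaf.

    The reference row is 0; rows are sorted by distance then label.
    """
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if reference_leaf not in labels:
        raise KeyError(f"reference leaf {reference_leaf!r} not in tree")
    dm = patristic_distances(tree)
    rows = [
        {"leaf": lab, "substitutions_per_site": dm.value(reference_leaf, lab)}
        for lab in dm.labels
    ]
    df = pd.DataFrame(rows).sort_values(
        ["substitutions_per_site", "leaf"], ignore_index=True
    )
    return df
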