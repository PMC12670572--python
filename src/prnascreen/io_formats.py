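"""Readers and writers for the formats the pipeline consumes.

Sequences travel as :class:`SeqRecord` (a deliberately small record: id,
residues, moltype), alignments as lists of gapped records plus an optional
:class:`FeatureMap` naming column sets, secondary structures as Vienna
dot-bracket, and trees as Newick (handed to :mod:`prnascreen.phylo_distance`).

Conventions
-----------
* RNA is canonicalized to uppercase ``AUCG``; ``T`` is silently converted to
  ``U`` on read (the conversion is logged, genomes are DNA while pRNAs are RNA).
* Coordinates are 0-based half-open internally; 1-based inclusive only in
  human-readable reports.
* Parsers reject structurally invalid input rather than coerce it.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class ParseError(ValueError):
    """Raised when an input file is structurally invalid."""


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence over a declared molecular alphabet.

    Parameters
    ----------
    id : str
        Identifier, unique within a file.
    residues : str
        Uppercase residues; ``AUCG`` for RNA, the 20 amino-acid letters for
        protein. Gap characters are only permitted in alignment rows.
    moltype : {"rna", "protein"}
    """

    id: str
    residues: str
    moltype: str = "rna"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if not self.residues:
            raise ValueError(f"SeqRecord {self.id!r}: residues must be non-empty")
        if self.moltype not in ("rna", "protein"):
            raise ValueError(f"unknown moltype {self.moltype!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FeatureMap:
    """Named alignment-column sets (e.g. Bulge1, Bulge2, Bulge3, critical_G, 3WJ).

    ``features`` maps a feature name to a frozen set of 0-based alignment
    column indices.
    """

    features: dict[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "features", {k: frozenset(v) for k, v in self.features.items()}
        )

    def validate(self, alignment_length: int) -> None:
        for name, cols in self.features.items():
            bad = [c for c in cols if not (0 <= c < alignment_length)]
            if bad:
                raise ParseError(
                    f"feature {name!r}: column index {min(bad)} out of range "
                    f"for alignment of length {alignment_length}"
                )

    def __contains__(self, name: str) -> bool:
        return name in self.features

    def __getitem__(self, name: str) -> frozenset[int]:
        return self.features[name]

    def names(self) -> list[str]:
        return list(self.features)


def canonical_rna(raw: str, *, where: str = "") -> str:
    """Uppercase and unify T→U; raise ParseError on anything outside AUCGT."""
    seq = raw.upper()
    if "T" in seq:
        logger.info("T→U conversion applied%s", f" ({where})" if where else "")
        seq = seq.replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ParseError(
            f"illegal RNA character(s) {sorted(bad)}" + (f" in {where}" if where else "")
        )
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA string (T tolerated and mapped as U)."""
    return canonical_rna(seq)[::-1].translate(_RNA_COMPLEMENT)


def _line_of_record(path: str | Path, rec_id: str) -> int:
    """Best-effort 1-based line number of the header for ``rec_id``."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].split()[:1] == [rec_id]:
                return i
    return 0


def read_fasta(path: str | Path, moltype: str = "rna") -> list[SeqRecord]:
    """Read an unaligned FASTA file into a list of :class:`SeqRecord`.

    Order is preserved, ids must be unique, gaps are rejected, and for RNA the
    documented T→U conversion is applied.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        line = _line_of_record(path, rec.id)
        if rec.id in seen:
            raise ParseError(f"{path}:{line}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if not raw:
            raise ParseError(f"{path}:{line}: empty sequence for record {rec.id!r}")
        if GAP in raw:
            raise ParseError(
                f"{path}:{line}: gap characters not allowed in unaligned FASTA "
                f"(record {rec.id!r})"
            )
        if moltype == "rna":
            try:
                seq = canonical_rna(raw, where=f"{path.name}:{rec.id}")
            except ParseError as exc:
                raise ParseError(f"{path}:{line}: {exc}") from None
        else:
            seq = raw.upper()
            bad = set(seq) - PROTEIN_ALPHABET
            if bad:
                raise ParseError(
                    f"{path}:{line}: illegal protein character(s) {sorted(bad)} "
                    f"in record {rec.id!r}"
                )
        records.append(SeqRecord(id=rec.id, residues=seq, moltype=moltype))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _read_feature_tsv(path: str | Path) -> FeatureMap:
    """Sidecar feature map: TSV of ``name<TAB>c1,c2,...`` with 0-based columns."""
    features: dict[str, frozenset[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'name<TAB>columns'")
            name, cols = parts
            if name in features:
                raise ParseError(f"{path}:{lineno}: duplicate feature name {name!r}")
            try:
                idx = frozenset(int(c) for c in cols.split(",") if c != "")
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer column index") from None
            if any(c < 0 for c in idx):
                raise ParseError(f"{path}:{lineno}: negative column index")
            features[name] = idx
    return FeatureMap(features)


def write_feature_tsv(fmap: FeatureMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, cols in fmap.features.items():
            fh.write(f"{name}\t{','.join(str(c) for c in sorted(cols))}\n")


def _sniff_stockholm(path: Path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return first.startswith("# STOCKHOLM")


def read_alignment(
    path: str | Path, feature_path: str | Path | None = None, moltype: str = "rna"
) -> tuple[list[SeqRecord], FeatureMap]:
    """Read an aligned FASTA or Stockholm file plus an optional feature TSV.

    All rows must be equal length; the gap character ``-`` is permitted (``.``
    in Stockholm is mapped to ``-``). Feature columns are validated against
    the alignment length.
    """
    path = Path(path)
    fmt = "stockholm" if _sniff_stockholm(path) else "fasta"
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None
    rows: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in aln:
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate row id {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq).replace(".", GAP).upper()
        if moltype == "rna":
            body = canonical_rna(raw.replace(GAP, ""), where=f"{path.name}:{rec.id}")
            # re-interleave gaps after canonicalization
            out, k = [], 0
            for ch in raw:
                if ch == GAP:
                    out.append(GAP)
                else:
                    out.append(body[k])
                    k += 1
            raw = "".join(out)
        else:
            bad = set(raw) - PROTEIN_ALPHABET - {GAP}
            if bad:
                raise ParseError(f"{path}: illegal character(s) {sorted(bad)} in {rec.id!r}")
        rows.append(SeqRecord(id=rec.id, residues=raw, moltype=moltype))
    if not rows:
        raise ParseError(f"{path}: empty alignment")
    length = len(rows[0].residues)
    if any(len(r.residues) != length for r in rows):
        raise ParseError(f"{path}: ragged alignment rows")
    fmap = _read_feature_tsv(feature_path) if feature_path is not None else FeatureMap()
    fmap.validate(length)
    return rows, fmap


def write_alignment(rows: Sequence[SeqRecord], path: str | Path) -> None:
    write_fasta(rows, path)


def read_dotbracket(path: str | Path) -> list[tuple[SeqRecord, str]]:
    """Read Vienna dot-bracket files: ``>id`` / sequence line / structure line.

    The structure line must equal the sequence length, contain only ``.()``,
    and be balanced; the error for an unbalanced structure reports the
    0-based position of the first violation.
    """
    path = Path(path)
    out: list[tuple[SeqRecord, str]] = []
    seen: set[str] = set()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith(">"):
            raise ParseError(f"{path}:{i + 1}: expected '>' header")
        rec_id = lines[i][1:].split()[0] if lines[i][1:].split() else ""
        if not rec_id:
            raise ParseError(f"{path}:{i + 1}: empty header")
        if rec_id in seen:
            raise ParseError(f"{path}:{i + 1}: duplicate id {rec_id!r}")
        seen.add(rec_id)
        if i + 2 >= len(lines):
            raise ParseError(f"{path}:{i + 1}: truncated record {rec_id!r}")
        seq = canonical_rna(lines[i + 1].strip(), where=f"{path.name}:{rec_id}")
        db = lines[i + 2].strip().split()[0] if lines[i + 2].strip() else ""
        if len(db) != len(seq):
            raise ParseError(
                f"{path}:{i + 3}: structure length {len(db)} != sequence length {len(seq)}"
            )
        bad = set(db) - set(".()")
        if bad:
            raise ParseError(f"{path}:{i + 3}: illegal structure character(s) {sorted(bad)}")
        _check_balanced(db, where=f"{path}:{i + 3}")
        out.append((SeqRecord(id=rec_id, residues=seq), db))
        i += 3
    if not out:
        raise ParseError(f"{path}: no dot-bracket records found")
    return out


def _check_balanced(db: str, where: str = "") -> None:
    depth = 0
    for pos, ch in enumerate(db):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ParseError(f"{where}: unbalanced ')' at position {pos}")
    if depth != 0:
        # first unmatched '(' is the leftmost one never closed
        depth = 0
        opens: list[int] = []
        for pos, ch in enumerate(db):
            if ch == "(":
                opens.append(pos)
            elif ch == ")":
                opens.pop()
        raise ParseError(f"{where}: unbalanced '(' at position {opens[0]}")


def write_dotbracket(
    entries: Iterable[tuple[SeqRecord, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for rec, db in entries:
            fh.write(f">{rec.id}\n{rec.residues}\n{db}\n")


def read_newick(path: str | Path):
    """Read a Newick tree; thin wrapper over phylo_distance's tree loader."""
    from .phylo_distance import load_newick

    return load_newick(path)
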