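"""Sequence/alignment/tree containers and FASTA / Newick readers and writers.

Conventions used throughout the package:

* Column and letter indices are 0-based internally; 1-based numbers appear
  only in human-readable reports.
* ``-`` is the only internal gap character; ``.`` is accepted on input and
  normalized to ``-``.
* Character case is meaningful: lowercase letters mark cells that carry no
  homology statement (insertion cells in UPP-family outputs). Residues always
  *compare* case-insensitively; case is a per-cell flag, not part of the
  residue identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import dendropy
from Bio import SeqIO

GAP = "-"

#: Canonical residue alphabets (uppercase). Input letters are validated
#: case-insensitively against these.
ALPHABETS = {
    "dna": "ACGT",
    "rna": "ACGU",
    "aa": "ACDEFGHIKLMNPQRSTVWY",
}


class AlignmentError(ValueError):
    """Raised for malformed alignments, sequences or trees."""


def _check_alphabet(name: str) -> str:
    if name not in ALPHABETS:
        raise AlignmentError(
            f"unknown alphabet {name!r}; expected one of {sorted(ALPHABETS)}"
        )
    return name


def _validate_letters(text: str, alphabet: str, *, allow_gaps: bool, where: str) -> None:
    allowed = set(ALPHABETS[alphabet]) | set(ALPHABETS[alphabet].lower())
    if allow_gaps:
        allowed.add(GAP)
    bad = set(text) - allowed
    if bad:
        raise AlignmentError(
            f"{where}: characters outside alphabet {alphabet!r}: {sorted(bad)!r}"
        )


@dataclass(frozen=True)
class Sequence:
    """An ungapped sequence. Lowercase letters flag non-homology cells."""

    id: str
    residues: str
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if not self.id:
            raise AlignmentError("sequence id must be non-empty")
        _check_alphabet(self.alphabet)
        if GAP in self.residues or "." in self.residues:
            raise AlignmentError(f"sequence {self.id!r} contains gap characters")
        _validate_letters(self.residues, self.alphabet, allow_gaps=False,
                          where=f"sequence {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def upper(self) -> str:
        return self.residues.upper()

    @property
    def lowercase_flags(self) -> tuple[bool, ...]:
        return tuple(c.islower() for c in self.residues)


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows over a declared alphabet.

    ``rows[i]`` preserves case; uppercase cells are homology-bearing, lowercase
    cells are insertion (non-homologous) cells. Gaps are ``-``.
    """

    ids: list[str]
    rows: list[str]
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        _check_alphabet(self.alphabet)
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate row ids")
        if self.rows:
            ncol = len(self.rows[0])
            for rid, row in zip(self.ids, self.rows):
                if len(row) != ncol:
                    raise AlignmentError(
                        f"row {rid!r} has length {len(row)}, expected {ncol}"
                    )
                _validate_letters(row, self.alphabet, allow_gaps=True,
                                  where=f"row {rid!r}")
        self._index = {rid: i for i, rid in enumerate(self.ids)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rid: str) -> str:
        try:
            return self.rows[self._index[rid]]
        except KeyError:
            raise AlignmentError(f"unknown row id {rid!r}") from None

    def degapped(self, rid: str) -> str:
        """Ungapped residues of a row, uppercased (case is not identity)."""
        return self.row(rid).replace(GAP, "").upper()

    def sequence(self, rid: str) -> Sequence:
        return Sequence(rid, self.row(rid).replace(GAP, ""), self.alphabet)

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)


@dataclass
class BackboneTree:
    """Unrooted tree over backbone row ids, as an adjacency structure.

    Internal nodes have degree 3 (degree-2 nodes, including a rooted Newick's
    root, are suppressed on construction). Branch lengths, when present, are
    carried but unused by the decomposition.
    """

    adjacency: dict[int, set[int]]
    leaf_labels: dict[int, str]
    edge_lengths: dict[frozenset[int], float] = field(default_factory=dict)

    @property
    def leaf_names(self) -> set[str]:
        return set(self.leaf_labels.values())

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def edges(self) -> list[tuple[int, int]]:
        seen = set()
        out = []
        for u, nbrs in self.adjacency.items():
            for v in nbrs:
                if frozenset((u, v)) not in seen:
                    seen.add(frozenset((u, v)))
                    out.append((u, v))
        return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, aligned: bool, alphabet: str = "dna"):
    """Read FASTA into a :class:`MultipleAlignment` (``aligned=True``) or a
    list of :class:`Sequence` (``aligned=False``).

    ``.`` gaps are normalized to ``-``; case is preserved as the per-cell
    insertion flag; whitespace terminates the record id.
    """
    _check_alphabet(alphabet)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise AlignmentError(f"{path}: duplicate record ids")
    texts = [str(r.seq).replace(".", GAP) for r in records]
    if aligned:
        return MultipleAlignment(ids, texts, alphabet)
    seqs = []
    for rid, text in zip(ids, texts):
        if GAP in text:
            raise AlignmentError(
                f"{path}: record {rid!r} contains gap characters but aligned=False"
            )
        seqs.append(Sequence(rid, text, alphabet))
    return seqs


def write_fasta(alignment, path, width: int = 60) -> None:
    """Write an alignment (or list of :class:`Sequence`) as FASTA.

    Round-trips through :func:`read_fasta` losslessly, including case flags.
    """
    if isinstance(alignment, MultipleAlignment):
        if alignment.n_rows == 0:
            raise AlignmentError("refusing to write an empty alignment")
        items: Iterable[tuple[str, str]] = zip(alignment.ids, alignment.rows)
    else:
        seqs = list(alignment)
        if not seqs:
            raise AlignmentError("refusing to write an empty sequence list")
        items = ((s.id, s.residues) for s in seqs)
    with open(path, "w") as fh:
        for rid, text in items:
            fh.write(f">{rid}\n")
            for start in range(0, len(text), width):
                fh.write(text[start:start + width] + "\n")
            if not text:
                fh.write("\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def _tree_from_dendropy(dtree: "dendropy.Tree") -> BackboneTree:
    dtree.is_rooted = False
    # collapse the artificial degree-2 root of rooted Newick strings
    dtree.suppress_unifurcations()
    node_id: dict = {}
    adjacency: dict[int, set[int]] = {}
    leaf_labels: dict[int, str] = {}
    lengths: dict[frozenset[int], float] = {}

    def nid(node) -> int:
        if node not in node_id:
            node_id[node] = len(node_id)
            adjacency[node_id[node]] = set()
        return node_id[node]

    for edge in dtree.preorder_edge_iter():
        if edge.head_node is None or edge.tail_node is None:
            continue
        u, v = nid(edge.tail_node), nid(edge.head_node)
        adjacency[u].add(v)
        adjacency[v].add(u)
        if edge.length is not None:
            lengths[frozenset((u, v))] = float(edge.length)
    for leaf in dtree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon is not None else None
        if not label:
            raise AlignmentError("tree has an unlabeled leaf")
        leaf_labels[nid(leaf)] = label
    # suppress remaining degree-2 internal nodes (e.g. the rooted root)
    changed = True
    while changed:
        changed = False
        for node in list(adjacency):
            if node in leaf_labels or len(adjacency[node]) != 2:
                continue
            u, v = sorted(adjacency.pop(node))
            adjacency[u].discard(node)
            adjacency[v].discard(node)
            adjacency[u].add(v)
            adjacency[v].add(u)
            lu = lengths.pop(frozenset((node, u)), 0.0)
            lv = lengths.pop(frozenset((node, v)), 0.0)
            lengths[frozenset((u, v))] = lu + lv
            changed = True
    labels = list(leaf_labels.values())
    if len(set(labels)) != len(labels):
        raise AlignmentError("duplicate leaf labels in tree")
    return BackboneTree(adjacency, leaf_labels, lengths)


def read_newick(path) -> BackboneTree:
    """Read a single Newick tree; returns it unrooted with degree-2 nodes
    suppressed. Duplicate leaf labels are an error."""
    try:
        dtree = dendropy.Tree.get(
            path=str(path), schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise AlignmentError(f"{path}: malformed Newick ({exc})") from exc
    return _tree_from_dendropy(dtree)


def read_newick_string(text: str) -> BackboneTree:
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise AlignmentError(f"malformed Newick ({exc})") from exc
    return _tree_from_dendropy(dtree)


def prune_newick(text: str, keep: Iterable[str]) -> str:
    """Restrict a Newick string to a leaf subset (degree-2 nodes suppressed)."""
    keep = set(keep)
    dtree = dendropy.Tree.get(data=text, schema="newick",
                              suppress_internal_node_taxa=True,
                              preserve_underscores=True)
    taxa = [t for t in dtree.taxon_namespace if t.label in keep]
    missing = keep - {t.label for t in taxa}
    if missing:
        raise AlignmentError(f"tree is missing leaves {sorted(missing)}")
    dtree.retain_taxa(taxa)
    return dtree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# Sub-alignment induction
# ---------------------------------------------------------------------------

def induce_subalignment(alignment: MultipleAlignment,
                        ids: TypingSequence[str]):
    """Restrict an alignment to a subset of rows, dropping columns that become
    all-gap in the restriction.

    Returns ``(subalignment, provenance)`` where ``provenance[j]`` is the
    global column index of the induced local column ``j`` (strictly
    increasing).
    """
    ids = list(ids)
    if not ids:
        raise AlignmentError("empty id set")
    rows = [alignment.row(r) for r in ids]  # raises on unknown id
    keep = [j for j in range(alignment.n_columns)
            if any(row[j] != GAP for row in rows)]
    sub_rows = ["".join(row[j] for j in keep) for row in rows]
    return MultipleAlignment(ids, sub_rows, alignment.alphabet), keep
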