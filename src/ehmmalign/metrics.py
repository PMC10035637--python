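"""Sum-of-pairs alignment error: SPFN, SPFP and their average.

Each alignment encodes a set of homology pairs — unordered pairs of letters
(identified by row id and ungapped letter index) that share a column. SPFN is
the fraction of reference pairs missing from the estimate; SPFP the fraction
of estimated pairs absent from the reference. Lowercase cells are unaligned
by convention (insertion blocks) and contribute no pairs. Rates are computed
over the entire alignment; when the reference covers only a subset of rows,
the estimate is restricted to that subset first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import GAP, AlignmentError, MultipleAlignment

_LETTER_BITS = 20  # letter index < 2^20; row rank < 2^12
_MAX_ROWS = 1 << 12
_MAX_LETTERS = 1 << _LETTER_BITS


class MetricUndefinedError(ValueError):
    """Raised when a rate's denominator (a pair set) is empty."""


@dataclass
class HomologyPairSet:
    """Encoded homology pairs of one alignment.

    ``codes`` packs each unordered pair of (row rank, letter index) cells into
    one uint64; ranks come from the sorted row-id list, so two alignments over
    the same ids encode compatibly.
    """

    row_ids: tuple[str, ...]  # sorted
    codes: np.ndarray         # sorted unique uint64

    def __len__(self) -> int:
        return int(self.codes.size)

    def as_tuples(self) -> set[frozenset[tuple[str, int]]]:
        """Decoded pairs, for small/test use."""
        out = set()
        for code in self.codes.tolist():
            a, b = divmod(int(code), 1 << 32)
            out.add(frozenset(((self.row_ids[a >> _LETTER_BITS],
                                a & (_MAX_LETTERS - 1)),
                               (self.row_ids[b >> _LETTER_BITS],
                                b & (_MAX_LETTERS - 1)))))
        return out


def homology_pairs(alignment: MultipleAlignment,
                   ids=None) -> HomologyPairSet:
    """All unordered pairs of uppercase non-gap cells sharing a column."""
    ids = sorted(alignment.ids if ids is None else ids)
    if len(ids) > _MAX_ROWS:
        raise AlignmentError("too many rows for pair encoding")
    rows = [alignment.row(r) for r in ids]
    if rows and len(rows[0]) >= _MAX_LETTERS:
        raise AlignmentError("alignment too wide for pair encoding")
    mat = np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])
    if mat.size == 0:
        return HomologyPairSet(tuple(ids), np.empty(0, dtype=np.uint64))
    nongap = mat != ord(GAP)
    upper = (mat >= ord("A")) & (mat <= ord("Z"))
    letter_idx = np.cumsum(nongap, axis=1) - 1
    node = ((np.arange(len(ids), dtype=np.uint64)[:, None] << _LETTER_BITS)
            | letter_idx.astype(np.uint64))
    keep = nongap & upper
    chunks = []
    for j in range(mat.shape[1]):
        col_nodes = node[keep[:, j], j]
        k = col_nodes.size
        if k < 2:
            continue
        ia, ib = np.triu_indices(k, 1)
        chunks.append((col_nodes[ia] << np.uint64(32)) | col_nodes[ib])
    if not chunks:
        return HomologyPairSet(tuple(ids), np.empty(0, dtype=np.uint64))
    codes = np.unique(np.concatenate(chunks))
    return HomologyPairSet(tuple(ids), codes)


def spfn_spfp(reference: MultipleAlignment,
              estimated: MultipleAlignment) -> tuple[float, float, float]:
    """Return (SPFN, SPFP, average error) of ``estimated`` against ``reference``.

    The two alignments must contain the same sequences (by id and degapped
    residues) over the reference's rows; an empty pair set on either side is
    an error (the rate is undefined, not zero).
    """
    ids = set(reference.ids)
    missing = ids - set(estimated.ids)
    if missing:
        raise AlignmentError(f"estimated alignment lacks rows {sorted(missing)}")
    for rid in ids:
        if reference.degapped(rid) != estimated.degapped(rid):
            raise AlignmentError(f"row {rid!r} differs in degapped residues")
    R = homology_pairs(reference, ids)
    E = homology_pairs(estimated, ids)
    if len(R) == 0:
        raise MetricUndefinedError("reference has no homology pairs; SPFN undefined")
    if len(E) == 0:
        raise MetricUndefinedError("estimate has no homology pairs; SPFP undefined")
    shared = np.intersect1d(R.codes, E.codes, assume_unique=True).size
    spfn = (len(R) - shared) / len(R)
    spfp = (len(E) - shared) / len(E)
    return float(spfn), float(spfp), float((spfn + spfp) / 2.0)


def average_p_distance(alignment: MultipleAlignment) -> float:
    """Proportion of homologous letter pairs that differ (case-insensitive),
    over all uppercase pairs of the alignment's columns."""
    total = 0
    different = 0
    mat = np.array([np.frombuffer(r.upper().encode(), dtype=np.uint8)
                    for r in alignment.rows])
    orig = np.array([np.frombuffer(r.encode(), dtype=np.uint8)
                     for r in alignment.rows])
    keep = (orig != ord(GAP)) & (orig >= ord("A")) & (orig <= ord("Z"))
    for j in range(mat.shape[1]):
        col = mat[keep[:, j], j]
        k = col.size
        if k < 2:
            continue
        pairs = k * (k - 1) // 2
        counts = np.bincount(col)
        same = int((counts * (counts - 1) // 2).sum())
        total += pairs
        different += pairs - same
    if total == 0:
        raise MetricUndefinedError("no homologous pairs in alignment")
    return different / total
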