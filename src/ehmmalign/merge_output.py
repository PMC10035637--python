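"""Per-query letter-to-column maps and the transitive merge into one MSA.

Each placed query is represented purely in memory as an
:class:`ExtendedAlignmentMap`: for every query letter, either the backbone
column it is homologous to, or the *insertion slot* it falls in. Slot ``s``
(0..n) denotes the gap between backbone columns ``s-1`` and ``s`` (slot 0 is
before the first column). The merge identifies the shared backbone columns of
all maps, pads insertion blocks to the widest query, and emits one alignment
whose restriction to the backbone reproduces it column-for-column. Insertion
letters are lowercased: letters of different queries inside the same block
are *not* asserted homologous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import GAP, AlignmentError, MultipleAlignment, Sequence
from .consensus import Trace, TraceError


@dataclass
class ExtendedAlignmentMap:
    """Placement of one query against the backbone columns.

    ``matched_col[i]`` is the 0-based backbone column of letter ``i`` or -1;
    unmatched letters carry ``slot[i]`` in 0..n (see module docstring), -1 for
    matched letters. Matched columns are strictly increasing in letter order,
    and an unmatched letter's slot lies between its neighbours' columns.
    """

    query_id: str
    n_columns: int
    matched_col: np.ndarray
    slot: np.ndarray

    def __post_init__(self) -> None:
        self.matched_col = np.asarray(self.matched_col, dtype=np.int64)
        self.slot = np.asarray(self.slot, dtype=np.int64)
        if self.matched_col.shape != self.slot.shape:
            raise AlignmentError("matched_col and slot must be parallel")
        self.validate()

    def __len__(self) -> int:
        return int(self.matched_col.size)

    def validate(self) -> None:
        last_col = -1
        min_col = 0  # next matched column must not precede a seen slot
        for i in range(len(self)):
            c, s = int(self.matched_col[i]), int(self.slot[i])
            if (c < 0) == (s < 0):
                raise AlignmentError(
                    f"letter {i}: exactly one of column/slot must be set")
            if c >= 0:
                if c >= self.n_columns or c <= last_col or c < min_col:
                    raise AlignmentError(
                        f"letter {i}: column {c} not strictly increasing "
                        f"within {self.n_columns} columns")
                last_col = c
                min_col = c + 1
            else:
                if not (last_col < s <= self.n_columns):
                    raise AlignmentError(
                        f"letter {i}: slot {s} incompatible with preceding "
                        f"column {last_col}")
                min_col = max(min_col, s)

    def matched_pairs(self):
        """(letter index, backbone column) pairs for matched letters."""
        idx = np.nonzero(self.matched_col >= 0)[0]
        return [(int(i), int(self.matched_col[i])) for i in idx]


def trace_to_map(query: Sequence, trace: Trace, n: int) -> ExtendedAlignmentMap:
    """Convert a trace into a total letter map for ``query``.

    Matched letters take their trace column; every unmatched letter goes into
    the insertion slot just after the nearest preceding matched letter's
    column (slot 0 if there is none).
    """
    m = len(query)
    matched = np.full(m, -1, dtype=np.int64)
    for x, y in trace.pairs:
        if not (0 <= x < m and 0 <= y < n):
            raise TraceError(f"trace pair ({x},{y}) outside query/backbone")
        matched[x] = y
    slot = np.full(m, -1, dtype=np.int64)
    last = -1
    for i in range(m):
        if matched[i] >= 0:
            if matched[i] <= last:
                raise TraceError("trace violates the non-crossing constraint")
            last = matched[i]
        else:
            slot[i] = last + 1
    return ExtendedAlignmentMap(query.id, n, matched, slot)


def transitive_merge(backbone: MultipleAlignment,
                     maps: list[ExtendedAlignmentMap],
                     queries: list[Sequence]) -> MultipleAlignment:
    """Merge all per-query maps with the backbone into one MSA.

    Output rows: backbone rows in input order, then query rows in input
    order. Between consecutive backbone columns an insertion block as wide as
    the largest number of letters any query puts there is inserted; letters in
    a block are left-justified and lowercased, backbone rows are all-gap
    there. Restricting the output to backbone rows and deleting the insertion
    blocks reproduces the backbone bit-exactly; degapping any row reproduces
    its input sequence.
    """
    if len(maps) != len(queries):
        raise AlignmentError("one map per query required")
    n = backbone.n_columns
    qids = [q.id for q in queries]
    if len(set(qids)) != len(qids):
        raise AlignmentError("duplicate query ids")
    clash = set(qids) & set(backbone.ids)
    if clash:
        raise AlignmentError(f"query ids collide with backbone ids: {sorted(clash)}")
    per_query_slots: list[dict[int, list[int]]] = []
    for emap, query in zip(maps, queries):
        if emap.query_id != query.id:
            raise AlignmentError(
                f"map for {emap.query_id!r} paired with query {query.id!r}")
        if len(emap) != len(query):
            raise AlignmentError(f"map/query length mismatch for {query.id!r}")
        if emap.n_columns != n:
            raise AlignmentError(f"map for {query.id!r} built for wrong backbone")
        slots: dict[int, list[int]] = {}
        for i in range(len(query)):
            s = int(emap.slot[i])
            if s >= 0:
                slots.setdefault(s, []).append(i)
        per_query_slots.append(slots)

    width = np.zeros(n + 1, dtype=np.int64)
    for slots in per_query_slots:
        for s, letters in slots.items():
            width[s] = max(width[s], len(letters))

    ids = list(backbone.ids) + qids
    rows: list[str] = []
    for brow in backbone.rows:
        parts = []
        for c in range(n):
            parts.append(GAP * int(width[c]))
            parts.append(brow[c])
        parts.append(GAP * int(width[n]))
        rows.append("".join(parts))
    for emap, query, slots in zip(maps, queries, per_query_slots):
        letters = query.upper
        parts = []
        for c in range(n + 1):
            ins = slots.get(c, [])
            block = "".join(letters[i] for i in ins).lower()
            parts.append(block + GAP * (int(width[c]) - len(ins)))
            if c < n:
                col = np.nonzero(emap.matched_col == c)[0]
                parts.append(letters[int(col[0])] if col.size else GAP)
        rows.append("".join(parts))
    return MultipleAlignment(ids, rows, backbone.alphabet)


def insertion_block_ranges(merged: MultipleAlignment,
                           backbone_ids: list[str]) -> list[tuple[int, int]]:
    """0-based half-open output-column ranges of the insertion blocks of a
    merged MSA (columns where every backbone row is a gap)."""
    mask = merged_insertion_columns(merged, backbone_ids)
    ranges: list[tuple[int, int]] = []
    start = None
    for i, ins in enumerate(mask):
        if ins and start is None:
            start = i
        elif not ins and start is not None:
            ranges.append((start, i))
            start = None
    if start is not None:
        ranges.append((start, int(mask.size)))
    return ranges


def merged_insertion_columns(merged: MultipleAlignment,
                             backbone_ids: list[str]) -> np.ndarray:
    """Boolean mask over merged columns: True where all backbone rows are gaps
    (i.e. the column belongs to an insertion block)."""
    rows = [merged.row(r) for r in backbone_ids]
    mask = np.ones(merged.n_columns, dtype=bool)
    for row in rows:
        mask &= np.frombuffer(row.encode(), dtype=np.uint8) == ord(GAP)
    return mask
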