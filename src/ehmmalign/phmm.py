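"""Minimal profile-HMM engine: build from a sub-alignment, forward bit-score,
Viterbi decoding into an extended-alignment map.

The topology is plan7-like without flanking random-sequence states: begin
(node 0) -> {M1, I0, D1}; each node j has match, insert and delete states with
the standard transitions; node L's M/I/D transition to the end state. Match
emissions are Laplace add-pseudocount estimates from the sub-alignment's
match columns (gap fraction below a threshold); insert states emit the
background distribution. Scores are log2-odds against a background null with
a geometric length model, so bit-scores are comparable across ensemble HMMs
of different lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._kernels import MM, MI, MD, IM, II, ID, DM, DI, DD, ST_M, ST_I, ST_D
from .core_io import ALPHABETS, GAP, AlignmentError, MultipleAlignment, Sequence
from .merge_output import ExtendedAlignmentMap


class HmmError(ValueError):
    """Raised for invalid profile construction or scoring inputs."""


def encode(residues: str, alphabet: str) -> np.ndarray:
    """Map residues (case-insensitive) to integer codes; error on others."""
    table = {c: i for i, c in enumerate(ALPHABETS[alphabet])}
    try:
        return np.array([table[c] for c in residues.upper()], dtype=np.int64)
    except KeyError as exc:
        raise HmmError(f"residue {exc.args[0]!r} outside alphabet {alphabet!r}")


def determine_match_columns(subalignment: MultipleAlignment,
                            gap_threshold: float = 0.5) -> list[int]:
    """Local column indices whose gap fraction is strictly below the threshold."""
    if subalignment.n_rows == 0 or subalignment.n_columns == 0:
        raise HmmError("empty sub-alignment")
    k = subalignment.n_rows
    cols = [j for j in range(subalignment.n_columns)
            if subalignment.column(j).count(GAP) / k < gap_threshold]
    if not cols:
        raise HmmError("no column passes the match-column gap threshold")
    return cols


def background_frequencies(alignment: MultipleAlignment) -> np.ndarray:
    """Add-one smoothed residue frequencies over all non-gap cells."""
    A = len(ALPHABETS[alignment.alphabet])
    counts = np.ones(A, dtype=float)
    for row in alignment.rows:
        counts += np.bincount(encode(row.replace(GAP, ""), alignment.alphabet),
                              minlength=A)
    return counts / counts.sum()


@dataclass
class ProfileHmm:
    """A built profile. ``columns[j]`` is the global backbone column of match
    state j+1 (strictly increasing)."""

    alphabet: str
    match_emissions: np.ndarray   # (L, A)
    insert_emissions: np.ndarray  # (A,)
    transitions: np.ndarray       # (9, L+1), structurally absent entries 0
    background: np.ndarray        # (A,)
    columns: np.ndarray           # (L,) global backbone columns
    _logs: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        L = self.match_emissions.shape[0]
        if L < 1:
            raise HmmError("profile needs at least one match state")
        if self.columns.shape != (L,) or np.any(np.diff(self.columns) <= 0):
            raise HmmError("global column map must be strictly increasing, length L")
        for name, dist in (("match", self.match_emissions),
                           ("insert", self.insert_emissions[None, :]),
                           ("background", self.background[None, :])):
            if not np.allclose(dist.sum(axis=1), 1.0, atol=1e-9):
                raise HmmError(f"{name} emission rows must sum to 1")
        t = self.transitions
        for src, rows in (("M", (MM, MI, MD)), ("I", (IM, II, ID)),
                          ("D", (DM, DI, DD))):
            tot = t[rows, :].sum(axis=0)
            j0 = 1 if src == "D" else 0
            if not np.allclose(tot[j0:], 1.0, atol=1e-9):
                raise HmmError(f"{src} transition rows must sum to 1")

    @property
    def L(self) -> int:
        return int(self.match_emissions.shape[0])

    def log_arrays(self):
        """(lme, lie, lt) in natural log space for the DP kernels."""
        if self._logs is None:
            with np.errstate(divide="ignore"):
                lme = np.full((self.L + 1, self.background.size), -np.inf)
                lme[1:] = np.log(self.match_emissions)
                lie = np.log(self.insert_emissions)
                lt = np.where(self.transitions > 0.0,
                              np.log(np.maximum(self.transitions, 1e-300)),
                              -np.inf)
            self._logs = (lme, lie, lt)
        return self._logs


@dataclass(frozen=True)
class HmmScore:
    """Bit-score of one query under one ensemble HMM (larger is better)."""

    hmm_index: int
    bitscore: float


def build_profile_hmm(subalignment: MultipleAlignment,
                      provenance,
                      pseudocount: float = 1.0,
                      gap_threshold: float = 0.5,
                      background: np.ndarray | None = None) -> ProfileHmm:
    """Estimate a profile HMM from a sub-alignment.

    ``provenance`` maps local columns to global backbone columns (from
    :func:`ehmmalign.core_io.induce_subalignment`); ``background`` defaults to
    the sub-alignment's own smoothed residue frequencies — the pipeline passes
    the full backbone alignment's frequencies instead.
    """
    if pseudocount <= 0:
        raise HmmError("pseudocount must be positive")
    alphabet = subalignment.alphabet
    A = len(ALPHABETS[alphabet])
    provenance = list(provenance)
    if len(provenance) != subalignment.n_columns:
        raise HmmError("provenance length must equal the sub-alignment width")
    match_cols = determine_match_columns(subalignment, gap_threshold)
    L = len(match_cols)
    node_of = {c: j + 1 for j, c in enumerate(match_cols)}
    if background is None:
        background = background_frequencies(subalignment)
    background = np.asarray(background, dtype=float)

    emit = np.full((L, A), pseudocount, dtype=float)
    tcount = np.zeros((9, L + 1), dtype=float)
    step_of = {("M", "M"): MM, ("M", "I"): MI, ("M", "D"): MD,
               ("I", "M"): IM, ("I", "I"): II, ("I", "D"): ID,
               ("D", "M"): DM, ("D", "I"): DI, ("D", "D"): DD}
    for row in subalignment.rows:
        state, j = "M", 0  # begin
        for c, cell in enumerate(row):
            if c in node_of:
                nxt = "D" if cell == GAP else "M"
                tcount[step_of[(state, nxt)], j] += 1
                state, j = nxt, node_of[c]
                if nxt == "M":
                    emit[j - 1, int(encode(cell, alphabet)[0])] += 1
            elif cell != GAP:
                tcount[step_of[(state, "I")], j] += 1
                state = "I"
        tcount[step_of[(state, "M")], j] += 1  # exit to end
    emissions = emit / emit.sum(axis=1, keepdims=True)

    trans = np.zeros((9, L + 1), dtype=float)
    for rows in ((MM, MI, MD), (IM, II, ID), (DM, DI, DD)):
        for j in range(L + 1):
            if rows[0] == DM and j == 0:
                continue  # no delete state at the begin node
            allowed = list(rows[:2]) if j == L else list(rows)  # no D_{L+1}
            tot = tcount[allowed, j].sum() + pseudocount * len(allowed)
            for r in allowed:
                trans[r, j] = (tcount[r, j] + pseudocount) / tot
    return ProfileHmm(alphabet, emissions, background.copy(), trans,
                      background, np.array([provenance[c] for c in match_cols],
                                           dtype=np.int64))


def _null_logprob(hmm: ProfileHmm, codes: np.ndarray) -> float:
    """Background null with geometric length model (continue prob r/(r+1))."""
    r = float(codes.size)
    lbg = float(np.log(hmm.background[codes]).sum())
    return lbg + r * np.log(r / (r + 1.0)) + np.log(1.0 / (r + 1.0))


def forward_logprob(hmm: ProfileHmm, query: Sequence) -> float:
    """Natural-log forward probability of the query under the profile."""
    codes = encode(query.residues, hmm.alphabet)
    lme, lie, lt = hmm.log_arrays()
    return float(_kernels.forward_logprob(codes, lme, lie, lt))


def forward_bitscore(hmm: ProfileHmm, query: Sequence,
                     hmm_index: int = 0) -> HmmScore:
    """log2( P_forward(query | hmm) / P_null(query) )."""
    if len(query) < 1:
        raise HmmError("query must have length >= 1")
    codes = encode(query.residues, hmm.alphabet)
    lme, lie, lt = hmm.log_arrays()
    lf = float(_kernels.forward_logprob(codes, lme, lie, lt))
    bits = (lf - _null_logprob(hmm, codes)) / np.log(2.0)
    return HmmScore(hmm_index, float(bits))


def viterbi_logprob(hmm: ProfileHmm, query: Sequence) -> float:
    codes = encode(query.residues, hmm.alphabet)
    lme, lie, lt = hmm.log_arrays()
    best, _arg, _pM, _pI, _pD = _kernels.viterbi(codes, lme, lie, lt)
    return float(best)


def viterbi_extended_alignment(hmm: ProfileHmm, query: Sequence,
                               n_columns: int | None = None
                               ) -> ExtendedAlignmentMap:
    """Decode the most probable path into a per-letter map.

    Match-emitted letters map to the match state's global backbone column;
    insert-emitted letters go to the slot just after the preceding match
    state's column (slot 0 before match state 1). Ties in the maximization are
    broken match > delete > insert, so decoding is deterministic.
    """
    if len(query) < 1:
        raise HmmError("query must have length >= 1")
    codes = encode(query.residues, hmm.alphabet)
    lme, lie, lt = hmm.log_arrays()
    best, arg, pM, pI, pD = _kernels.viterbi(codes, lme, lie, lt)
    if not np.isfinite(best):
        raise HmmError("no finite-probability path (zero emission?)")
    if n_columns is None:
        n_columns = int(hmm.columns[-1]) + 1
    m = codes.size
    matched = np.full(m, -1, dtype=np.int64)
    slot = np.full(m, -1, dtype=np.int64)
    state, i, j = int(arg), m, hmm.L
    while not (state == ST_M and i == 0 and j == 0):
        if state == ST_M:
            matched[i - 1] = hmm.columns[j - 1]
            state, i, j = int(pM[i, j]), i - 1, j - 1
        elif state == ST_I:
            slot[i - 1] = int(hmm.columns[j - 1]) + 1 if j >= 1 else 0
            state, i = int(pI[i, j]), i - 1
        else:  # delete
            state, j = int(pD[i, j]), j - 1
    return ExtendedAlignmentMap(query.id, n_columns, matched, slot)
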