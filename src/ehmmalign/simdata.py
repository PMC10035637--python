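"""Synthetic benchmark generator for high-fragmentation (HF) conditions.

Sequences are evolved down a random bifurcating tree with per-branch
substitutions and geometric-length indels; column identity is tracked through
every event, so the emitted alignment is the exact homology record (the
"true" alignment). A stated fraction of leaves is then fragmented to a short
target length (default: half the sequences to ~250 bp, normally distributed
lengths); fragments become the query set and the remaining full-length
sequences the backbone, whose true sub-alignment and pruned true tree serve
as the backbone inputs of the pipeline.

The generator aims at homology structure and divergence control, not model
realism: substitutions are uniform across residues (no GTR rates), indel
lengths are geometric, and branch lengths only shape the tree, not the event
probabilities (each branch applies the same per-site probabilities).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .core_io import (ALPHABETS, GAP, AlignmentError, MultipleAlignment,
                      Sequence, induce_subalignment, prune_newick)


@dataclass
class SimulationParams:
    """Knobs of the HF simulation; the seed is mandatory."""

    seed: int
    n_taxa: int = 120
    root_length: int = 1000
    sub_prob: float = 0.1          # per site per branch
    indel_prob: float = 0.02       # per site per branch (ins/del 50:50)
    indel_mean_length: float = 2.0  # geometric mean length
    frag_fraction: float = 0.5
    frag_mean: float = 250.0
    frag_sd: float | None = None   # default mean/10
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        for p in (self.sub_prob, self.indel_prob, self.frag_fraction):
            if not 0.0 <= p <= 1.0:
                raise AlignmentError(f"probability {p} outside [0, 1]")
        if self.n_taxa < 2 or self.root_length < 1 or self.frag_mean <= 0:
            raise AlignmentError("taxon count and lengths must be positive")
        if self.frag_sd is None:
            self.frag_sd = self.frag_mean / 10.0


class _Node:
    __slots__ = ("label", "left", "right", "blen")

    def __init__(self, label=None, left=None, right=None, blen=0.0):
        self.label, self.left, self.right, self.blen = label, left, right, blen


def _random_tree(n_taxa: int, rng: np.random.Generator) -> _Node:
    """Uniform random joins (coalescent-style topology), exponential lengths."""
    nodes = [_Node(label=f"S{i:04d}", blen=float(rng.exponential(0.1)))
             for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(_Node(left=a, right=b, blen=float(rng.exponential(0.1))))
    return nodes[0]


def _newick(node: _Node) -> str:
    def fmt(n: _Node) -> str:
        if n.label is not None:
            return f"{n.label}:{n.blen:.6f}"
        return f"({fmt(n.left)},{fmt(n.right)}):{n.blen:.6f}"
    return f"({fmt(node.left)},{fmt(node.right)});" if node.label is None \
        else f"({fmt(node)});"


def _evolve_branch(sites, params: SimulationParams,
                   rng: np.random.Generator):
    """Apply one branch of substitutions then indels to [(key, residue)]."""
    A = len(ALPHABETS[params.alphabet])
    n = len(sites)
    if n == 0:
        return []
    res = np.array([r for _k, r in sites], dtype=np.int64)
    hit = np.nonzero(rng.random(n) < params.sub_prob)[0]
    if hit.size:
        res[hit] = (res[hit] + 1 + rng.integers(0, A - 1, size=hit.size)) % A
    events = np.zeros(n, dtype=np.int8)
    ev_pos = np.nonzero(rng.random(n) < params.indel_prob)[0]
    if ev_pos.size:
        events[ev_pos] = np.where(rng.random(ev_pos.size) < 0.5, 1, 2)
    p_geom = min(1.0, 1.0 / params.indel_mean_length)
    out = []
    i = 0
    max_key = sites[-1][0] + 1
    while i < n:
        key = sites[i][0]
        ev = int(events[i])
        if ev == 2:  # deletion of a geometric run starting here
            i += int(rng.geometric(p_geom))
            continue
        out.append((key, int(res[i])))
        if ev == 1:  # insertion after this site; keys bisect to the next key
            ln = int(rng.geometric(p_geom))
            nxt = sites[i + 1][0] if i + 1 < n else max_key
            span = nxt - key
            new_res = rng.integers(0, A, size=ln)
            for t in range(ln):
                out.append((key + span * Fraction(t + 1, ln + 1),
                            int(new_res[t])))
        i += 1
    return out


def _simulate_once(params: SimulationParams, rng: np.random.Generator):
    root = _random_tree(params.n_taxa, rng)
    letters = ALPHABETS[params.alphabet]
    root_sites = [(Fraction(k), int(r)) for k, r in
                  enumerate(rng.integers(0, len(letters), size=params.root_length))]
    leaves: dict[str, list] = {}

    def walk(node: _Node, sites) -> None:
        sites = _evolve_branch(sites, params, rng)
        if node.label is not None:
            leaves[node.label] = sites
            return
        walk(node.left, sites)
        walk(node.right, sites)

    walk(root.left, root_sites)
    walk(root.right, root_sites)
    return root, leaves


def simulate_true_alignment(params: SimulationParams):
    """Evolve down a random tree; return (true alignment, Newick string).

    Deterministic given ``params.seed``. If a leaf loses every site, the
    simulation is redrawn once (continuing the seeded stream) before failing.
    """
    rng = np.random.default_rng(params.seed)
    for attempt in range(2):
        root, leaves = _simulate_once(params, rng)
        if all(len(s) > 0 for s in leaves.values()):
            break
    else:
        raise AlignmentError("a simulated sequence lost all sites twice")
    letters = ALPHABETS[params.alphabet]
    all_keys = sorted({k for sites in leaves.values() for k, _r in sites})
    col = {k: i for i, k in enumerate(all_keys)}
    ids = sorted(leaves)
    rows = []
    for rid in ids:
        row = [GAP] * len(all_keys)
        for k, r in leaves[rid]:
            row[col[k]] = letters[r]
        rows.append("".join(row))
    return MultipleAlignment(ids, rows, params.alphabet), _newick(root)


def fragmentize(sequences: list[Sequence], fraction: float, mean: float,
                sd: float | None = None, seed: int = 0):
    """Replace a seeded sample of ``round(fraction*n)`` sequences by random
    contiguous fragments (truncated-normal lengths, floor 10).

    Returns ``(sequences, windows)`` where ``windows`` maps each fragment id
    to its (start, stop) half-open letter range in the source sequence; its
    key set is the fragment id set.
    """
    if not 0.0 <= fraction <= 1.0:
        raise AlignmentError("fraction outside [0, 1]")
    if sd is None:
        sd = mean / 10.0
    lengths = np.array([len(s) for s in sequences], dtype=float)
    if lengths.size and mean >= float(np.median(lengths)):
        raise AlignmentError("fragment mean must be below the median length")
    rng = np.random.default_rng(seed)
    n_frag = int(round(fraction * len(sequences)))
    picked = set(rng.choice(len(sequences), size=n_frag, replace=False).tolist())
    out: list[Sequence] = []
    windows: dict[str, tuple[int, int]] = {}
    for i, seq in enumerate(sequences):
        if i not in picked:
            out.append(seq)
            continue
        full = len(seq)
        ln = int(np.clip(round(rng.normal(mean, sd)), 10, full))
        start = int(rng.integers(0, full - ln + 1))
        out.append(Sequence(seq.id, seq.residues[start:start + ln],
                            seq.alphabet))
        windows[seq.id] = (start, start + ln)
    return out, windows


@dataclass
class HfDataset:
    """One simulated HF benchmark instance."""

    params: SimulationParams
    true_alignment: MultipleAlignment
    tree_newick: str
    reference: MultipleAlignment      # true alignment with fragment letters only
    backbone_alignment: MultipleAlignment
    backbone_tree_newick: str
    backbone_ids: list[str]
    queries: list[Sequence]           # the fragments
    fragment_windows: dict[str, tuple[int, int]]


def _mask_to_window(row: str, window: tuple[int, int]) -> str:
    """Gap out letters of a gapped row whose letter index is outside window."""
    start, stop = window
    out = []
    idx = 0
    for cell in row:
        if cell == GAP:
            out.append(GAP)
        else:
            out.append(cell if start <= idx < stop else GAP)
            idx += 1
    return "".join(out)


def make_hf_dataset(params: SimulationParams) -> HfDataset:
    """Simulate, fragment, and split into backbone/query per HF conditions.

    Fragments are assigned to the query set directly and full-length
    sequences to the backbone; the backbone alignment is the true
    sub-alignment on the backbone ids and the backbone tree is the true tree
    pruned to them. The evaluation reference is the true alignment with each
    fragment's off-window letters gapped out (a fragment letter inherits the
    true homology of the source letter).
    """
    true_aln, newick = simulate_true_alignment(params)
    seqs = [true_aln.sequence(rid) for rid in true_aln.ids]
    fragged, windows = fragmentize(seqs, params.frag_fraction,
                                   params.frag_mean, params.frag_sd,
                                   seed=params.seed)
    backbone_ids = [s.id for s in fragged if s.id not in windows]
    if len(backbone_ids) < 3:
        raise AlignmentError("too few full-length sequences for a backbone")
    queries = [s for s in fragged if s.id in windows]
    backbone_aln, _prov = induce_subalignment(true_aln, backbone_ids)
    backbone_tree = prune_newick(newick, backbone_ids)
    ref_rows = []
    for rid in true_aln.ids:
        row = true_aln.row(rid)
        if rid in windows:
            row = _mask_to_window(row, windows[rid])
        ref_rows.append(row)
    reference = MultipleAlignment(list(true_aln.ids), ref_rows, params.alphabet)
    return HfDataset(params, true_aln, newick, reference, backbone_aln,
                     backbone_tree, backbone_ids, queries, windows)
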