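"""HMM weighting, top-k selection, the weighted alignment graph, and the
exact maximum-weight non-crossing trace.

Per query, every ensemble HMM gets a weight proportional to
``s_i * 2**b_i`` (subset size times the bit-score odds ratio). The top-k
HMMs' Viterbi placements vote edges into a bipartite graph between query
letters and backbone columns; the consensus placement is the maximum-weight
*trace* — a set of edges in which query and backbone coordinates strictly
increase together (a valid pairwise alignment's match set). With zero gap
cost this is solvable exactly by an O(mn) dynamic program; an exhaustive
enumeration oracle is provided for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from ._kernels import trace_dp_matrix

_LN2 = float(np.log(2.0))


class TraceError(ValueError):
    """Raised for invalid graphs or traces."""


@dataclass
class HmmWeightVector:
    """Normalized per-HMM weights, optionally restricted to a selected set.

    ``weights`` always has one entry per ensemble HMM; entries outside
    ``selected`` are zero after top-k selection. Selected weights sum to 1.
    """

    weights: np.ndarray
    selected: list[int]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        total = self.weights[self.selected].sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise TraceError(f"selected weights sum to {total}, expected 1")


def compute_weights(bitscores, sizes) -> HmmWeightVector:
    """Weight w_i = s_i 2^{b_i} / sum_j s_j 2^{b_j}, in log space.

    ``bitscores`` may be floats or objects with a ``bitscore`` attribute.
    """
    b = np.array([getattr(s, "bitscore", s) for s in bitscores], dtype=float)
    s = np.array(list(sizes), dtype=float)
    if b.size == 0 or b.size != s.size:
        raise TraceError("bitscores and sizes must be nonempty and aligned")
    log_w = np.log(s) + b * _LN2
    log_w -= logsumexp(log_w)
    w = np.exp(log_w)
    w /= w.sum()  # tidy residual rounding
    return HmmWeightVector(w, list(range(b.size)))


def select_top_k(weights: HmmWeightVector, k: int) -> HmmWeightVector:
    """Keep the k largest weights (ties to the smaller index), renormalized."""
    if k < 1:
        raise TraceError("k must be at least 1")
    order = np.argsort(-weights.weights[weights.selected], kind="stable")
    keep = [weights.selected[i] for i in order[:k]]
    out = np.zeros_like(weights.weights)
    out[keep] = weights.weights[keep]
    out[keep] /= out[keep].sum()
    return HmmWeightVector(out, keep)


@dataclass
class WeightedAlignmentGraph:
    """Sparse positive weights on (query letter, backbone column) pairs.

    Absent pairs are forbidden matches (score minus infinity); stored weights
    are strictly positive. Coordinates are 0-based.
    """

    m: int  # query length
    n: int  # backbone column count
    edges: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (x, y), w in self.edges.items():
            if not (0 <= x < self.m and 0 <= y < self.n):
                raise TraceError(f"edge ({x},{y}) outside {self.m}x{self.n}")
            if not w > 0:
                raise TraceError(f"edge ({x},{y}) has non-positive weight {w}")

    @property
    def total_weight(self) -> float:
        return float(sum(self.edges.values()))


def build_alignment_graph(maps, weights: HmmWeightVector, m: int,
                          n: int) -> WeightedAlignmentGraph:
    """Sum selected-HMM weights over each (letter, column) pair the HMMs'
    extended alignments agree on. ``maps[i]`` belongs to ``weights.selected[i]``.
    """
    if len(maps) != len(weights.selected):
        raise TraceError("one extended-alignment map per selected HMM required")
    edges: dict[tuple[int, int], float] = {}
    for emap, idx in zip(maps, weights.selected):
        w = float(weights.weights[idx])
        if w <= 0.0:
            continue
        for x, y in emap.matched_pairs():
            if x >= m or y >= n:
                raise TraceError(f"map pair ({x},{y}) outside {m}x{n}")
            edges[(x, y)] = edges.get((x, y), 0.0) + w
    return WeightedAlignmentGraph(m, n, edges)


@dataclass
class Trace:
    """A non-crossing set of matched (query letter, backbone column) pairs."""

    pairs: list[tuple[int, int]]
    total_weight: float

    def __post_init__(self) -> None:
        self.pairs = sorted(self.pairs)


def validate_trace(trace: Trace, graph: WeightedAlignmentGraph) -> None:
    """Check the non-crossing constraint and edge membership; raise if violated."""
    prev = None
    for pair in trace.pairs:
        if pair not in graph.edges:
            raise TraceError(f"trace pair {pair} is not a graph edge")
        if prev is not None and not (pair[0] > prev[0] and pair[1] > prev[1]):
            raise TraceError(f"trace pairs {prev} and {pair} cross")
        prev = pair
    got = sum(graph.edges[p] for p in trace.pairs)
    if abs(got - trace.total_weight) > 1e-9:
        raise TraceError("trace weight does not match its pairs")


def max_weight_trace(graph: WeightedAlignmentGraph) -> Trace:
    """Exact maximum-weight trace by the O(mn) zero-gap-cost DP.

    Recurrence D[x][y] = max(D[x-1][y], D[x][y-1], D[x-1][y-1] + w(x,y));
    traceback prefers diagonal, then vertical (skip a query letter), then
    horizontal, so among optima the result is deterministic and matches as
    many letters as possible.
    """
    m, n = graph.m, graph.n
    if not graph.edges or m == 0 or n == 0:
        return Trace([], 0.0)
    items = sorted(graph.edges.items())
    ex = np.array([x for (x, _y), _w in items], dtype=np.int64)
    ey = np.array([y for (_x, y), _w in items], dtype=np.int64)
    ew = np.array([w for _xy, w in items], dtype=np.float64)
    D, W = trace_dp_matrix(m, n, ex, ey, ew)
    pairs: list[tuple[int, int]] = []
    x, y = m, n
    while x > 0 and y > 0:
        here = D[x, y]
        if W[x, y] != -np.inf and here == D[x - 1, y - 1] + W[x, y]:
            pairs.append((x - 1, y - 1))
            x -= 1
            y -= 1
        elif here == D[x - 1, y]:
            x -= 1
        else:
            y -= 1
    trace = Trace(pairs, float(D[m, n]))
    validate_trace(trace, graph)
    return trace


def _compatible(p: tuple[int, int], q: tuple[int, int]) -> bool:
    return (p[0] < q[0] and p[1] < q[1]) or (q[0] < p[0] and q[1] < p[1])


def brute_force_trace(graph: WeightedAlignmentGraph,
                      max_edges: int = 20) -> Trace:
    """Test oracle: enumerate all edge subsets, keep non-crossing ones, return
    a maximum-weight one. Exponential; refuses more than ``max_edges`` edges.
    """
    items = sorted(graph.edges.items())
    E = len(items)
    if E > max_edges:
        raise TraceError(f"{E} edges exceeds brute-force limit {max_edges}")
    # bitmask of edges incompatible with each edge
    incompat = [0] * E
    for i in range(E):
        for j in range(E):
            if i != j and not _compatible(items[i][0], items[j][0]):
                incompat[i] |= 1 << j
    weights = [w for _p, w in items]
    best_mask, best_w = 0, 0.0
    for mask in range(1 << E):
        w = 0.0
        ok = True
        mm = mask
        while mm:
            i = (mm & -mm).bit_length() - 1
            if mask & incompat[i]:
                ok = False
                break
            w += weights[i]
            mm &= mm - 1
        if ok and w > best_w:
            best_mask, best_w = mask, w
    pairs = [items[i][0] for i in range(E) if best_mask >> i & 1]
    return Trace(pairs, best_w)
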