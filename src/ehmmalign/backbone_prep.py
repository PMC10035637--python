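"""Backbone/query splitting and centroid-edge decomposition of the backbone tree.

The ensemble of profile HMMs is built on nested subsets of the backbone,
obtained by recursively deleting the *centroid edge* of the (sub)tree — the
edge whose removal splits the leaves most evenly. All subsets at all levels
are kept, so the ensemble contains the full backbone set, its two halves,
their halves, and so on down to subsets of at most ``min_subset_size`` leaves.
This is the hierarchical decomposition scheme of the UPP family of methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import AlignmentError, BackboneTree, Sequence


@dataclass(frozen=True)
class DecompositionNode:
    """One subset of the hierarchical decomposition."""

    subset: frozenset[str]
    level: int  # 0 = full backbone set

    @property
    def size(self) -> int:
        return len(self.subset)


def split_backbone_queries(sequences: list[Sequence],
                           backbone_size: int = 1000,
                           length_window: float = 0.25,
                           seed: int = 0):
    """Split sequences into backbone candidates and queries by length.

    A sequence is a full-length candidate iff its ungapped length is at least
    ``(1 - length_window)`` times the median length; shorter sequences are
    treated as fragments and always become queries. Up to ``backbone_size``
    candidates are sampled uniformly (seeded); the rest are queries.

    Returns ``(backbone_ids, query_ids)`` in input order.
    """
    if len(sequences) < 2:
        raise AlignmentError("need at least 2 sequences to split")
    lengths = np.array([len(s) for s in sequences], dtype=float)
    median = float(np.median(lengths))
    cutoff = (1.0 - length_window) * median
    candidates = [s.id for s, ln in zip(sequences, lengths) if ln >= cutoff]
    if len(candidates) < 2:
        raise AlignmentError(
            f"fewer than 2 full-length candidates (cutoff {cutoff:.1f})"
        )
    if len(candidates) > backbone_size:
        rng = np.random.default_rng(seed)
        picked = rng.choice(len(candidates), size=backbone_size, replace=False)
        backbone = {candidates[i] for i in picked}
    else:
        backbone = set(candidates)
    backbone_ids = [s.id for s in sequences if s.id in backbone]
    query_ids = [s.id for s in sequences if s.id not in backbone]
    return backbone_ids, query_ids


def _component_split(tree: BackboneTree, nodes: set[int], u: int, v: int):
    """Leaf-label sets of the two components of ``nodes`` after cutting (u,v)."""

    def reach(start: int, blocked: int) -> set[int]:
        seen = {start}
        stack = [start]
        while stack:
            w = stack.pop()
            for x in tree.adjacency[w]:
                if x in nodes and x != blocked and x not in seen:
                    seen.add(x)
                    stack.append(x)
        return seen

    side_u = reach(u, v)
    side_v = nodes - side_u
    leaves_u = {tree.leaf_labels[n] for n in side_u if n in tree.leaf_labels}
    leaves_v = {tree.leaf_labels[n] for n in side_v if n in tree.leaf_labels}
    return side_u, leaves_u, side_v, leaves_v


def _centroid_edge(tree: BackboneTree, nodes: set[int]):
    """Pick the centroid edge of the subtree induced by ``nodes``.

    Ties on the balance criterion (smaller max-side leaf count) are broken
    deterministically: orient each edge so side A contains the overall
    lexicographically smallest leaf, then prefer the edge whose side B has the
    lexicographically smallest leaf.
    """
    all_leaves = sorted(tree.leaf_labels[n] for n in nodes if n in tree.leaf_labels)
    global_min = all_leaves[0]
    best = None
    for u in sorted(nodes):
        for v in sorted(tree.adjacency[u]):
            if v not in nodes or v < u:
                continue
            side_u, leaves_u, side_v, leaves_v = _component_split(tree, nodes, u, v)
            if not leaves_u or not leaves_v:
                continue  # cutting here strands no leaves on one side
            if global_min in leaves_u:
                other = leaves_v
            else:
                other = leaves_u
            key = (max(len(leaves_u), len(leaves_v)), min(other))
            if best is None or key < best[0]:
                best = (key, side_u, side_v)
    if best is None:
        raise AlignmentError("subtree has no splittable edge")
    return best[1], best[2]


def centroid_edge_decompose(tree: BackboneTree,
                            min_subset_size: int = 10) -> list[DecompositionNode]:
    """Hierarchical centroid-edge decomposition of the backbone tree.

    Returns every subset at every level (the full leaf set first, then by
    recursion order); a subset is split further only while it has more than
    ``min_subset_size`` leaves.
    """
    if min_subset_size < 2:
        raise AlignmentError("min_subset_size must be at least 2")
    out: list[DecompositionNode] = []

    def recurse(nodes: set[int], level: int) -> None:
        leaves = frozenset(tree.leaf_labels[n] for n in nodes
                           if n in tree.leaf_labels)
        out.append(DecompositionNode(leaves, level))
        if len(leaves) <= min_subset_size:
            return
        side_a, side_b = _centroid_edge(tree, nodes)
        recurse(side_a, level + 1)
        recurse(side_b, level + 1)

    recurse(set(tree.adjacency), 0)
    return out
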