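"""End-to-end orchestration: decompose, build the HMM ensemble, place every
query, and transitively merge.

Per-query work (score all HMMs, weight, select top-k, Viterbi-decode, build
the alignment graph, solve the trace DP, map) is independent across queries;
results are merged in input order, so the output is identical for any worker
count.
"""

from __future__ import annotations

import logging
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import asdict, dataclass

from .backbone_prep import centroid_edge_decompose
from .consensus import (build_alignment_graph, compute_weights,
                        max_weight_trace, select_top_k, HmmWeightVector)
from .core_io import (AlignmentError, BackboneTree, MultipleAlignment,
                      Sequence, induce_subalignment)
from .merge_output import ExtendedAlignmentMap, trace_to_map, transitive_merge
from .phmm import (HmmError, ProfileHmm, background_frequencies,
                   build_profile_hmm, forward_bitscore,
                   viterbi_extended_alignment)

log = logging.getLogger("ehmmalign")


@dataclass
class PipelineConfig:
    """Effective knobs of one run; every field has a default."""

    k: int = 10
    min_subset_size: int = 10
    pseudocount: float = 1.0
    gap_threshold: float = 0.5
    weight_floor: float = 1e-12
    workers: int = 1
    seed: int = 0


@dataclass
class SubsetHmm:
    """One ensemble member: a backbone subset and its profile HMM."""

    ids: frozenset[str]
    level: int
    hmm: ProfileHmm

    @property
    def size(self) -> int:
        return len(self.ids)


def build_ensemble(backbone: MultipleAlignment, tree: BackboneTree,
                   min_subset_size: int = 10, pseudocount: float = 1.0,
                   gap_threshold: float = 0.5) -> list[SubsetHmm]:
    """Decompose the backbone tree and build one profile HMM per subset.

    All HMMs share the full backbone's background frequencies. Subsets whose
    induced sub-alignment yields no match column are skipped with a warning
    (possible only for extreme gap content).
    """
    if tree.leaf_names != set(backbone.ids):
        raise AlignmentError("tree leaves do not match backbone row ids")
    background = background_frequencies(backbone)
    ensemble: list[SubsetHmm] = []
    for node in centroid_edge_decompose(tree, min_subset_size):
        sub, provenance = induce_subalignment(backbone, sorted(node.subset))
        try:
            hmm = build_profile_hmm(sub, provenance, pseudocount,
                                    gap_threshold, background)
        except HmmError as exc:
            log.warning("skipping subset of %d: %s", node.size, exc)
            continue
        ensemble.append(SubsetHmm(node.subset, node.level, hmm))
    if not ensemble:
        raise AlignmentError("no usable HMM could be built from the backbone")
    return ensemble


def place_query(query: Sequence, ensemble: list[SubsetHmm], n_columns: int,
                k: int = 10, weight_floor: float = 1e-12):
    """Score, weight, select top-k, vote, and solve the trace for one query.

    Returns ``(map, diagnostics)`` where diagnostics records the selected HMM
    indices, their weights, and the optimal trace weight.
    """
    scores = [forward_bitscore(sh.hmm, query, i)
              for i, sh in enumerate(ensemble)]
    weights = compute_weights(scores, [sh.size for sh in ensemble])
    kept = [i for i in weights.selected if weights.weights[i] >= weight_floor]
    if kept and len(kept) < len(weights.selected):
        w = weights.weights.copy()
        mask = [i for i in weights.selected if i not in set(kept)]
        w[mask] = 0.0
        w[kept] /= w[kept].sum()
        weights = HmmWeightVector(w, kept)
    selected = select_top_k(weights, k)
    maps = [viterbi_extended_alignment(ensemble[i].hmm, query, n_columns)
            for i in selected.selected]
    graph = build_alignment_graph(maps, selected, len(query), n_columns)
    trace = max_weight_trace(graph)
    emap = trace_to_map(query, trace, n_columns)
    diag = {
        "query": query.id,
        "selected": list(selected.selected),
        "weights": [float(selected.weights[i]) for i in selected.selected],
        "trace_weight": trace.total_weight,
        "matched_letters": len(trace.pairs),
    }
    return emap, diag


# -- worker plumbing (fork-safe module globals, initialized per process) ----
_POOL_STATE: dict = {}


def _pool_init(ensemble, n_columns, k, weight_floor):
    _POOL_STATE["args"] = (ensemble, n_columns, k, weight_floor)


def _pool_place(query: Sequence):
    ensemble, n_columns, k, weight_floor = _POOL_STATE["args"]
    return place_query(query, ensemble, n_columns, k, weight_floor)


def align_pipeline(backbone: MultipleAlignment, tree: BackboneTree,
                   queries: list[Sequence],
                   config: PipelineConfig | None = None):
    """Run decomposition through merge; returns ``(merged MSA, run report)``.

    The report carries the effective config, per-phase wall times and
    per-query diagnostics; wall times are informational only.
    """
    config = config or PipelineConfig()
    log.info("effective config: %s", asdict(config))
    qids = [q.id for q in queries]
    if len(set(qids)) != len(qids):
        raise AlignmentError("duplicate query ids")
    clash = set(qids) & set(backbone.ids)
    if clash:
        raise AlignmentError(f"query ids collide with backbone: {sorted(clash)}")
    report = {"config": asdict(config), "seed": config.seed, "phases": {},
              "queries": []}
    if not queries:
        log.warning("empty query set; emitting the backbone unchanged")
        return backbone, report

    t0 = time.perf_counter()
    ensemble = build_ensemble(backbone, tree, config.min_subset_size,
                              config.pseudocount, config.gap_threshold)
    report["phases"]["build_ensemble"] = time.perf_counter() - t0
    report["n_hmms"] = len(ensemble)
    n_columns = backbone.n_columns

    t0 = time.perf_counter()
    if config.workers > 1:
        with ProcessPoolExecutor(
                max_workers=config.workers, initializer=_pool_init,
                initargs=(ensemble, n_columns, config.k,
                          config.weight_floor)) as pool:
            results = list(pool.map(_pool_place, queries, chunksize=8))
    else:
        results = [place_query(q, ensemble, n_columns, config.k,
                               config.weight_floor) for q in queries]
    report["phases"]["place_queries"] = time.perf_counter() - t0
    maps: list[ExtendedAlignmentMap] = [r[0] for r in results]
    report["queries"] = [r[1] for r in results]

    t0 = time.perf_counter()
    merged = transitive_merge(backbone, maps, queries)
    report["phases"]["transitive_merge"] = time.perf_counter() - t0
    return merged, report
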