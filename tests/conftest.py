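"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import logsumexp

import ehmmalign as ea
from ehmmalign._kernels import MM, MI, MD, IM, II, ID, DM, DI, DD
from ehmmalign.core_io import GAP
from ehmmalign.merge_output import merged_insertion_columns


# ---------------------------------------------------------------------------
# random generators for small structured inputs
# ---------------------------------------------------------------------------

def random_subalignment(rng: np.random.Generator, n_rows: int, n_cols: int,
                        alphabet: str = "dna",
                        gap_prob: float = 0.25) -> ea.MultipleAlignment:
    """Random gapped alignment guaranteed to have >= 1 match column and no
    all-gap column or all-gap row."""
    letters = ea.ALPHABETS[alphabet]
    while True:
        rows = []
        for _ in range(n_rows):
            cells = [letters[rng.integers(len(letters))]
                     if rng.random() > gap_prob else GAP
                     for _ in range(n_cols)]
            rows.append("".join(cells))
        cols_ok = all(any(r[j] != GAP for r in rows) for j in range(n_cols))
        rows_ok = all(set(r) != {GAP} for r in rows)
        gapfrac = [sum(r[j] == GAP for r in rows) / n_rows
                   for j in range(n_cols)]
        if cols_ok and rows_ok and any(f < 0.5 for f in gapfrac):
            ids = [f"r{i}" for i in range(n_rows)]
            return ea.MultipleAlignment(ids, rows, alphabet)


def random_query(rng: np.random.Generator, length: int,
                 alphabet: str = "dna", qid: str = "q") -> ea.Sequence:
    letters = ea.ALPHABETS[alphabet]
    return ea.Sequence(qid, "".join(letters[rng.integers(len(letters))]
                                    for _ in range(length)), alphabet)


def random_graph(rng: np.random.Generator, m: int, n: int,
                 max_edges: int) -> ea.WeightedAlignmentGraph:
    """Sparse random bipartite graph with strictly positive weights."""
    n_edges = int(rng.integers(0, max_edges + 1))
    edges = {}
    for _ in range(n_edges):
        x = int(rng.integers(0, m))
        y = int(rng.integers(0, n))
        edges[(x, y)] = float(rng.uniform(0.05, 1.0))
    return ea.WeightedAlignmentGraph(m, n, edges)


# ---------------------------------------------------------------------------
# exhaustive path-enumeration oracle for the profile HMM
# ---------------------------------------------------------------------------

def enumerate_path_logprobs(hmm: ea.ProfileHmm, codes: np.ndarray) -> list[float]:
    """Log-probability of every complete state path emitting ``codes``.

    Independent of the DP kernels: walks the begin->end topology recursively.
    Tractable only for tiny profiles (L <= 3) and short queries.
    """
    lme, lie, lt = hmm.log_arrays()
    L = hmm.L
    m = codes.size
    into_m = {"M": MM, "I": IM, "D": DM}
    into_i = {"M": MI, "I": II, "D": DI}
    into_d = {"M": MD, "I": ID, "D": DD}
    out: list[float] = []

    def rec(state: str, j: int, i: int, lp: float) -> None:
        # arrival transitions out of (state, j)
        t = lt[into_m[state], j]
        if np.isfinite(t):
            if j + 1 <= L:
                if i < m and np.isfinite(lme[j + 1, codes[i]]):
                    rec("M", j + 1, i + 1, lp + t + lme[j + 1, codes[i]])
            elif i == m:  # end transition
                out.append(lp + t)
        t = lt[into_i[state], j]
        if np.isfinite(t) and i < m:
            rec("I", j, i + 1, lp + t + lie[codes[i]])
        t = lt[into_d[state], j]
        if np.isfinite(t) and j + 1 <= L:
            rec("D", j + 1, i, lp + t)

    rec("M", 0, 0, 0.0)
    return out


def oracle_forward_viterbi(hmm: ea.ProfileHmm, codes: np.ndarray):
    lps = enumerate_path_logprobs(hmm, codes)
    assert lps, "topology guarantees at least one path"
    return float(logsumexp(lps)), float(max(lps))


# ---------------------------------------------------------------------------
# merge-invariant helpers
# ---------------------------------------------------------------------------

def restrict_to_backbone(merged: ea.MultipleAlignment,
                         backbone_ids: list[str]) -> ea.MultipleAlignment:
    """Backbone rows of a merged MSA with insertion-block columns removed."""
    mask = merged_insertion_columns(merged, backbone_ids)
    rows = ["".join(c for c, ins in zip(merged.row(r), mask) if not ins)
            for r in backbone_ids]
    return ea.MultipleAlignment(list(backbone_ids), rows, merged.alphabet)


def recover_map_from_merged(merged: ea.MultipleAlignment,
                            backbone_ids: list[str], qid: str):
    """Re-derive a query's letter map from the merged MSA (the induction
    property: the output must induce the constructed extended alignments).

    Also asserts the case convention: uppercase only in backbone columns,
    lowercase only in insertion blocks.
    """
    mask = merged_insertion_columns(merged, backbone_ids)
    matched, slot = [], []
    bcol = -1
    for cell, is_ins in zip(merged.row(qid), mask):
        if not is_ins:
            bcol += 1
        if cell == GAP:
            continue
        if is_ins:
            assert cell.islower(), "insertion-block letters must be lowercase"
            matched.append(-1)
            slot.append(bcol + 1)
        else:
            assert cell.isupper(), "backbone-column letters must be uppercase"
            matched.append(bcol)
            slot.append(-1)
    return np.array(matched, dtype=np.int64), np.array(slot, dtype=np.int64)


# ---------------------------------------------------------------------------
# shared small datasets
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_hf_dataset() -> ea.HfDataset:
    """One modest HF dataset reused by merge/pipeline/CLI tests."""
    params = ea.SimulationParams(seed=11, n_taxa=24, root_length=150,
                                 sub_prob=0.08, indel_prob=0.02,
                                 frag_mean=60.0, frag_sd=6.0)
    return ea.make_hf_dataset(params)


@pytest.fixture(scope="session")
def small_hf_run(small_hf_dataset):
    """The pipeline's merged output and report on the small dataset."""
    ds = small_hf_dataset
    tree = ea.read_newick_string(ds.backbone_tree_newick)
    merged, report = ea.align_pipeline(
        ds.backbone_alignment, tree, ds.queries,
        ea.PipelineConfig(k=10, min_subset_size=6))
    return ds, merged, report
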