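# Methods

`ehmmalign` adds query sequences — typically short fragments — into an
existing backbone multiple sequence alignment without altering the backbone's
homology statements. This note documents the model, the algorithmic choices,
the synthetic benchmark generator, and the numerical conventions, in enough
detail to reproduce or modify any of them.

## The placement model

### Ensemble of profile HMMs

A single profile HMM built on a large, divergent backbone is a blunt
instrument: its match-state emissions average over clades that may share
little. The package therefore represents the backbone by an *ensemble* of
profile HMMs built on nested subsets of the backbone, obtained by
hierarchical centroid-edge decomposition of the backbone tree:

1. start with the full leaf set;
2. delete the *centroid edge* — the edge whose removal splits the current
   subtree's leaves most evenly;
3. recurse on both sides while a side has more than `min_subset_size`
   (default 10) leaves.

Every subset at every level is retained, so the ensemble contains the full
set, its halves, their halves, and so on. Each subset's rows are restricted
to their induced sub-alignment (all-gap columns dropped, with a provenance
map back to global backbone columns) and a profile HMM is estimated from it.

Centroid ties are broken deterministically: prefer the smaller max-side leaf
count; among remaining ties, orient each edge so side A holds the overall
lexicographically smallest leaf and prefer the edge whose side B holds the
lexicographically smallest leaf. Edges that split identical leaf partitions
(possible through suppressed degree-2 chains) are interchangeable and yield
identical subsets.

### Profile HMM construction

The topology is plan7-like without flanking random-sequence states: a begin
state (node 0) feeds `{M1, I0, D1}`; each node `j` has match/insert/delete
states with the standard transitions (including I→D and D→I); node `L`'s
three states transition to the end state. This is the simplest topology that
decodes a fragment *through* a sub-profile (paying delete transitions across
unoccupied flanks) while keeping an exhaustive path-enumeration oracle
tractable for testing.

- **Match columns**: a column of the sub-alignment is a match column iff its
  gap fraction is strictly below `gap_threshold` (default 0.5). At least one
  match column is required.
- **Match emissions**: Laplace add-pseudocount counts,
  `(count(r, j) + c) / (nongap(j) + c·|A|)` with pseudocount `c = 1.0` by
  default. Dirichlet-mixture priors (as in HMMER) are a known fidelity gap,
  accepted for simplicity and testability.
- **Insert emissions**: the background distribution.
- **Background**: add-one smoothed residue frequencies of the *full* backbone
  alignment (all ensemble members share it; standalone profile construction
  falls back to the sub-alignment's own frequencies).
- **Transitions**: maximum-likelihood counts of each row's observed path
  through the match/insert/delete topology, with pseudocount `c` added per
  allowed successor.

### Scoring and weighting

For a query of length `r`, each HMM `i` receives a forward bit-score

    b_i = log2( P_forward(query | HMM_i) / P_null(query) )

computed by the log-space forward recursion over all state paths. The null
model emits each residue from the background and applies a geometric length
model with per-residue continue probability `r/(r+1)`; this makes bit-scores
comparable across HMMs of different lengths. (The null cancels when weights
are compared for one query, so its exact form only affects reported score
magnitudes, not placement.)

HMM weights combine the subset size `s_i` (a prior favouring HMMs estimated
from more sequences) with the score odds:

    w_i = s_i · 2^{b_i} / Σ_j s_j · 2^{b_j}

evaluated in log space (log-sum-exp), so bit-scores of ±500 and beyond are
safe. The top `k` HMMs by weight (default `k = 10`, ties to the smaller
index) are kept and their weights renormalized to sum to 1. Renormalizing
rescales every edge of one query's alignment graph by the same constant and
therefore cannot change the optimal trace — it is done so edge weights lie
in (0, 1] and are comparable across queries. An HMM whose weight falls below
`weight_floor` (default 1e-12) is dropped before selection.

### The weighted alignment graph and the exact trace

Each selected HMM's Viterbi decoding of the query yields an extended
alignment: each query letter is either matched to a global backbone column
(via the match-state provenance map) or assigned to an insertion slot. The
`k` decodings vote edges into a bipartite graph between query letters
`q_1..q_m` and backbone columns `b_1..b_n`: edge `(x, y)` carries the summed
weight of the HMMs that align letter `x` to column `y`. Pairs aligned by no
selected HMM are absent — equivalently, their score is −∞, forbidding
unsupported matches.

The consensus placement is the maximum-weight *trace*: a subset of edges in
which both coordinates strictly increase together (a valid pairwise
alignment's match set). With zero gap cost this is solved exactly by the
O(mn) dynamic program

    D[x][y] = max( D[x-1][y], D[x][y-1], D[x-1][y-1] + w(x, y) )

with `D[0][·] = D[·][0] = 0`. The traceback prefers diagonal, then vertical
(skip a query letter), then horizontal moves, making the result
deterministic and of maximal matched-letter count among equal-weight optima.
A dense table is used; at the package's scale (fragments vs. a few thousand
columns) this is never the bottleneck. An exhaustive-enumeration oracle
(`brute_force_trace`, ≤ 20 edges) exists purely for testing.

With `k = 1` the graph is a single HMM's decoding with all weights 1 and the
trace is exactly that decoding — the single-best-HMM strategy — exposed via
`--k 1` for comparison experiments.

### Transitive merge

Each query's trace is converted to a total per-letter map (matched letters
take their trace column; an unmatched letter takes the insertion slot after
the nearest preceding matched letter's column, slot 0 if none). All maps are
merged with the backbone purely in memory: between consecutive backbone
columns, an insertion block as wide as the largest number of letters any
query puts in that slot is emitted; block letters are left-justified and
lowercased; backbone rows carry gaps across blocks. Lowercase letters assert
*no* homology — two queries' letters sharing an insertion block are not
claimed homologous, matching the UPP-family convention — and the evaluation
metrics ignore them. Per-query extended alignments are never materialized as
files.

Row order is backbone rows in input order, then queries in input order.
Left-justification (rather than centering) inside blocks is arbitrary but
deterministic and metric-neutral.

## Evaluation metrics

`spfn_spfp` implements the sum-of-pairs rates: each alignment encodes the
set of unordered pairs of letters (keyed by row id and ungapped letter
index) that share a column; SPFN is the fraction of reference pairs missing
from the estimate, SPFP the fraction of estimated pairs absent from the
reference, and the average error their mean. Rates are computed over the
entire alignment; lowercase cells contribute no pairs; when the reference
covers a row subset, the estimate is restricted to it first. An empty pair
set makes the corresponding rate undefined (an error, not zero). Pairs are
bit-packed into 64-bit integers so set arithmetic runs as sorted-array
intersections.

`average_p_distance` reports the proportion of homologous letter pairs that
differ — the divergence statistic used to situate simulated datasets.

## The synthetic HF generator

`simdata` emulates high-fragmentation (HF) benchmark conditions: sequences
evolve down a random bifurcating tree (uniform random joins, exponential
branch lengths); each branch applies i.i.d. per-site substitutions
(`sub_prob`, uniform target residue) and indel events (`indel_prob` per
site, insertion/deletion 50:50, geometric lengths of mean
`indel_mean_length`). Column identity is tracked exactly through every event
(insertions key new columns by exact rational bisection between their
neighbours), so the emitted alignment *is* the true homology record. Half of
the sequences (`frag_fraction = 0.5`) are then replaced by contiguous
fragments with truncated-normal lengths (mean 250, sd = mean/10, floor 10).
Fragments become the query set; full-length sequences become the backbone,
whose true induced sub-alignment and pruned true tree stand in for an
estimated backbone. The evaluation reference is the true alignment with each
fragment's off-window letters gapped out, so a fragment letter inherits the
true homology of its source letter.

Defaults: 120 taxa, root length 1000, `sub_prob 0.1`, `indel_prob 0.02`,
geometric mean indel length 2 — divergence comparable to published HF
benchmarks (average p-distance roughly 0.5–0.7 depending on size).

What the generator does *not* emulate: GTR-style rate heterogeneity,
protein substitution matrices, long-indel regimes, alignment-estimation
error in the backbone (the backbone here is a true sub-alignment), and
sequencing artifacts in fragments. Tests passing on these fixtures therefore
demonstrate algorithmic correctness and the qualitative ensemble-vs-single
comparison, not absolute accuracy on real data.

## Study sizes used by the tests and the acceptance script

Problem sizes are chosen to keep a full run at desk scale:

- merge-contract sweep: 50 datasets of 120 taxa, root length 200,
  fragments ~80 bp;
- ensemble-vs-single comparison: 20 datasets of 100 taxa (50 backbone / 50
  query), root length 500, fragments ~250 bp, `sub_prob = 0.11` — calibrated
  once so the mean backbone p-distance is ≈ 0.6 (measured 0.629 over eight
  seeds), the high-divergence regime where ensemble placement matters;
- the acceptance script repeats the comparison on 8 datasets and checks the
  exact-trace DP on 1000 random sparse instances and the forward recursion
  against path enumeration on 200 tiny profiles.

At these sizes the k=10 ensemble's mean average error improvement over k=1
is small in absolute terms (~1e-4 to 1e-3) but consistent in sign across
seeds; absolute error levels (~0.5 average error at p-distance 0.63 with a
50-row backbone) are far above published large-backbone results, as expected
for 20× smaller backbones and pseudocount-only profile estimation.

## Numerical conventions and degenerate inputs

- All DP arithmetic is in natural-log space; bit conversions happen only at
  the score interface. Forward/Viterbi kernels are numba-compiled.
- Viterbi ties are broken match > delete > insert; trace-DP traceback ties
  diagonal > vertical > horizontal; top-k ties to the smaller HMM index. All
  outputs are deterministic for fixed inputs and config, independent of the
  worker count (queries are independent and merged in input order).
- Indices are 0-based internally, half-open ranges; FASTA/Newick interfaces
  accept `.` gaps (normalized to `-`), preserve case, and compare residues
  case-insensitively.
- Degenerate inputs: an empty query set returns the backbone unchanged with
  a warning; an all-gap column never becomes a match column; a sub-alignment
  with no match column is skipped with a warning during ensemble
  construction; an empty trace maps every letter to insertion slot 0.

## Known limitations

- Viterbi decoding is used for per-HMM extended alignments; HMMER's default
  decoder optimizes posterior accuracy instead, which can differ on
  ambiguous regions. The decoder is a single seam (`viterbi_extended_alignment`)
  should a posterior decoder be added.
- The geometric length null is a stand-in for HMMER's calibrated null; only
  score magnitudes, not placements or weights, depend on it.
- Letters of distinct queries are never asserted homologous within insertion
  blocks, even when they descend from the same ancestral column; SPFN
  therefore has a floor determined by the match-column coverage of the
  backbone.
- The backbone estimation stage (aligning and tree-building for the backbone
  itself) is out of scope: the backbone alignment and tree are inputs.
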