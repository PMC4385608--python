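# Methods

## Graph model

A multiconcept graph `G = (V, E, W)` holds nodes of three types — `gene`,
`disease`, `go` — in a single symmetric adjacency matrix `A` with integer
confidence weights in [0, 1000] (the STRING convention; scoreless sources
such as morbidmap gene–disease links and GO annotations enter at 1000).
Self-associations are rejected at parse time; duplicate edges keep the
maximum weight, the conservative merge for confidence scores. Nodes are
ordered by (layer, identifier), so matrices, masks and every downstream
output are reproducible across runs and platforms. Storage is sparse
(CSR), proportional to the edge count.

Each layer contributes a binary mask `m_i` over all n nodes; the masks
partition V. A cross-layer block is the full-size masked matrix
`W_ij = diag(m_i)·A·diag(m_j)`. Masking is applied to the **raw**
adjacency and the block is column-normalized afterwards: masking an
already column-stochastic matrix leaves substochastic columns that leak
probability mass, whereas mask-then-normalize keeps every propagation a
proper Markov map. Columns that are empty after masking (and isolated
nodes in general) receive a unit self-loop before normalization — the
walker simply stays put there — which makes the normalized matrix exactly
column-stochastic with no arbitrary mass redistribution. When a
renormalized cross block is used to push one layer's scores onto the
gene layer, those self-loop columns are re-zeroed so that only genuine
cross-layer edges contribute support.

An optional reweighting step rescales each edge by the geometric mean of
its endpoints' principal-eigenvector centrality (`w′ = w·√(c_u·c_v)`,
rescaled to the [0, 1000] integer range). On an undirected graph hub and
authority scores coincide, so a single power iteration (on `A + I`, the
unit shift preventing oscillation on bipartite spectra) suffices. The
step is off by default and excluded from the validation results.

## Random walk with restarts

The walk iterates `p⁽ᵗ⁺¹⁾ = (1 − r)·W·p⁽ᵗ⁾ + r·p⁽⁰⁾` with `p⁽⁰⁾` uniform
over the resolved seed nodes. Because `W` is column-stochastic the map is
an L1 contraction with factor `1 − r`; every iterate is a probability
vector and the fixed point `p = r·(I − (1 − r)W)⁻¹·p⁽⁰⁾` is unique. A
dense linear solve of that fixed point is included as a testing oracle,
capped at n = 2000 so it cannot be mistaken for the production path.

Stopping uses a mask-weighted L1 residual `Σ_i m_i·|p⁽ᵗ⁾_i − p⁽ᵗ⁻¹⁾_i|`.
Absolute values are deliberate: a signed sum of changes can cancel and
declare convergence while individual scores are still moving. With the
all-ones mask the residual is non-increasing after the first step, so the
masked (single-layer) test can only stop earlier, never later.

Defaults: restart `r = 0.75` (the prevailing choice in the RWR
prioritization literature; the walk then contracts by 4× per step and
converges in ~10 iterations at tolerance `ϱ = 1e−6`), iteration cap 1000.
Both are user-settable everywhere; hitting the cap sets a warning flag on
the result rather than raising.

## The recursive method

RecRWR wraps the walk in a seed-refinement loop:

1. Converge the walk on the full normalized multilayer graph from the
   current seed set.
2. Propagate the steady state back onto the gene layer through the sum of
   the renormalized `gene ← disease` and `gene ← go` cross blocks,
   yielding a cross-support score per gene.
3. Select `a_m`, the current **seed** with the smallest steady-state
   probability, and `a_n`, the non-seed gene with the largest
   cross-support (ties broken by smallest node index). Swap them — but
   only if `a_n`'s cross-support strictly exceeds `a_m`'s. A candidate
   that cannot beat the seed it would oust signals that refinement is
   exhausted, and the recursion stops. This acceptance rule is what makes
   an uncorrupted seed set a fixed point: genuine module genes carry
   direct disease-layer support that no outsider matches, so zero
   replacements are accepted and the output equals plain RWR.
4. Terminate when the disease-masked residual between successive
   recursions' steady states falls below `ϱ`, on the no-candidate signal,
   or at the recursion cap (default 30, warning-flagged).

The argmin in step 3 is restricted to the current seed set: replacing a
non-seed would not change the restart vector and the recursion would
stall. The candidate must not already be a seed for the same reason. One
replacement per recursion is the default (configurable) — the smallest
step that keeps the refinement monotone. Swapped-out genes may re-enter
later by default; a flag installs a tabu list. The seed-set size is
invariant throughout. All tie-breaking is total, so identical inputs
yield byte-identical traces.

On a graph with only a gene layer there is no cross block, no
replacement is possible, and the method returns exactly the plain RWR
vector with a trace of length 1 (regression-tested to entrywise
equality).

## Synthetic benchmark

The generator emulates the structure of a real PPI+OMIM+GO compilation at
desk scale. Gene layer: Erdős–Rényi background (default edge probability
0.005, giving average background degree ≈ 5 at the 1000-gene default —
the sparse regime of real curated interactomes) with one planted dense
module per disease (default 10 genes at internal edge probability 0.8).
Disease nodes link to each of their module genes at weight 1000
(morbidmap-style); module-internal gene edges carry weight 900 and
background edges 400, STRING-like high/medium confidences. GO terms form
a random tree (each term attaches to an earlier one) as a DAG stand-in,
and every gene receives 3 random annotations. Everything is reproducible
from one integer seed.

Modules are sampled **disjoint** across diseases (an error if they cannot
be packed). Real diseases share genes; disjointness is a deliberate
simplification that makes the ground-truth ranking unambiguous. Other
features of real data the generator does not emulate: scale (the package
targets hundreds to thousands of genes, not 60,000 nodes), degree
heterogeneity (hubs), GO term depth/specificity, and literature bias in
edge confidences. Passing benchmarks here therefore demonstrates the
methods' relative behaviour under seed noise on recoverable modules, not
absolute performance on genome-scale data.

The validation protocol: for every disease, the seed set starts as its
module and is corrupted in 20% increments — at noise level f,
`round(f·m)` module genes are replaced by uniformly drawn non-module
genes — up to fully random at 100%. With 100 diseases and 6 levels this
is a test space of 600 seed sets. Each method ranks the true disease
among all disease nodes (average rank under ties); ranks are pooled into
a ROC by treating each seed set as one positive and the other D − 1
diseases as negatives, sweeping the rank cutoff k = 0..D; AUC by the
trapezoidal rule (a single set at integer rank r gives the closed form
`(D − r)/(D − 1)`).

Three methods are compared. `rwr_ppi` walks the gene-gene block only and
scores each disease by the weighted sum of its known genes' final scores
(guilt-by-association readout — diseases are absent from that graph, so
some readout convention is required and this is the standard one).
`rwr_all` walks the full multilayer graph and reads disease scores
directly. `recrwr` is the recursive method. At the default desk scale all
three are near-ceiling for noise ≤ 60% — the direct weight-1000
disease–gene links make the clean part of a seed set very informative —
and the separation appears at 80–100% noise, where impostor seeds pull
toward competitor modules. At 100% noise no method carries signal (AUC
near 0.5, typically slightly below since impostors actively support wrong
diseases). A known limitation: at extreme noise (≥ 80%) the recursive
refinement can lock onto an impostor's module and perform slightly worse
than the plain walk; with a majority of genuine seeds it is never worse
and repairs the seed set outright.

## Numerical and reproducibility choices

- All score vectors are validated to sum to 1 within 1e−9; normalized
  columns to 1 within 1e−12.
- Walk convergence at `ϱ = 1e−6` (L1, masked); the test oracle runs at
  1e−10 and agrees with the dense solve to < 1e−8 L∞ across hundreds of
  random graphs.
- Ranks use scipy's average-rank ties; score TSVs order ties by node
  index; argmax/argmin take the smallest index. There is no hidden RNG:
  every stochastic step takes an explicit integer seed recorded in the
  run manifest.
- Benchmark problem sizes default to 50–100 diseases × 10 genes in
  1000 genes with 10 generator replicates — large enough for stable
  medians, small enough to run in seconds.
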