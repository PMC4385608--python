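# recrwr

Disease–gene prioritization by **Recursive Random Walk with Restarts
(RecRWR)** on a multilayer biomedical graph.

High-throughput screens return hundreds of candidate genes per disease
profile. Network propagation narrows them down: a random walk with
restarts (RWR) on a protein–protein interaction (PPI) network scores every
node by its proximity to a set of *seed* genes,

```
p⁽ᵗ⁺¹⁾ = (1 − r)·W·p⁽ᵗ⁾ + r·p⁽⁰⁾
```

where `W` is the column-normalized adjacency matrix, `p⁽⁰⁾` the uniform
distribution over the seeds, and `r` the restart probability. Mixing
annotation layers — OMIM-style disease nodes, Gene Ontology terms — into
the graph should help, but plain RWR actually *degrades* on such
multiconcept graphs, especially when the seed list is noisy.

RecRWR fixes this by refining the seed set between walks. The graph keeps
one binary mask `m_i` per layer, so any cross-layer block is
`W_ij = diag(m_i)·A·diag(m_j)`. After each converged walk, the steady-state
scores of the annotation layers are propagated back onto the gene layer
through these (renormalized) blocks, and the weakest-supported seed
`a_m = argmin_{seeds} p_i` is swapped for the strongest cross-supported
non-seed gene `a_n = argmax W_ij·p_j`. The recursion stops when the
disease-layer scores stabilize, `m₁·|p⁽ᵗ⁾ − p⁽ᵗ⁻¹⁾| < ϱ`, or when no
candidate beats the seed it would replace. Noisy seeds receive little
support from the disease/GO layers, so they are the ones replaced — the
method repairs corrupted seed sets instead of being diluted by them.

The package is for computational biologists who want to rank candidate
diseases (or genes) from an expression profile against a PPI+OMIM+GO
graph, and for methods researchers who want a reproducible harness that
measures robustness of propagation methods to seed noise.

## Worked example

Generate the bundled toy graph (60 genes, 3 planted disease modules,
12 GO terms), corrupt 40% of one disease's seed genes, and run RecRWR:

```
$ recrwr fixtures --out fx
$ recrwr recrwr --graph fx/toy_graph.tsv --seeds noisy_seeds.txt \
      --out scores.tsv --trace trace.json
INFO recursion 1: residual=inf replaced G00005 -> G00039
INFO recursion 2: residual=2.104e-03 replaced G00001 -> G00013
INFO recrwr terminated: no_candidate after 3 recursion(s)

$ grep disease scores.tsv | head -3
MIM:100000      disease 0.0142510869407
MIM:100002      disease 0.000200373327584
MIM:100001      disease 0.000181845378581
```

The trace shows the recursion swapping out two impostor seeds (`G00005`,
`G00001`) for genes of the true module (`G00039`, `G00013`); it stops when
no remaining candidate is better supported than the seeds. The true
disease `MIM:100000` ranks first with a ~70× score margin over the
runners-up. `scores.tsv` holds the full steady-state probability vector
(one row per node, descending); `trace.json` records every recursion's
seed set, swap and disease-layer residual.

The same pipeline is available as a library:

```python
from recrwr import (SyntheticGraphParams, generate_graph, SeedSet, recrwr)

graph, truth = generate_graph(SyntheticGraphParams(rng_seed=7))
result = recrwr(graph, SeedSet(truth["MIM:100000"]))
print(result.trace.termination, result.scores.values.sum())  # sums to 1
```

Other subcommands: `recrwr build` assembles a graph from edge lists
(generic TSV, STRING-links, morbidmap and GAF dialects), `recrwr walk`
runs plain RWR, and `recrwr benchmark` runs the full synthetic
noise-robustness comparison (`rwr_ppi`, `rwr_all`, `recrwr` at noise
levels 0–100%), writing `auc_table.csv`, `ranks.csv` and
`roc_points.csv`. Every command writes a JSON manifest (config, input
digests, seeds) so deterministic runs are byte-for-byte reproducible.

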