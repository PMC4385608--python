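"""Synthetic validation harness for seed-noise robustness.

The real evaluation setting — a genome-scale PPI network annotated with
OMIM diseases and GO terms — is emulated here at desk scale: an
Erdős–Rényi gene background with one planted dense module per disease,
a disease node linked (weight 1000) to each of its module genes, and GO
terms forming a random tree with random gene annotations.  Ground truth
is the disease→module map, so ranking quality is directly measurable.

The protocol corrupts each disease's seed set in 20% increments (0%
through 100% of module genes replaced by random non-module genes), runs a
prioritization method from each corrupted set, records the rank of the
true disease among all diseases, and pools the ranks into ROC curves and
AUCs per noise level.  Three methods are compared: RWR on the gene layer
only, RWR on the whole multilayer graph, and RecRWR.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .graph import (
    AssociationRecord,
    MulticonceptGraph,
    build_graph,
    column_normalize,
    extract_block,
    normalize_columns,
)
from .recursive import (
    DISEASE_LAYER,
    GENE_LAYER,
    RecursionConfig,
    prepare_operators,
    recrwr,
)
from .walk import ScoreVector, SeedSet, WalkConfig, make_seed_vector, rwr_converge

NOISE_LEVELS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
METHODS = ("rwr_ppi", "rwr_all", "recrwr")

#: STRING-like confidence constants for generated gene-gene edges.
MODULE_EDGE_WEIGHT = 900
BACKGROUND_EDGE_WEIGHT = 400
CROSS_LAYER_WEIGHT = 1000


@dataclass(frozen=True)
class SyntheticGraphParams:
    """Knobs of the synthetic multilayer graph.

    Defaults give a desk-scale graph (1000 genes, 100 diseases of 10 genes
    each, 200 GO terms) whose modules are dense (80% internal edge
    probability) against a sparse background chosen so the average
    background degree is about 5, the sparse regime of real curated
    interactomes.
    """

    n_genes: int = 1000
    n_diseases: int = 100
    genes_per_disease: int = 10
    n_go_terms: int = 200
    background_edge_prob: float = 0.005
    within_module_edge_prob: float = 0.8
    go_annotations_per_gene: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.genes_per_disease < 10:
            raise ValueError(
                f"genes_per_disease must be >= 10, got {self.genes_per_disease}"
            )
        if not (self.within_module_edge_prob > self.background_edge_prob):
            raise ValueError(
                "within_module_edge_prob must exceed background_edge_prob "
                f"({self.within_module_edge_prob} <= {self.background_edge_prob})"
            )
        if self.n_diseases * self.genes_per_disease > self.n_genes:
            raise ValueError(
                f"cannot plant {self.n_diseases} disjoint modules of "
                f"{self.genes_per_disease} genes in {self.n_genes} genes"
            )
        if self.go_annotations_per_gene > self.n_go_terms:
            raise ValueError("more annotations per gene than GO terms")


@dataclass(frozen=True)
class NoisySeedSet:
    """A disease's seed list with a known fraction of random impostors."""

    disease_id: str
    noise_fraction: float
    seeds: tuple[str, ...]
    rng_seed: int


@dataclass
class BenchmarkResult:
    """Per (method, noise level): true-disease ranks, ROC points, AUC."""

    ranks: dict[tuple[str, float], list[float]] = field(default_factory=dict)
    roc: dict[tuple[str, float], tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    auc: dict[tuple[str, float], float] = field(default_factory=dict)
    n_diseases: int = 0

    def auc_table(self) -> list[dict[str, object]]:
        """Rows of method x noise AUCs, one dict per method."""
        methods = sorted({m for m, _ in self.auc})
        levels = sorted({l for _, l in self.auc})
        rows = []
        for m in methods:
            row: dict[str, object] = {"method": m}
            for l in levels:
                row[f"noise_{int(round(l * 100))}"] = self.auc[(m, l)]
            rows.append(row)
        return rows


# ---------------------------------------------------------------------------
# Graph generation
# ---------------------------------------------------------------------------

def _gene_id(i: int) -> str:
    return f"G{i:05d}"


def _disease_id(i: int) -> str:
    return f"MIM:{100000 + i}"


def _go_id(i: int) -> str:
    return f"GO:{i:07d}"


def generate_graph(
    params: SyntheticGraphParams,
) -> tuple[MulticonceptGraph, dict[str, tuple[str, ...]]]:
    """Generate the three-layer graph and its disease→module ground truth.

    Fully reproducible from ``params.rng_seed``.  Modules are sampled
    disjoint across diseases so each disease has an unambiguous gene set;
    every disease node therefore has degree ``genes_per_disease`` (>= 10).
    GO terms form a random tree (each term attaches to an earlier one) and
    every gene receives ``go_annotations_per_gene`` distinct annotations.
    """
    rng = np.random.default_rng(params.rng_seed)
    ng, nd, m = params.n_genes, params.n_diseases, params.genes_per_disease

    gene_ids = [_gene_id(i) for i in range(ng)]

    # background ER edges over the gene layer
    iu, ju = np.triu_indices(ng, k=1)
    keep = rng.random(iu.size) < params.background_edge_prob
    gene_edges: dict[tuple[int, int], int] = {
        (int(a), int(b)): BACKGROUND_EDGE_WEIGHT
        for a, b in zip(iu[keep], ju[keep])
    }

    # disjoint planted modules, densified
    perm = rng.permutation(ng)
    truth: dict[str, tuple[str, ...]] = {}
    disease_edges: list[AssociationRecord] = []
    for d in range(nd):
        module = np.sort(perm[d * m : (d + 1) * m])
        did = _disease_id(d)
        truth[did] = tuple(gene_ids[g] for g in module)
        for g in module:
            disease_edges.append(
                AssociationRecord(gene_ids[g], did, CROSS_LAYER_WEIGHT)
            )
        for a_i in range(m):
            for b_i in range(a_i + 1, m):
                if rng.random() < params.within_module_edge_prob:
                    key = (int(module[a_i]), int(module[b_i]))
                    gene_edges[key] = max(gene_edges.get(key, 0), MODULE_EDGE_WEIGHT)

    gene_records = [
        AssociationRecord(gene_ids[a], gene_ids[b], w)
        for (a, b), w in sorted(gene_edges.items())
    ]

    # GO layer: random tree over terms + per-gene annotations
    go_records = [
        AssociationRecord(_go_id(child), _go_id(int(rng.integers(0, child))), CROSS_LAYER_WEIGHT)
        for child in range(1, params.n_go_terms)
    ]
    annot_records = []
    for g in range(ng):
        terms = rng.choice(params.n_go_terms, size=params.go_annotations_per_gene, replace=False)
        for t in np.sort(terms):
            annot_records.append(
                AssociationRecord(gene_ids[g], _go_id(int(t)), CROSS_LAYER_WEIGHT)
            )

    graph = build_graph(
        {
            (GENE_LAYER, GENE_LAYER): gene_records,
            (GENE_LAYER, DISEASE_LAYER): disease_edges,
            ("go", "go"): go_records,
            (GENE_LAYER, "go"): annot_records,
        }
    )
    return graph, truth


# ---------------------------------------------------------------------------
# Seed-set corruption
# ---------------------------------------------------------------------------

def make_noisy_seed_sets(
    truth: Mapping[str, Sequence[str]],
    noise_levels: Sequence[float],
    rng_seed: int,
    gene_ids: Sequence[str],
) -> list[NoisySeedSet]:
    """Corrupt every disease's module at every noise level.

    At level f, ``round(f * |module|)`` module genes are replaced by
    uniformly sampled non-module genes (without replacement), so the seed
    list keeps its size while being progressively randomized; level 1.0
    shares no gene with the module.  Yields ``len(noise_levels) x
    len(truth)`` seed sets.
    """
    allowed = set(NOISE_LEVELS)
    for lvl in noise_levels:
        if not any(abs(lvl - a) < 1e-12 for a in allowed):
            raise ValueError(f"noise level {lvl} not in {sorted(allowed)}")
    rng = np.random.default_rng(rng_seed)
    gene_ids = list(gene_ids)
    out: list[NoisySeedSet] = []
    for lvl in noise_levels:
        for did in sorted(truth):
            module = list(truth[did])
            n_replace = int(round(lvl * len(module)))
            pool = [g for g in gene_ids if g not in set(module)]
            if n_replace > len(pool):
                raise ValueError(
                    f"cannot sample {n_replace} non-module genes for {did}: "
                    f"only {len(pool)} available"
                )
            drop = rng.choice(len(module), size=n_replace, replace=False)
            impostors = rng.choice(len(pool), size=n_replace, replace=False)
            seeds = list(module)
            for k, pos in enumerate(np.sort(drop)):
                seeds[pos] = pool[int(impostors[k])]
            out.append(NoisySeedSet(did, float(lvl), tuple(seeds), rng_seed))
    return out


# ---------------------------------------------------------------------------
# Ranking and ROC
# ---------------------------------------------------------------------------

def rank_true_disease(
    scores: ScoreVector | np.ndarray,
    graph: MulticonceptGraph,
    true_disease: str,
) -> float:
    """1-based rank of the true disease among all disease nodes by score.

    Ties receive their average rank, so a fully tied field of D diseases
    puts every disease at rank (D + 1) / 2.
    """
    if true_disease not in graph or graph.node_layers[graph.index_of(true_disease)] != DISEASE_LAYER:
        raise KeyError(f"{true_disease!r} is not a disease node of the graph")
    values = scores.values if isinstance(scores, ScoreVector) else np.asarray(scores)
    d_idx = graph.layer_indices(DISEASE_LAYER)
    ranks = rankdata(-values[d_idx], method="average")
    pos = int(np.searchsorted(d_idx, graph.index_of(true_disease)))
    return float(ranks[pos])


def roc_and_auc(
    ranks: Sequence[float], n_diseases: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pooled ROC over seed sets, one positive and D-1 negatives per set.

    Sweeping the cutoff k = 0..D: a seed set contributes a true positive
    when its true disease ranks within the top k, and ``k - hit`` false
    positives (the other diseases occupying its top k).  TPR and FPR are
    pooled over all sets; AUC by the trapezoidal rule.  Single set with
    integer rank r reduces to the closed form AUC = (D - r) / (D - 1).
    """
    ranks = np.asarray(ranks, dtype=np.float64)
    if ranks.size == 0:
        raise ValueError("empty rank list")
    if (ranks < 1).any() or (ranks > n_diseases).any():
        raise ValueError(f"ranks must lie in [1, {n_diseases}]")
    S = ranks.size
    ks = np.arange(0, n_diseases + 1, dtype=np.float64)
    hits = (ranks[None, :] <= ks[:, None]).sum(axis=1).astype(np.float64)
    tpr = hits / S
    fpr = (ks * S - hits) / (S * (n_diseases - 1))
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


# ---------------------------------------------------------------------------
# Method runners
# ---------------------------------------------------------------------------

def _disease_scores_rwr_ppi(graph, W_gene, disease_from_gene, seeds, walk_cfg):
    """Walk the gene layer only, then read diseases out by guilt-by-association.

    Diseases are absent from the PPI-only graph, so each disease is scored
    by the weighted sum of final gene scores over its known gene links
    (the raw disease<-gene cross block applied to the steady state).
    """
    p0 = make_seed_vector(seeds, graph)
    res = rwr_converge(W_gene, p0, walk_cfg)
    return np.asarray(disease_from_gene @ res.scores.values).ravel()


def run_benchmark(
    params: SyntheticGraphParams,
    methods: Sequence[str] = METHODS,
    config: RecursionConfig | None = None,
    noise_levels: Sequence[float] = NOISE_LEVELS,
    seed_rng_seed: int | None = None,
) -> BenchmarkResult:
    """Full protocol: generate, corrupt, rank, pool into ROC/AUC.

    ``seed_rng_seed`` controls seed-set corruption (defaults to
    ``params.rng_seed + 1`` so graph and noise draws are decoupled).
    Deterministic end to end for fixed seeds.
    """
    for meth in methods:
        if meth not in METHODS:
            raise ValueError(f"unknown method {meth!r}; expected subset of {METHODS}")
    if config is None:
        config = RecursionConfig()
    walk_cfg = config.walk

    graph, truth = generate_graph(params)
    gene_ids = [_gene_id(i) for i in range(params.n_genes)]
    noise_seed = params.rng_seed + 1 if seed_rng_seed is None else seed_rng_seed
    seed_sets = make_noisy_seed_sets(truth, noise_levels, noise_seed, gene_ids)

    ops = prepare_operators(graph) if ("rwr_all" in methods or "recrwr" in methods) else None
    if "rwr_ppi" in methods:
        W_gene = normalize_columns(extract_block(graph, GENE_LAYER, GENE_LAYER))
        disease_from_gene = extract_block(graph, DISEASE_LAYER, GENE_LAYER).astype(np.float64)
    result = BenchmarkResult(n_diseases=params.n_diseases)

    ranks: dict[tuple[str, float], list[float]] = {
        (m, float(l)): [] for m in methods for l in noise_levels
    }
    for nss in seed_sets:
        seeds = SeedSet(nss.seeds)
        for meth in methods:
            if meth == "rwr_ppi":
                scores = _disease_scores_rwr_ppi(
                    graph, W_gene, disease_from_gene, seeds, walk_cfg
                )
            elif meth == "rwr_all":
                p0 = make_seed_vector(seeds, graph)
                scores = rwr_converge(ops.W_full, p0, walk_cfg).scores
            else:
                scores = recrwr(graph, seeds, config, operators=ops).scores
            ranks[(meth, nss.noise_fraction)].append(
                rank_true_disease(scores, graph, nss.disease_id)
            )

    for key, rk in ranks.items():
        fpr, tpr, auc = roc_and_auc(rk, params.n_diseases)
        result.ranks[key] = rk
        result.roc[key] = (fpr, tpr)
        result.auc[key] = auc
    return result


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def write_benchmark_outputs(result: BenchmarkResult, out_dir: str | Path) -> None:
    """Write auc_table.csv, ranks.csv and roc_points.csv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = result.auc_table()
    if rows:
        with open(out / "auc_table.csv", "wt", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
            writer.writeheader()
            for row in rows:
                writer.writerow(
                    {k: (f"{v:.6f}" if isinstance(v, float) else v) for k, v in row.items()}
                )
    with open(out / "ranks.csv", "wt", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["method", "noise", "set_index", "rank"])
        for (meth, lvl) in sorted(result.ranks):
            for idx, r in enumerate(result.ranks[(meth, lvl)]):
                writer.writerow([meth, f"{lvl:.1f}", idx, f"{r:.1f}"])
    with open(out / "roc_points.csv", "wt", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["method", "noise", "fpr", "tpr"])
        for (meth, lvl) in sorted(result.roc):
            fpr, tpr = result.roc[(meth, lvl)]
            for x, y in zip(fpr, tpr):
                writer.writerow([meth, f"{lvl:.1f}", f"{x:.6f}", f"{y:.6f}"])
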