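"""Recursive Random Walk with Restarts (RecRWR).

Plain RWR treats every node of a multilayer graph alike, which dilutes the
signal when annotation layers (diseases, GO terms) are mixed into a PPI
network.  RecRWR instead refines the *seed set* between walks: after each
converged walk it propagates the steady-state scores of the non-gene layers
back onto the gene layer through the masked cross blocks, then swaps the
weakest-supported seed gene for the strongest cross-supported non-seed
gene.  The recursion stops when the disease-layer scores stabilize between
successive walks (masked L1 residual below the walk tolerance), when no
beneficial replacement exists, or at the recursion cap.

Each recursion is recorded in a :class:`RecursionTrace` — seed set used,
the swap performed, the disease-masked residual, and the inner walk's
iteration count — so a run is fully auditable and byte-reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.sparse as sp

from .graph import (
    ColumnStochasticMatrix,
    LayerMask,
    MulticonceptGraph,
    column_normalize,
    extract_block,
    normalize_columns,
)
from .walk import ScoreVector, SeedSet, WalkConfig, make_seed_vector, masked_l1, rwr_converge

logger = logging.getLogger(__name__)

GENE_LAYER = "gene"
DISEASE_LAYER = "disease"


@dataclass(frozen=True)
class RecursionConfig:
    """Outer-loop parameters wrapped around a :class:`WalkConfig`.

    max_recursions
        Cap on seed-refinement rounds (each round runs one full walk).
    replacements_per_recursion
        Seed swaps attempted per round; 1 is the smallest refinement step.
    allow_reentry
        Whether a swapped-out gene may be selected again later.
    """

    walk: WalkConfig = field(default_factory=WalkConfig)
    max_recursions: int = 30
    replacements_per_recursion: int = 1
    allow_reentry: bool = True

    def __post_init__(self) -> None:
        if self.max_recursions < 1:
            raise ValueError(f"max_recursions must be >= 1, got {self.max_recursions}")
        if self.replacements_per_recursion < 1:
            raise ValueError(
                f"replacements_per_recursion must be >= 1, got {self.replacements_per_recursion}"
            )


@dataclass(frozen=True)
class RecursionRecord:
    """One recursion's bookkeeping."""

    recursion: int
    seed_ids: tuple[str, ...]
    removed: str | None
    added: str | None
    disease_residual: float
    inner_iterations: int

    def to_dict(self) -> dict[str, Any]:
        return {
            "recursion": self.recursion,
            "seed_ids": list(self.seed_ids),
            "removed": self.removed,
            "added": self.added,
            "disease_residual": (
                None if np.isinf(self.disease_residual) else self.disease_residual
            ),
            "inner_iterations": self.inner_iterations,
        }


@dataclass
class RecursionTrace:
    """Ordered per-recursion records plus the termination verdict."""

    records: list[RecursionRecord] = field(default_factory=list)
    termination: str = "max_recursions"
    converged: bool = False

    def __len__(self) -> int:
        return len(self.records)

    def to_json_obj(self) -> dict[str, Any]:
        return {
            "termination": self.termination,
            "converged": self.converged,
            "records": [r.to_dict() for r in self.records],
        }


@dataclass(frozen=True)
class RecRWRResult:
    scores: ScoreVector
    trace: RecursionTrace


def masked_residual(
    p_t: ScoreVector, p_prev: ScoreVector, disease_mask: LayerMask | np.ndarray
) -> float:
    """Disease-layer L1 change ``sum_i m_i |p_t[i] - p_prev[i]|``.

    Absolute values are taken entrywise: a signed sum could cancel opposite
    score shifts and falsely declare stability.
    """
    if len(p_t) != len(p_prev):
        raise ValueError("score vectors differ in length")
    return masked_l1(p_t.values - p_prev.values, disease_mask)


def select_replacement(
    p_current: ScoreVector,
    cross_block: sp.spmatrix,
    p_other: ScoreVector,
    seeds: SeedSet,
    graph: MulticonceptGraph,
    *,
    forbidden: frozenset[str] = frozenset(),
) -> tuple[int, int] | None:
    """Pick the seed to drop and the gene to adopt.

    The dropped seed ``a_m`` is the current seed with the smallest
    steady-state probability; the candidate ``a_n`` maximizes the
    cross-propagated support ``cross_block @ p_other`` over gene-layer
    nodes not already in the seed set (ties broken by smallest node
    index).  Returns ``None`` when every candidate's support is zero.
    """
    seed_idx = sorted(graph.index_of(s) for s in seeds if s in graph)
    if not seed_idx:
        raise ValueError("no seed resolves to a graph node")
    seed_arr = np.asarray(seed_idx)
    a_m = int(seed_arr[np.argmin(p_current.values[seed_arr])])

    support = np.asarray(cross_block @ p_other.values).ravel()
    candidate_mask = graph.masks[GENE_LAYER].bits.astype(bool).copy()
    candidate_mask[seed_arr] = False
    if forbidden:
        for nid in forbidden:
            if nid in graph:
                candidate_mask[graph.index_of(nid)] = False
    scores = np.where(candidate_mask, support, -np.inf)
    if not candidate_mask.any() or np.nanmax(scores) <= 0:
        return None
    a_n = int(np.argmax(scores))  # argmax takes the first maximum: smallest index
    return a_m, a_n


@dataclass(frozen=True)
class _Operators:
    """Precomputed matrices shared across many walks on one graph."""

    W_full: ColumnStochasticMatrix
    cross_to_gene: sp.csr_matrix | None  # sum of normalized gene<-j blocks
    disease_mask: np.ndarray
    other_layers: tuple[str, ...]


def prepare_operators(graph: MulticonceptGraph) -> _Operators:
    """Normalize the full graph and the gene<-other-layer cross blocks once.

    Each cross block is column-normalized after masking, so propagating a
    layer's steady state back to genes is a proper stochastic map.
    """
    W_full = column_normalize(graph)
    others = tuple(l for l in graph.layers if l != GENE_LAYER)
    cross = None
    for layer in others:
        block = normalize_columns(extract_block(graph, GENE_LAYER, layer)).matrix
        # restrict to the layer's columns: normalize_columns put self-loops
        # on the zeroed columns, which must not contribute support
        cols = graph.masks[layer].bits.astype(np.float64)
        block = (block @ sp.diags(cols)).tocsr()
        cross = block if cross is None else cross + block
    if DISEASE_LAYER in graph.masks:
        dmask = graph.masks[DISEASE_LAYER].bits.astype(np.float64)
    else:
        dmask = np.zeros(graph.n_nodes)
    return _Operators(W_full, None if cross is None else cross.tocsr(), dmask, others)


def recrwr(
    graph: MulticonceptGraph,
    seeds: SeedSet,
    config: RecursionConfig | None = None,
    *,
    operators: _Operators | None = None,
) -> RecRWRResult:
    """Run the full recursive walk from an initial gene seed set.

    Per recursion: (1) converge a restart walk on the whole normalized
    graph from the current seeds; (2) propagate every non-gene layer's
    steady-state scores back to genes through its normalized cross block;
    (3) swap the weakest seed for the best-supported non-seed gene, but
    only when the candidate's cross support strictly exceeds that of the
    seed it replaces — otherwise the refinement has nothing left to offer
    and the recursion stops.  Termination also occurs when the
    disease-masked residual between successive steady states drops below
    the walk tolerance, or at ``max_recursions`` (with a warning flag).

    On a single-layer graph no cross block exists, so the result equals
    plain RWR and the trace has length 1.
    """
    if config is None:
        config = RecursionConfig()
    ops = operators if operators is not None else prepare_operators(graph)

    current = SeedSet([s for s in seeds if s in graph])
    if len(current) == 0:
        raise ValueError("no seed identifier resolves to a graph node")
    seed_size = len(current)

    trace = RecursionTrace()
    removed_ever: set[str] = set()
    p_prev: ScoreVector | None = None
    result_scores: ScoreVector | None = None

    for rec in range(1, config.max_recursions + 1):
        p0 = make_seed_vector(current, graph)
        walk_res = rwr_converge(ops.W_full, p0, config.walk)
        p = walk_res.scores
        result_scores = p

        residual = (
            masked_residual(p, p_prev, ops.disease_mask)
            if p_prev is not None
            else float("inf")
        )
        p_prev = p

        if rec > 1 and residual < config.walk.tolerance:
            trace.records.append(
                RecursionRecord(rec, current.node_ids, None, None, residual, walk_res.iterations)
            )
            trace.termination = "disease_scores_stable"
            trace.converged = True
            break

        if ops.cross_to_gene is None:
            trace.records.append(
                RecursionRecord(rec, current.node_ids, None, None, residual, walk_res.iterations)
            )
            trace.termination = "single_layer"
            trace.converged = True
            break

        support = np.asarray(ops.cross_to_gene @ p.values).ravel()
        working = list(current.node_ids)
        swaps: list[tuple[str, str]] = []
        for _ in range(config.replacements_per_recursion):
            forbidden = frozenset() if config.allow_reentry else frozenset(removed_ever)
            pick = select_replacement(
                p, ops.cross_to_gene, p, SeedSet(working), graph, forbidden=forbidden
            )
            if pick is None:
                break
            a_m, a_n = pick
            if support[a_n] <= support[a_m]:
                break  # candidate no better supported than the seed it would oust
            out_id, in_id = graph.node_ids[a_m], graph.node_ids[a_n]
            working[working.index(out_id)] = in_id
            removed_ever.add(out_id)
            swaps.append((out_id, in_id))

        if not swaps:
            trace.records.append(
                RecursionRecord(rec, current.node_ids, None, None, residual, walk_res.iterations)
            )
            trace.termination = "no_candidate"
            trace.converged = True
            break

        for out_id, in_id in swaps:
            logger.info(
                "recursion %d: residual=%.3e replaced %s -> %s", rec, residual, out_id, in_id
            )
        trace.records.append(
            RecursionRecord(
                rec,
                current.node_ids,
                ";".join(o for o, _ in swaps),
                ";".join(i for _, i in swaps),
                residual,
                walk_res.iterations,
            )
        )
        current = SeedSet(working)
        assert len(current) == seed_size, "seed-set size must be invariant"
    else:
        trace.termination = "max_recursions"
        trace.converged = False
        warnings.warn(
            f"RecRWR hit the recursion cap ({config.max_recursions}) before the "
            "disease scores stabilized",
            RuntimeWarning,
        )

    assert result_scores is not None
    return RecRWRResult(result_scores, trace)
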