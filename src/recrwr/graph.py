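"""Multilayer ("multiconcept") graph model.

A multiconcept graph holds typed nodes from up to three layers — ``gene``
(protein–protein interactions), ``disease`` (phenotype entries linked to
their known genes) and ``go`` (ontology terms annotating genes, plus the
term hierarchy) — in one symmetric weighted adjacency matrix.  Edge weights
are integer confidence scores in [0, 1000], the convention of STRING-style
interaction databases.  Binary layer masks select the rows/columns of one
layer, so any cross-layer block ``W_ij = diag(m_i) A diag(m_j)`` is a
full-size masked matrix rather than a compacted one.

Parsing supports a generic 3-column TSV plus dialect readers for
STRING-style protein links, OMIM-morbidmap-style gene–disease pairs,
GAF 2.x gene–GO annotations and 2-column GO ``is_a`` pair files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

#: Recognised layer names, in their canonical (sorted) order.
LAYERS = ("disease", "gene", "go")

#: Maximum confidence score an association may carry.
MAX_WEIGHT = 1000

DIALECTS = ("generic-tsv", "string-links", "morbidmap", "gaf", "go-isa")


class ParseError(ValueError):
    """A malformed association line; the message names the line number."""


class GraphBuildError(ValueError):
    """Inconsistent input to graph construction (e.g. cross-layer id clash)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationRecord:
    """One weighted association between two term identifiers.

    Parameters
    ----------
    source_id, target_id
        Opaque term identifiers.  Self-associations are rejected.
    weight
        Integer confidence score in ``[0, 1000]``.
    """

    source_id: str
    target_id: str
    weight: int

    def __post_init__(self) -> None:
        if self.source_id == self.target_id:
            raise ValueError(
                f"self-association not allowed: {self.source_id!r}"
            )
        if not (0 <= int(self.weight) <= MAX_WEIGHT):
            raise ValueError(
                f"weight {self.weight} outside [0, {MAX_WEIGHT}] for "
                f"({self.source_id}, {self.target_id})"
            )


@dataclass(frozen=True)
class LayerMask:
    """Binary indicator over all n nodes for one layer's membership."""

    layer_name: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        if self.layer_name not in LAYERS:
            raise ValueError(f"unknown layer {self.layer_name!r}; expected one of {LAYERS}")
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=np.int8))

    def __len__(self) -> int:
        return int(self.bits.shape[0])


@dataclass
class MulticonceptGraph:
    """Typed node set with a symmetric integer-weighted adjacency matrix.

    Attributes
    ----------
    node_ids
        Node identifiers in deterministic order (sorted by layer, then id).
    node_layers
        Layer label per node, aligned with ``node_ids``.
    adjacency
        ``n x n`` symmetric CSR matrix of integer weights, zero diagonal.
    masks
        One :class:`LayerMask` per layer present; the masks partition V.
    """

    node_ids: list[str]
    node_layers: list[str]
    adjacency: sp.csr_matrix
    masks: dict[str, LayerMask]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {nid: i for i, nid in enumerate(self.node_ids)}
        if len(self._index) != len(self.node_ids):
            raise GraphBuildError("duplicate node identifiers")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def layers(self) -> tuple[str, ...]:
        return tuple(sorted(self.masks))

    def index_of(self, node_id: str) -> int:
        return self._index[node_id]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def layer_indices(self, layer: str) -> np.ndarray:
        """Indices of the nodes belonging to ``layer``."""
        return np.flatnonzero(self.masks[layer].bits)


@dataclass(frozen=True)
class ColumnStochasticMatrix:
    """A nonnegative matrix whose every column sums to 1 (within 1e-12)."""

    matrix: sp.csr_matrix

    def __post_init__(self) -> None:
        sums = np.asarray(self.matrix.sum(axis=0)).ravel()
        if not np.allclose(sums, 1.0, atol=1e-12):
            bad = np.flatnonzero(~np.isclose(sums, 1.0, atol=1e-12))
            raise ValueError(f"columns {bad[:5].tolist()} do not sum to 1")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _parse_weight(token: str, lineno: int) -> int:
    try:
        w = int(token)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer weight {token!r}") from exc
    if not (0 <= w <= MAX_WEIGHT):
        raise ParseError(f"line {lineno}: weight {w} outside [0, {MAX_WEIGHT}]")
    return w


def _record(a: str, b: str, w: int, lineno: int) -> AssociationRecord:
    try:
        return AssociationRecord(a, b, w)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc


def parse_association_table(
    path: str | Path,
    dialect: str = "generic-tsv",
    *,
    strip_species_prefix: bool = False,
    score_threshold: int | None = None,
) -> list[AssociationRecord]:
    """Read an association file into :class:`AssociationRecord` tuples.

    Dialects
    --------
    ``generic-tsv``
        Three tab-separated columns (source, target, integer score);
        ``#`` comment lines allowed.
    ``string-links``
        Whitespace-separated ``protein1 protein2 combined_score`` with an
        optional header line.  ``strip_species_prefix`` removes a leading
        ``taxid.`` from identifiers; ``score_threshold`` drops rows with a
        lower combined score (none applied by default).
    ``morbidmap``
        Two tab-separated columns, gene symbol and MIM number; weight
        defaults to 1000 and the disease id gains a ``MIM:`` prefix so the
        two namespaces cannot collide.
    ``gaf``
        GAF 2.x annotation lines (``!`` comments); columns 2 and 5 give the
        gene and GO ids, weight defaults to 1000.
    ``go-isa``
        Two tab-separated GO ids (child, parent ``is_a`` pairs), weight 1000.

    Empty files yield an empty list.  Malformed lines and out-of-range
    weights raise :class:`ParseError` naming the line number.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unsupported dialect {dialect!r}; expected one of {DIALECTS}")
    records: list[AssociationRecord] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if dialect == "gaf":
                if line.startswith("!"):
                    continue
                cols = line.split("\t")
                if len(cols) < 5:
                    raise ParseError(f"line {lineno}: GAF line has {len(cols)} columns, need >= 5")
                records.append(_record(cols[1], cols[4], MAX_WEIGHT, lineno))
                continue
            if line.startswith("#"):
                continue
            if dialect == "generic-tsv":
                cols = line.split("\t")
                if len(cols) != 3:
                    raise ParseError(f"line {lineno}: expected 3 tab-separated columns, got {len(cols)}")
                records.append(_record(cols[0], cols[1], _parse_weight(cols[2], lineno), lineno))
            elif dialect == "string-links":
                cols = line.split()
                if len(cols) < 3:
                    raise ParseError(f"line {lineno}: expected 3 whitespace-separated columns")
                a, b, score = cols[0], cols[1], cols[2]
                if lineno == 1 and not score.lstrip("-").isdigit():
                    continue  # header line
                w = _parse_weight(score, lineno)
                if score_threshold is not None and w < score_threshold:
                    continue
                if strip_species_prefix:
                    a = a.split(".", 1)[-1]
                    b = b.split(".", 1)[-1]
                records.append(_record(a, b, w, lineno))
            elif dialect == "morbidmap":
                cols = line.split("\t")
                if len(cols) < 2:
                    raise ParseError(f"line {lineno}: expected 2 tab-separated columns")
                gene, mim = cols[0], cols[1]
                if not mim.startswith("MIM:"):
                    mim = f"MIM:{mim}"
                records.append(_record(gene, mim, MAX_WEIGHT, lineno))
            else:  # go-isa
                cols = line.split("\t")
                if len(cols) < 2:
                    raise ParseError(f"line {lineno}: expected 2 tab-separated columns")
                records.append(_record(cols[0], cols[1], MAX_WEIGHT, lineno))
    return records


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def build_graph(
    records_by_layer_pair: Mapping[tuple[str, str], Sequence[AssociationRecord]],
) -> MulticonceptGraph:
    """Assemble a :class:`MulticonceptGraph` from per-layer-pair records.

    Node order is deterministic: sorted by layer name, then lexicographically
    by identifier.  Duplicate edges keep the maximum weight (confidence
    scores — the conservative merge).  An identifier appearing under two
    different layers raises :class:`GraphBuildError`.
    """
    if not records_by_layer_pair or not any(records_by_layer_pair.values()):
        raise GraphBuildError("no association records supplied")

    node_layer: dict[str, str] = {}
    conflicts: set[str] = set()
    for (la, lb), recs in records_by_layer_pair.items():
        for layer in (la, lb):
            if layer not in LAYERS:
                raise GraphBuildError(f"unknown layer {layer!r}; expected one of {LAYERS}")
        for rec in recs:
            for nid, layer in ((rec.source_id, la), (rec.target_id, lb)):
                prev = node_layer.setdefault(nid, layer)
                if prev != layer:
                    conflicts.add(nid)
    if conflicts:
        raise GraphBuildError(
            "identifiers assigned to more than one layer: "
            + ", ".join(sorted(conflicts))
        )

    node_ids = sorted(node_layer, key=lambda nid: (node_layer[nid], nid))
    index = {nid: i for i, nid in enumerate(node_ids)}
    n = len(node_ids)

    best: dict[tuple[int, int], int] = {}
    for (la, lb), recs in records_by_layer_pair.items():
        for rec in recs:
            i, j = index[rec.source_id], index[rec.target_id]
            key = (i, j) if i < j else (j, i)
            w = int(rec.weight)
            if w > best.get(key, -1):
                best[key] = w

    if best:
        rows = np.fromiter((k[0] for k in best), dtype=np.int64, count=len(best))
        cols = np.fromiter((k[1] for k in best), dtype=np.int64, count=len(best))
        vals = np.fromiter(best.values(), dtype=np.int64, count=len(best))
        upper = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
        adjacency = (upper + upper.T).tocsr()
    else:
        adjacency = sp.csr_matrix((n, n), dtype=np.int64)

    node_layers = [node_layer[nid] for nid in node_ids]
    masks = {}
    for layer in sorted(set(node_layers)):
        bits = np.fromiter((1 if l == layer else 0 for l in node_layers), dtype=np.int8, count=n)
        masks[layer] = LayerMask(layer, bits)
    return MulticonceptGraph(node_ids, node_layers, adjacency, masks)


# ---------------------------------------------------------------------------
# Matrix operations
# ---------------------------------------------------------------------------

def normalize_columns(matrix: sp.spmatrix) -> ColumnStochasticMatrix:
    """Column-normalize a nonnegative matrix into a stochastic map.

    Zero columns (isolated nodes, or nodes outside a masked block) receive a
    unit self-loop first, so the walker stays put there instead of leaking
    probability mass.
    """
    m = sp.csr_matrix(matrix, dtype=np.float64, copy=True)
    col_sums = np.asarray(m.sum(axis=0)).ravel()
    zero = col_sums == 0
    if zero.any():
        idx = np.flatnonzero(zero)
        loops = sp.coo_matrix(
            (np.ones(idx.size), (idx, idx)), shape=m.shape
        )
        m = (m + loops).tocsr()
        col_sums = col_sums + zero
    inv = sp.diags(1.0 / col_sums)
    return ColumnStochasticMatrix((m @ inv).tocsr())


def column_normalize(graph: MulticonceptGraph) -> ColumnStochasticMatrix:
    """Column-normalized transition matrix W of the graph's adjacency."""
    return normalize_columns(graph.adjacency)


def extract_block(
    graph: MulticonceptGraph, from_layer: str, to_layer: str
) -> sp.csr_matrix:
    """Masked cross-layer block ``diag(m_i) A diag(m_j)`` of the raw adjacency.

    Rows outside ``from_layer`` and columns outside ``to_layer`` are zeroed;
    the result keeps the full ``n x n`` shape.  Applied to the *raw*
    adjacency (renormalize afterwards if a stochastic map is needed):
    masking an already-stochastic matrix would leave substochastic columns.
    """
    for layer in (from_layer, to_layer):
        if layer not in graph.masks:
            raise KeyError(f"layer {layer!r} not present in graph (has {graph.layers})")
    mi = graph.masks[from_layer].bits.astype(np.float64)
    mj = graph.masks[to_layer].bits.astype(np.float64)
    return (sp.diags(mi) @ graph.adjacency @ sp.diags(mj)).tocsr()


def hits_reweight(
    graph: MulticonceptGraph, iterations: int = 1000, enabled: bool = False
) -> MulticonceptGraph:
    """Optionally rescale edge weights by hub/authority centrality.

    On an undirected graph hub and authority scores coincide with the
    principal-eigenvector centrality, computed here by power iteration.
    Each edge weight becomes ``w * sqrt(c_u * c_v)`` and the result is
    rescaled to the [0, 1000] integer range by its maximum.  Disabled by
    default; when disabled the graph is returned unchanged.
    """
    if not enabled:
        return graph
    A = graph.adjacency.astype(np.float64)
    n = A.shape[0]
    # diagonal shift by the max row sum: same eigenvectors, but the shifted
    # matrix is positive semidefinite, so power iteration cannot oscillate on
    # bipartite spectra (paired +/- extreme eigenvalues)
    shift = float(np.asarray(np.abs(A).sum(axis=1)).max()) or 1.0
    shifted = (A + shift * sp.identity(n, format="csr")).tocsr()
    c = np.full(n, 1.0 / np.sqrt(n))
    converged = False
    for _ in range(int(iterations)):
        nxt = shifted @ c
        norm = np.linalg.norm(nxt)
        if norm == 0:
            break
        nxt /= norm
        if np.max(np.abs(nxt - c)) < 1e-10:
            c = nxt
            converged = True
            break
        c = nxt
    if not converged:
        warnings.warn(
            f"centrality power iteration did not converge in {iterations} steps; "
            "using last iterate",
            RuntimeWarning,
        )
    coo = A.tocoo()
    scale = np.sqrt(c[coo.row] * c[coo.col])
    vals = coo.data * scale
    if vals.size and vals.max() > 0:
        vals = np.rint(vals / vals.max() * MAX_WEIGHT).astype(np.int64)
    else:
        vals = vals.astype(np.int64)
    new_adj = sp.coo_matrix((vals, (coo.row, coo.col)), shape=A.shape).tocsr()
    return MulticonceptGraph(
        list(graph.node_ids), list(graph.node_layers), new_adj, dict(graph.masks)
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_graph(graph: MulticonceptGraph, path: str | Path) -> None:
    """Write the graph as an edge TSV plus a JSON node-order sidecar.

    The TSV holds (source, source_layer, target, target_layer, weight) for
    each upper-triangle edge; the sidecar ``<path>.nodes.json`` records the
    node order and layers so the matrix layout is reproducible.
    """
    path = Path(path)
    coo = sp.triu(graph.adjacency, k=1).tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#source\tsource_layer\ttarget\ttarget_layer\tweight\n")
        for k in order:
            i, j, w = int(coo.row[k]), int(coo.col[k]), int(coo.data[k])
            fh.write(
                f"{graph.node_ids[i]}\t{graph.node_layers[i]}\t"
                f"{graph.node_ids[j]}\t{graph.node_layers[j]}\t{w}\n"
            )
    sidecar = {
        "node_ids": graph.node_ids,
        "node_layers": graph.node_layers,
    }
    with open(path.with_name(path.name + ".nodes.json"), "wt", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=0, sort_keys=True)
        fh.write("\n")


def load_graph(path: str | Path) -> MulticonceptGraph:
    """Load a graph written by :func:`save_graph`.

    Falls back to rebuilding the node order from the edge list when the
    sidecar is absent.
    """
    path = Path(path)
    pairs: dict[tuple[str, str], list[AssociationRecord]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise ParseError(f"line {lineno}: expected 5 columns, got {len(cols)}")
            src, sl, tgt, tl, w = cols
            key = (sl, tl)
            pairs.setdefault(key, []).append(
                _record(src, tgt, _parse_weight(w, lineno), lineno)
            )
    graph = build_graph(pairs)
    sidecar = path.with_name(path.name + ".nodes.json")
    if sidecar.exists():
        with open(sidecar, "rt", encoding="utf-8") as fh:
            meta = json.load(fh)
        if meta["node_ids"] != graph.node_ids:
            raise GraphBuildError("sidecar node order disagrees with edge list")
    return graph


def records_from_edges(
    edges: Iterable[tuple[str, str, int]]
) -> list[AssociationRecord]:
    """Convenience: turn (source, target, weight) triples into records."""
    return [AssociationRecord(a, b, w) for a, b, w in edges]
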