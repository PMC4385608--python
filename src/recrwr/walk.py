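"""Random Walk with Restarts on a column-stochastic transition matrix.

Each step applies ``p_{t+1} = (1 - r) W p_t + r p_0``: with probability
``r`` the walker restarts at the seed distribution ``p_0``, otherwise it
follows an edge of the column-normalized adjacency ``W``.  Because ``W``
is column-stochastic every iterate is a probability vector, and the map is
a contraction with factor ``1 - r`` in L1, so the fixed point
``p = r (I - (1 - r) W)^{-1} p_0`` is unique; :func:`rwr_closed_form`
solves it directly and serves as a dense testing oracle.

Convergence is declared when a mask-weighted L1 residual
``sum_i m_i |p_t[i] - p_{t-1}[i]|`` drops below the tolerance, which lets
a caller watch only one layer's scores stabilize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse.linalg  # noqa: F401  (namespace for spsolve users)

from .graph import ColumnStochasticMatrix, LayerMask, MulticonceptGraph

#: Largest n the dense closed-form oracle will accept.
DEFAULT_ORACLE_CAP = 2000


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of the restart walk.

    restart
        Restart probability r in (0, 1]; 0.75 is the prevailing default in
        the network-prioritization literature.
    tolerance
        Convergence threshold on the masked L1 residual.
    max_iterations
        Hard cap on propagation steps.
    """

    restart: float = 0.75
    tolerance: float = 1e-6
    max_iterations: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.restart <= 1.0):
            raise ValueError(f"restart must be in (0, 1], got {self.restart}")
        if self.tolerance <= 0:
            raise ValueError(f"tolerance must be > 0, got {self.tolerance}")
        if self.max_iterations < 1:
            raise ValueError(f"max_iterations must be >= 1, got {self.max_iterations}")


@dataclass(frozen=True)
class ScoreVector:
    """Probability vector over all graph nodes at iteration ``step``."""

    values: np.ndarray
    step: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ValueError("score vector must be one-dimensional")
        if (v < -1e-15).any():
            raise ValueError("score vector has negative entries")
        total = float(v.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"score vector sums to {total}, expected 1")

    def __len__(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class SeedSet:
    """The list L of seed node identifiers (duplicates removed)."""

    node_ids: tuple[str, ...]

    def __init__(self, node_ids: Sequence[str]) -> None:
        seen: dict[str, None] = dict.fromkeys(node_ids)
        object.__setattr__(self, "node_ids", tuple(seen))

    def __len__(self) -> int:
        return len(self.node_ids)

    def __iter__(self):
        return iter(self.node_ids)

    @classmethod
    def from_file(cls, path: str | Path) -> "SeedSet":
        """Read one identifier per line; '#' comments and blanks skipped."""
        ids = []
        with open(path, "rt", encoding="utf-8") as fh:
            for raw in fh:
                line = raw.strip()
                if line and not line.startswith("#"):
                    ids.append(line)
        return cls(ids)


@dataclass(frozen=True)
class WalkResult:
    """Converged walk output with diagnostics."""

    scores: ScoreVector
    iterations: int
    residual: float
    converged: bool


def make_seed_vector(seeds: SeedSet, graph: MulticonceptGraph) -> ScoreVector:
    """Uniform restart distribution over the seeds that resolve in the graph.

    Every resolved seed receives probability ``1/|resolved|``.  Seeds absent
    from the graph trigger a warning listing them; if none resolve a
    ``ValueError`` is raised.
    """
    resolved = [s for s in seeds if s in graph]
    missing = [s for s in seeds if s not in graph]
    if not resolved:
        raise ValueError("no seed identifier resolves to a graph node")
    if missing:
        warnings.warn(
            f"{len(missing)} seed id(s) not in graph, ignored: "
            + ", ".join(missing[:10]),
            UserWarning,
        )
    p0 = np.zeros(graph.n_nodes)
    idx = [graph.index_of(s) for s in resolved]
    p0[idx] = 1.0 / len(idx)
    return ScoreVector(p0, step=0)


def rwr_step(
    W: ColumnStochasticMatrix,
    p_t: ScoreVector,
    p0: ScoreVector,
    config: WalkConfig,
) -> ScoreVector:
    """One propagation step ``(1 - r) W p_t + r p_0``."""
    if W.n != len(p_t) or W.n != len(p0):
        raise ValueError(
            f"dimension mismatch: W is {W.n}x{W.n}, p_t has {len(p_t)}, p0 has {len(p0)}"
        )
    r = config.restart
    nxt = (1.0 - r) * (W.matrix @ p_t.values) + r * p0.values
    return ScoreVector(nxt, step=p_t.step + 1)


def masked_l1(
    delta: np.ndarray, mask: LayerMask | np.ndarray | None
) -> float:
    """Mask-weighted L1 norm ``sum_i m_i |delta_i|`` (all-ones if no mask)."""
    a = np.abs(delta)
    if mask is None:
        return float(a.sum())
    bits = mask.bits if isinstance(mask, LayerMask) else np.asarray(mask)
    return float(a @ bits.astype(np.float64))


def rwr_converge(
    W: ColumnStochasticMatrix,
    p0: ScoreVector,
    config: WalkConfig,
    mask: LayerMask | np.ndarray | None = None,
) -> WalkResult:
    """Iterate :func:`rwr_step` until the masked L1 residual drops below tol.

    ``mask`` restricts the stopping rule to one layer's entries (all nodes
    by default).  Hitting ``max_iterations`` sets ``converged=False`` on the
    result instead of raising.
    """
    p = p0
    residual = np.inf
    for it in range(1, config.max_iterations + 1):
        nxt = rwr_step(W, p, p0, config)
        residual = masked_l1(nxt.values - p.values, mask)
        p = nxt
        if residual < config.tolerance:
            return WalkResult(p, it, residual, True)
    warnings.warn(
        f"walk did not converge in {config.max_iterations} iterations "
        f"(residual {residual:.3e})",
        RuntimeWarning,
    )
    return WalkResult(p, config.max_iterations, residual, False)


def rwr_closed_form(
    W: ColumnStochasticMatrix,
    p0: ScoreVector,
    config: WalkConfig,
    oracle_cap: int = DEFAULT_ORACLE_CAP,
) -> ScoreVector:
    """Fixed point by dense linear solve: ``p = r (I - (1-r) W)^{-1} p0``.

    A testing oracle — refuses matrices larger than ``oracle_cap`` so it is
    never mistaken for the production path.  Invertibility holds because
    the spectral radius of ``(1 - r) W`` is at most ``1 - r < 1``.
    """
    n = W.n
    if n > oracle_cap:
        raise ValueError(f"closed-form oracle capped at n={oracle_cap}, got {n}")
    r = config.restart
    A = np.eye(n) - (1.0 - r) * W.matrix.toarray()
    p = r * np.linalg.solve(A, p0.values)
    p = p / p.sum()  # scrub last-ulp drift; the exact solution sums to 1
    return ScoreVector(p, step=-1)


def write_scores(
    path: str | Path, graph: MulticonceptGraph, scores: ScoreVector
) -> None:
    """Write (node_id, layer, score) TSV sorted by descending score.

    Ties are ordered by node index so output is byte-reproducible.
    """
    order = np.lexsort((np.arange(len(scores)), -scores.values))
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#node_id\tlayer\tscore\n")
        for i in order:
            fh.write(
                f"{graph.node_ids[i]}\t{graph.node_layers[i]}\t"
                f"{scores.values[i]:.12g}\n"
            )
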