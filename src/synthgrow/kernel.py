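"""Iterative similarity optimal-assignment graph kernel (ISOAK-style score).

Similarity between two molecules is computed on either the typed molecular
graph or the reduced feature graph. A recursive notion of vertex similarity
("two vertices are similar if their neighbors are similar") is iterated to a
fixed point:

    s(u, v) = (1 - alpha) * base(u, v) + alpha * neighbor_term(u, v)

where ``base`` compares vertex labels (pharmacophore-type equality on
molecular graphs; size-penalized Tanimoto of the 10-bit labels on reduced
graphs) and ``neighbor_term`` is the value of a maximum-weight one-to-one
matching between the two neighbor lists, each matched pair weighted by
edge compatibility (equal bond order) times the current similarity, and
normalized by the larger neighbor count. ``alpha`` in [0, 1) controls the
influence of the neighborhood and makes the update a contraction.

From the converged vertex-pair similarities an optimal assignment of each
vertex of the smaller graph to one vertex of the larger graph is computed
(Hungarian algorithm); the assignment sum scaled by the larger vertex count
is the molecule similarity in [0, 1], with self-similarity exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .chemgraph import TypedMolecularGraph
from .reduced_graph import MAX_DEGREE, ReducedGraph, vertex_similarity

log = logging.getLogger(__name__)

#: neighborhood-weight defaults by representation
DEFAULT_ALPHA = {"molgraph": 0.875, "reduced": 0.4}


class KernelError(ValueError):
    pass


@dataclass(frozen=True)
class KernelParams:
    """Kernel knobs: neighborhood weight, tolerance, iteration cap."""

    alpha: float = 0.875
    tol: float = 1e-6
    max_iter: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise KernelError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.tol <= 0 or self.max_iter < 1:
            raise KernelError("tol must be > 0 and max_iter >= 1")


@dataclass
class SimilarityMatrix:
    """Converged vertex-pair similarities of two graphs."""

    s: np.ndarray  # shape (|V_A|, |V_B|), entries in [0, 1]
    iterations: int
    converged: bool


Graph = TypedMolecularGraph | ReducedGraph


def _mode(graph: Graph) -> str:
    return "reduced" if isinstance(graph, ReducedGraph) else "molgraph"


def _edge_orders(graph: Graph) -> dict[tuple[int, int], object]:
    orders: dict[tuple[int, int], object] = {}
    for i, j, o in graph.edges:
        orders[(i, j)] = o
        orders[(j, i)] = o
    return orders


def base_similarity_matrix(g_a: Graph, g_b: Graph) -> np.ndarray:
    """Label-only vertex similarities (the alpha = 0 limit of the kernel)."""
    if _mode(g_a) != _mode(g_b):
        raise KernelError("cannot compare molecular and reduced graphs")
    if _mode(g_a) == "molgraph":
        ta, tb = g_a.types, g_b.types
        return np.array([[1.0 if x == y else 0.0 for y in tb] for x in ta])
    return np.array(
        [[vertex_similarity(u, v) for v in g_b.vertices] for u in g_a.vertices]
    )


def base_vertex_similarity(g_a: Graph, u: int, g_b: Graph, v: int) -> float:
    """Base similarity of one vertex pair (mode inferred from the graphs)."""
    return float(base_similarity_matrix_cache(g_a, g_b)[u, v])


def base_similarity_matrix_cache(g_a: Graph, g_b: Graph) -> np.ndarray:
    # small convenience; matrices are cheap at the sizes handled here
    return base_similarity_matrix(g_a, g_b)


def _check_degrees(graph: Graph) -> None:
    n = len(graph.vertices)
    for i in range(n):
        if len(graph.neighbors(i)) > MAX_DEGREE:
            raise KernelError(
                f"vertex {i} of {getattr(graph, 'source_id', '?')} has more than "
                f"{MAX_DEGREE} neighbors; graph must be discarded before scoring"
            )


def iterate_similarity(g_a: Graph, g_b: Graph, params: KernelParams) -> SimilarityMatrix:
    """Iterate the recursive vertex-similarity update to its fixed point.

    Synchronous updates from the all-base initialization; with alpha < 1 the
    map is a contraction, so the fixed point is unique and independent of
    vertex input order. Non-convergence within ``max_iter`` returns the last
    iterate with ``converged=False`` and logs a warning.
    """
    if not g_a.vertices or not g_b.vertices:
        raise KernelError("cannot compare empty graphs")
    _check_degrees(g_a)
    _check_degrees(g_b)
    base = base_similarity_matrix(g_a, g_b)
    alpha = params.alpha
    if alpha == 0.0:
        return SimilarityMatrix(s=base, iterations=0, converged=True)

    na, nb = base.shape
    nbrs_a = [g_a.neighbors(i) for i in range(na)]
    nbrs_b = [g_b.neighbors(j) for j in range(nb)]
    ord_a = _edge_orders(g_a)
    ord_b = _edge_orders(g_b)
    # per vertex pair: compatible neighbor pairs (equal edge order)
    compat: list[list[tuple[np.ndarray, np.ndarray, int, int] | None]] = []
    for i in range(na):
        row = []
        for j in range(nb):
            ca, cb = nbrs_a[i], nbrs_b[j]
            if not ca and not cb:
                row.append(None)  # vacuous perfect matching, term = 1
                continue
            mask = np.array(
                [[ord_a[(i, x)] == ord_b[(j, y)] for y in cb] for x in ca],
                dtype=float,
            ) if ca and cb else np.zeros((max(len(ca), 1), max(len(cb), 1)))
            ia = np.array(ca, dtype=int) if ca else np.zeros(0, dtype=int)
            ib = np.array(cb, dtype=int) if cb else np.zeros(0, dtype=int)
            row.append((ia, ib, mask, max(len(ca), len(cb))))
        compat.append(row)

    s = base.copy()
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        s_new = np.empty_like(s)
        for i in range(na):
            for j in range(nb):
                entry = compat[i][j]
                if entry is None:
                    term = 1.0
                else:
                    ia, ib, mask, denom = entry
                    if ia.size == 0 or ib.size == 0:
                        term = 0.0
                    else:
                        w = mask * s[np.ix_(ia, ib)]
                        r, c = linear_sum_assignment(w, maximize=True)
                        term = w[r, c].sum() / denom
                s_new[i, j] = (1.0 - alpha) * base[i, j] + alpha * term
        delta = float(np.max(np.abs(s_new - s)))
        s = s_new
        if delta < params.tol:
            converged = True
            break
    if not converged:
        log.warning("similarity iteration did not converge in %d steps", params.max_iter)
    return SimilarityMatrix(s=s, iterations=it, converged=converged)


def assignment_score(s: np.ndarray) -> float:
    """Optimal-assignment sum over s, scaled by the larger vertex count."""
    r, c = linear_sum_assignment(s, maximize=True)
    return float(s[r, c].sum()) / max(s.shape)


def molecule_similarity(g_a: Graph, g_b: Graph, params: KernelParams) -> float:
    """Kernel similarity of two graphs in [0, 1]; symmetric, self-sim 1."""
    sim = iterate_similarity(g_a, g_b, params)
    return assignment_score(sim.s)
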