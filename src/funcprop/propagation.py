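"""Coupled random walk with restart over the correlation networks.

The propagation network (PN) is assembled by running, for every protein,
a two-step restart walk on the co-neighbor transition structure:

    VD(t+1) = alpha * H  @ VC(t) + (1 - alpha) * RV_D
    VC(t+1) = alpha * H' @ VD(t) + (1 - alpha) * RV_C

where ``H`` row-normalizes the co-neighbor weights, and the restart
vectors ``RV_D`` / ``RV_C`` are the seed's raw co-domain and co-complex
weight rows.  The two score vectors deliberately feed each other: the
structural scores (VD) are refreshed from the modular ones (VC) and vice
versa, so domain-derived and complex-derived evidence mix through the
interaction topology.  Restart vectors are *not* renormalized, so the
converged vectors are not probability distributions.

At convergence the PN entry (i, j) is ``VD_i[j] + VC_i[j]``; the matrix is
then thresholded per row, the diagonal removed, and symmetrized by
averaging, yielding a weighted undirected functional-similarity network.

Updates are synchronous (both new vectors are computed from the time-t
pair).  All seeds iterate simultaneously as two dense n-by-n matrices with
a sparse ``H``, which is exact because the per-seed iterations are
independent linear maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .correlation import CorrelationTriplet

__all__ = [
    "TransitionMatrix",
    "SeedState",
    "PropagationNetwork",
    "ConvergenceError",
    "build_transition_matrix",
    "make_restart_vectors",
    "propagate_seed",
    "build_propagation_network",
]

DEFAULT_ALPHA = 0.5     # balance between propagation and restart
DEFAULT_TOL = 1e-6      # L1 convergence threshold on the (VD, VC) pair
DEFAULT_MAX_ITER = 1000
DEFAULT_EPSILON = 1e-4  # per-row sparsification threshold, relative to row max


class ConvergenceError(RuntimeError):
    """Propagation failed to converge; carries the residual and seed."""

    def __init__(self, msg: str, residual: float, seed: str | None = None):
        super().__init__(msg)
        self.residual = residual
        self.seed = seed


@dataclass
class TransitionMatrix:
    """Row-normalized co-neighbor weights with their identifier order.

    Every row sums to 1, or to 0 for proteins with no co-neighbor
    out-weight (the walk has nowhere to go from them).
    """

    order: list[str]
    values: sp.csr_matrix

    @property
    def n(self) -> int:
        return len(self.order)

    def index(self, protein: str) -> int:
        try:
            return self.order.index(protein)
        except ValueError as exc:
            raise KeyError(protein) from exc


@dataclass
class SeedState:
    """Per-seed walk state: score vectors, restart vectors, step count."""

    seed: str
    vd: np.ndarray
    vc: np.ndarray
    rv_d: np.ndarray
    rv_c: np.ndarray
    alpha: float
    iterations: int = 0


@dataclass
class PropagationNetwork:
    """The assembled propagation network.

    ``weights[i, j]`` holds the symmetrized, sparsified similarity between
    proteins ``order[i]`` and ``order[j]``; ``sparsified`` is the same
    information as an undirected :class:`networkx.Graph`.
    """

    order: list[str]
    weights: np.ndarray
    sparsified: nx.Graph
    iterations: dict[str, int] = field(default_factory=dict)

    def neighbors(self, protein: str) -> dict[str, float]:
        """PN neighbours of *protein* with their similarity weights."""
        if protein not in self.sparsified:
            return {}
        return {u: d["weight"] for u, d in self.sparsified[protein].items()}

    @classmethod
    def from_graph(cls, graph: nx.Graph,
                   order: list[str] | None = None) -> "PropagationNetwork":
        """Wrap a weighted undirected graph (e.g. a re-read PN edge list)."""
        if order is None:
            order = sorted(graph.nodes)
        idx = {p: i for i, p in enumerate(order)}
        weights = np.zeros((len(order), len(order)))
        for a, b, d in graph.edges(data=True):
            w = float(d.get("weight", 1.0))
            weights[idx[a], idx[b]] = weights[idx[b], idx[a]] = w
        return cls(order=list(order), weights=weights, sparsified=graph)


def _weight_matrix(net: nx.Graph, order: list[str]) -> sp.csr_matrix:
    idx = {p: i for i, p in enumerate(order)}
    rows, cols, vals = [], [], []
    for a, b, data in net.edges(data=True):
        if a not in idx or b not in idx:
            continue
        w = float(data.get("weight", 1.0))
        ia, ib = idx[a], idx[b]
        rows += [ia, ib]
        cols += [ib, ia]
        vals += [w, w]
    n = len(order)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def shared_order(triplet: CorrelationTriplet) -> list[str]:
    """Sorted union of the three networks' node sets."""
    nodes = (set(triplet.co_neighbor) | set(triplet.co_domain)
             | set(triplet.co_complex))
    return sorted(nodes)


def build_transition_matrix(co_neighbor: nx.Graph,
                            order: list[str] | None = None) -> TransitionMatrix:
    """Row-normalize the co-neighbor weights into a transition matrix.

    Rows with zero out-weight (proteins absent from the co-neighbor
    network) are left all-zero.
    """
    if order is None:
        order = sorted(co_neighbor.nodes)
    w = _weight_matrix(co_neighbor, order)
    row_sums = np.asarray(w.sum(axis=1)).ravel()
    inv = np.divide(1.0, row_sums, out=np.zeros_like(row_sums),
                    where=row_sums > 0)
    h = sp.diags(inv) @ w
    return TransitionMatrix(order=list(order), values=sp.csr_matrix(h))


def make_restart_vectors(seed: str, co_domain: nx.Graph, co_complex: nx.Graph,
                         order: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Raw co-domain / co-complex rows of *seed*, as restart vectors.

    Positions without a corresponding edge are 0; the vectors are not
    renormalized.
    """
    n = len(order)
    idx = {p: i for i, p in enumerate(order)}
    rv_d = np.zeros(n)
    rv_c = np.zeros(n)
    for net, rv in ((co_domain, rv_d), (co_complex, rv_c)):
        if seed in net:
            for u, data in net[seed].items():
                if u in idx:
                    rv[idx[u]] = float(data.get("weight", 1.0))
    return rv_d, rv_c


def initial_state(seed: str, rv_d: np.ndarray, rv_c: np.ndarray,
                  alpha: float) -> SeedState:
    """Fresh seed state with both score vectors at the uniform 1/n start."""
    n = rv_d.shape[0]
    uniform = np.full(n, 1.0 / n)
    return SeedState(seed=seed, vd=uniform.copy(), vc=uniform.copy(),
                     rv_d=rv_d, rv_c=rv_c, alpha=alpha)


def propagate_seed(state: SeedState, h: TransitionMatrix,
                   tol: float = DEFAULT_TOL,
                   max_iter: int = DEFAULT_MAX_ITER) -> SeedState:
    """Iterate the coupled walk for one seed until the L1 change of the
    concatenated (VD, VC) pair drops below *tol*.

    Raises :class:`ConvergenceError` if *max_iter* steps do not suffice.
    """
    if not (0.0 <= state.alpha < 1.0):
        raise ValueError("alpha must be in [0, 1)")
    if tol <= 0:
        raise ValueError("tol must be positive")
    a = state.alpha
    ht = h.values.T.tocsr()
    vd, vc = state.vd, state.vc
    for t in range(1, max_iter + 1):
        vd_next = a * (h.values @ vc) + (1.0 - a) * state.rv_d
        vc_next = a * (ht @ vd) + (1.0 - a) * state.rv_c
        resid = np.abs(vd_next - vd).sum() + np.abs(vc_next - vc).sum()
        vd, vc = vd_next, vc_next
        if resid < tol:
            return SeedState(seed=state.seed, vd=vd, vc=vc, rv_d=state.rv_d,
                             rv_c=state.rv_c, alpha=a, iterations=t)
    raise ConvergenceError(
        f"no convergence for seed {state.seed!r} after {max_iter} iterations "
        f"(residual {resid:.3g})", residual=float(resid), seed=state.seed)


def _restart_matrix(net: nx.Graph, order: list[str]) -> np.ndarray:
    """Dense symmetric weight matrix; column s is seed s's restart vector."""
    return _weight_matrix(net, order).toarray()


def build_propagation_network(triplet: CorrelationTriplet,
                              alpha: float = DEFAULT_ALPHA,
                              tol: float = DEFAULT_TOL,
                              max_iter: int = DEFAULT_MAX_ITER,
                              epsilon: float = DEFAULT_EPSILON,
                              order: list[str] | None = None,
                              ) -> PropagationNetwork:
    """Run the coupled walk for every protein and assemble the PN.

    All seeds are iterated simultaneously (columns of two n-by-n
    matrices).  PN row i is seed i's converged ``VD + VC``; the matrix is
    sparsified per row (entries below ``epsilon`` times the row maximum
    are dropped), its diagonal removed, and symmetrized by averaging
    (i, j) with (j, i).
    """
    if not (0.0 <= alpha < 1.0):
        raise ValueError("alpha must be in [0, 1)")
    if order is None:
        order = shared_order(triplet)
    n = len(order)
    h = build_transition_matrix(triplet.co_neighbor, order)
    ht = h.values.T.tocsr()
    rvd = _restart_matrix(triplet.co_domain, order)    # column s = RV_D of seed s
    rvc = _restart_matrix(triplet.co_complex, order)

    vd = np.full((n, n), 1.0 / n)
    vc = np.full((n, n), 1.0 / n)
    first_converged = np.full(n, -1, dtype=int)
    for t in range(1, max_iter + 1):
        vd_next = alpha * (h.values @ vc) + (1.0 - alpha) * rvd
        vc_next = alpha * (ht @ vd) + (1.0 - alpha) * rvc
        resid = (np.abs(vd_next - vd).sum(axis=0)
                 + np.abs(vc_next - vc).sum(axis=0))
        vd, vc = vd_next, vc_next
        newly = (resid < tol) & (first_converged < 0)
        first_converged[newly] = t
        if resid.max() < tol:
            break
    else:
        worst = int(np.argmax(resid))
        raise ConvergenceError(
            f"no convergence for seed {order[worst]!r} after {max_iter} "
            f"iterations (residual {resid[worst]:.3g})",
            residual=float(resid[worst]), seed=order[worst])

    pn = (vd + vc).T  # row i = seed i's converged scores
    pn = np.maximum(pn, 0.0)

    # per-row relative threshold, then diagonal removal, then symmetrization
    row_max = pn.max(axis=1, keepdims=True)
    pn[pn < epsilon * row_max] = 0.0
    np.fill_diagonal(pn, 0.0)
    pn = 0.5 * (pn + pn.T)

    g = nx.Graph()
    g.add_nodes_from(order)
    ii, jj = np.nonzero(np.triu(pn, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        g.add_edge(order[i], order[j], weight=float(pn[i, j]))
    iterations = {p: int(first_converged[k]) for k, p in enumerate(order)}
    return PropagationNetwork(order=list(order), weights=pn, sparsified=g,
                              iterations=iterations)
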