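"""Functional-module detection and top-K function annotation.

For a target protein *v*, the candidate module starts as all of *v*'s
propagation-network neighbours.  Cohesion of a module M is the fitness

    f(M) = w_in / (w_in + w_out) ** beta

where ``w_in`` sums PN edge weights inside M and ``w_out`` sums weights
crossing the module boundary.  Each neighbour *u* is visited in descending
order of similarity to *v* and removed whenever its neighbour fitness
``f(M ∪ {u}) - f(M \\ {u})`` is not positive, leaving a high-cohesion
candidate set.  Candidate functions are then scored by the similarity-
weighted count of candidates carrying them, and the top K are predicted,
with K taken from the annotation count of the most similar annotated
neighbour.

The target anchors its module: its edges into the candidate set count as
internal weight while the module is pruned (so a partner tied only to the
target is judged by that tie), but the target is never itself reported as
a candidate and only candidates vote on functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import AbstractSet, Iterable

from .data_io import AnnotationMap
from .propagation import PropagationNetwork

__all__ = [
    "FunctionalModule",
    "PredictionRecord",
    "NoCandidatesError",
    "module_fitness",
    "neighbour_fitness",
    "select_candidates",
    "score_functions",
    "choose_k",
    "predict",
]

DEFAULT_BETA = 1.0  # module-size control in the fitness denominator


class NoCandidatesError(LookupError):
    """The target has no usable propagation-network neighbourhood."""


@dataclass
class FunctionalModule:
    """A candidate protein set with its cached cohesion terms."""

    members: frozenset[str]
    w_in: float
    w_out: float
    beta: float
    fitness: float


@dataclass
class PredictionRecord:
    """Outcome of annotating one target protein.

    ``candidate_functions`` keeps the full descending-score ranking so
    evaluation can re-truncate at any K; ``predicted`` is the top-K set
    actually reported.  A record with an empty ``predicted`` set marks an
    unpredictable target ("no prediction"), which evaluation still counts.
    """

    target: str
    candidates: tuple[str, ...] = ()
    candidate_functions: tuple[tuple[str, float], ...] = ()
    k: int = 0
    predicted: frozenset[str] = frozenset()
    module_fitness: float = 0.0


def _module_weights(members: AbstractSet[str], pn: PropagationNetwork,
                    ) -> tuple[float, float]:
    """Total internal and boundary PN edge weight of a protein set."""
    w_in = 0.0
    w_out = 0.0
    g = pn.sparsified
    for p in members:
        if p not in g:
            continue
        for u, data in g[p].items():
            w = data["weight"]
            if u in members:
                w_in += w  # each internal edge visited from both ends
            else:
                w_out += w
    return w_in / 2.0, w_out


def module_fitness(members: AbstractSet[str], pn: PropagationNetwork,
                   beta: float = DEFAULT_BETA) -> float:
    """Cohesion f(M) = w_in / (w_in + w_out)**beta; 0 for weightless sets."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    w_in, w_out = _module_weights(members, pn)
    total = w_in + w_out
    if total <= 0.0:
        return 0.0
    return w_in / total ** beta


def neighbour_fitness(u: str, base: AbstractSet[str], pn: PropagationNetwork,
                      beta: float = DEFAULT_BETA) -> float:
    """Fitness gain of having *u* inside the module versus outside."""
    base = set(base)
    with_u = module_fitness(base | {u}, pn, beta)
    without_u = module_fitness(base - {u}, pn, beta)
    return with_u - without_u


def _ranked_neighbors(v: str, pn: PropagationNetwork) -> list[tuple[str, float]]:
    """PN neighbours of *v*, descending by weight, ties lexicographic."""
    neigh = pn.neighbors(v)
    return sorted(neigh.items(), key=lambda it: (-it[1], it[0]))


def select_candidates(v: str, pn: PropagationNetwork,
                      beta: float = DEFAULT_BETA,
                      sequential: bool = True) -> FunctionalModule:
    """Prune *v*'s PN neighbourhood down to a high-cohesion module.

    Starts from all PN neighbours of *v*; visits them in descending
    similarity order and drops any whose neighbour fitness against the
    current module (anchored by *v*, see the module docstring) is <= 0.
    With ``sequential=False`` every neighbour is instead judged against
    the full initial module (a static variant kept for comparison).  The
    returned candidate set never contains *v* itself.

    Raises :class:`NoCandidatesError` when *v* has no positive-weight PN
    neighbour.
    """
    ranked = _ranked_neighbors(v, pn)
    if not ranked:
        raise NoCandidatesError(f"{v!r} has no propagation-network neighbours")
    # v anchors the module: its edges count as internal weight, so a
    # neighbour tied only to v is judged by that tie rather than dropped
    # outright.  Only neighbours are candidates and only they are pruned.
    members = {u for u, _ in ranked} | {v}

    # Incremental bookkeeping: with S = sum of member strengths and w_in the
    # internal weight, w_out = S - 2*w_in, so one pass over each visited
    # neighbour's edges suffices.  Equivalent to calling neighbour_fitness
    # against the current module (the definitional form kept above).
    g = pn.sparsified
    strength = {u: sum(d["weight"] for d in g[u].values()) for u in members}
    w_in = 0.0
    for u in members:
        w_in += sum(d["weight"] for x, d in g[u].items() if x in members)
    w_in /= 2.0
    s_sum = sum(strength.values())

    def _fit(win: float, wout: float) -> float:
        total = win + wout
        return win / total ** beta if total > 0 else 0.0

    reference = frozenset(members)
    for u, _w in ranked:
        if sequential:
            inside = u in members
            a = sum(d["weight"] for x, d in g[u].items()
                    if x in members and x != u)
            s_base = s_sum - strength[u] if inside else s_sum
            win_base = w_in - a if inside else w_in
            # module with u outside vs inside
            f_without = _fit(win_base, s_base - 2.0 * win_base)
            s_with = s_base + strength[u]
            win_with = win_base + a
            f_with = _fit(win_with, s_with - 2.0 * win_with)
            if f_with - f_without <= 0.0:
                if inside:
                    members.discard(u)
                    s_sum = s_base
                    w_in = win_base
        else:
            if neighbour_fitness(u, reference, pn, beta) <= 0.0:
                members.discard(u)
    w_in, w_out = _module_weights(members, pn)
    fit = module_fitness(members, pn, beta) if len(members) > 1 else 0.0
    return FunctionalModule(members=frozenset(members - {v}), w_in=w_in,
                            w_out=w_out, beta=beta, fitness=fit)


def score_functions(v: str, module: FunctionalModule | Iterable[str],
                    pn: PropagationNetwork, go: AnnotationMap,
                    ) -> list[tuple[str, float]]:
    """Similarity-weighted vote of the module's annotations.

    Each candidate u contributes its PN similarity to *v* to every
    function it is annotated with; functions are ranked by descending
    score, ties broken by function identifier.  Unannotated candidates
    contribute nothing.
    """
    members = module.members if isinstance(module, FunctionalModule) else module
    weights = pn.neighbors(v)
    scores: dict[str, float] = {}
    for u in members:
        w = weights.get(u, 0.0)
        if w <= 0.0:
            continue
        for f in go.labels(u):
            scores[f] = scores.get(f, 0.0) + w
    return sorted(scores.items(), key=lambda it: (-it[1], it[0]))


def choose_k(v: str, pn: PropagationNetwork, go: AnnotationMap) -> int:
    """K = annotation count of the most similar *annotated* PN neighbour.

    Ties on similarity are broken toward the larger annotation count,
    then the lexicographically smallest identifier, so the choice is
    deterministic.  Raises :class:`NoCandidatesError` when no annotated
    neighbour exists.
    """
    annotated = [(u, w) for u, w in pn.neighbors(v).items() if u in go]
    if not annotated:
        raise NoCandidatesError(f"{v!r} has no annotated PN neighbour")
    best = max(annotated, key=lambda it: (it[1], len(go.labels(it[0])),
                                          _lex_min_key(it[0])))
    return len(go.labels(best[0]))


def _lex_min_key(s: str) -> tuple[int, ...]:
    # max() with this key prefers the lexicographically *smallest* id
    return tuple(-ord(c) for c in s)


def predict(v: str, pn: PropagationNetwork, go: AnnotationMap,
            beta: float = DEFAULT_BETA,
            sequential: bool = True) -> PredictionRecord:
    """Full annotation of one target: module -> scores -> top-K set.

    Raises :class:`NoCandidatesError` (from the helpers) when *v* cannot
    be predicted at all; callers that prefer an empty record should catch
    it.  Ties at the K-th score are broken by function identifier, so
    identical inputs always give identical records.
    """
    module = select_candidates(v, pn, beta=beta, sequential=sequential)
    ranked = score_functions(v, module, pn, go)
    k = choose_k(v, pn, go)
    predicted = frozenset(f for f, _ in ranked[:k])
    order_index = {u: i for i, (u, _) in enumerate(_ranked_neighbors(v, pn))}
    candidates = tuple(sorted(module.members, key=order_index.get))
    return PredictionRecord(
        target=v,
        candidates=candidates,
        candidate_functions=tuple(ranked),
        k=k,
        predicted=predicted,
        module_fitness=module.fitness,
    )
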