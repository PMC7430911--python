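"""The three protein--protein correlation networks.

From one harmonized dataset three weighted, undirected networks are built,
each capturing an independent line of evidence that two proteins share
function:

* **co-neighbor** -- interacting proteins that also share interaction
  partners.  The weight is the product of two overlap ratios between the
  neighbour sets, so it is 1 exactly when the two neighbourhoods coincide.
* **co-domain** -- proteins sharing conserved domains.  The raw weight is a
  negative log-probability of the observed domain overlap arising by
  chance, min--max normalized to [0, 1] over all scored pairs.
* **co-complex** -- proteins co-occurring in protein complexes, weighted by
  the shared-complex count relative to both membership counts.

All weights lie in [0, 1]; all score functions are symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import AbstractSet

import networkx as nx

from .data_io import AnnotationMap

__all__ = [
    "CorrelationTriplet",
    "co_neighbor_score",
    "build_co_neighbor",
    "co_domain_score_raw",
    "build_co_domain",
    "co_complex_score",
    "build_co_complex",
    "build_triplet",
]


@dataclass
class CorrelationTriplet:
    """The three correlation networks derived from one dataset."""

    co_neighbor: nx.Graph
    co_domain: nx.Graph
    co_complex: nx.Graph


def co_neighbor_score(ni: AbstractSet[str], nj: AbstractSet[str]) -> float:
    """Neighbourhood-overlap correlation between two interacting proteins.

    Given the direct-neighbour sets ``ni`` and ``nj``, returns

        (2|ni ∩ nj| / (|ni| + |ni ∩ nj|)) * (2|ni ∩ nj| / (|nj| + |ni ∩ nj|))

    which is 0 for disjoint neighbourhoods and 1 exactly when they are
    identical (and non-empty).  Each factor's numerator never exceeds its
    denominator, so the score is in [0, 1].
    """
    z = len(ni & nj)
    if z == 0:
        return 0.0
    return (2.0 * z / (len(ni) + z)) * (2.0 * z / (len(nj) + z))


def build_co_neighbor(pin: nx.Graph) -> nx.Graph:
    """Build the co-neighbor network from a PIN.

    An edge (i, j) survives iff i and j interact physically *and* share at
    least one interaction partner; its weight is :func:`co_neighbor_score`
    of the two neighbour sets.  Nodes with no surviving edge are dropped,
    so the node set is exactly the set of edge endpoints.
    """
    out = nx.Graph()
    neigh = {n: set(pin.neighbors(n)) for n in pin.nodes}
    for i, j in pin.edges:
        w = co_neighbor_score(neigh[i], neigh[j])
        if w > 0.0:
            out.add_edge(i, j, weight=w)
    return out


def co_domain_score_raw(x: int, y: int, z: int, m: int) -> float:
    """Raw (unnormalized) co-domain score.

    *x* and *y* are the domain counts of the two proteins, *z* the number
    of shared domains, *m* the total number of domain categories.  Returns

        -log( m^z (m-z)^(x-z) (m-x)^(y-z) / (m^x m^y) )

    evaluated term-wise in log space to avoid overflow.  Natural log; the
    base is irrelevant after min--max normalization.

    Raises :class:`ValueError` when the log argument is zero (x == m with
    y > z); callers cap that case at the largest finite raw score.
    """
    if not (0 <= z <= min(x, y)):
        raise ValueError("need 0 <= z <= min(x, y)")
    if m < 1 or x > m or y > m:
        raise ValueError("need x, y <= m and m >= 1")

    def _term(base: int, exp: int) -> float:
        if exp == 0:
            return 0.0  # base**0 == 1 even when base == 0
        if base <= 0:
            raise ValueError("co-domain score undefined: zero factor with "
                             f"positive exponent (x={x}, y={y}, z={z}, m={m})")
        return exp * math.log(base)

    log_num = _term(m, z) + _term(m - z, x - z) + _term(m - x, y - z)
    log_den = _term(m, x) + _term(m, y)
    return -(log_num - log_den)


def build_co_domain(domains: AnnotationMap) -> nx.Graph:
    """Build the co-domain network from domain assignments.

    Edges are created only for protein pairs sharing at least one domain
    (pairs with no shared domain carry no evidence).  Raw scores are
    min--max normalized over exactly the scored pair set; if every raw
    score is identical all weights become 1.0.  Singular raw scores
    (a protein annotated with every domain category) are capped at the
    largest finite raw score before normalization.
    """
    m = len(domains.label_universe)
    if m == 0:
        return nx.Graph()
    counts = {p: len(ls) for p, ls in domains.entries.items()}

    # enumerate candidate pairs via the domain -> proteins inverse index
    by_domain: dict[str, list[str]] = {}
    for p, ls in domains.entries.items():
        for d in ls:
            by_domain.setdefault(d, []).append(p)
    pairs: set[tuple[str, str]] = set()
    for members in by_domain.values():
        members.sort()
        pairs.update(combinations(members, 2))

    raw: dict[tuple[str, str], float] = {}
    singular: list[tuple[str, str]] = []
    for i, j in pairs:
        z = len(domains.labels(i) & domains.labels(j))
        # the raw score is not symmetric under x <-> y; evaluate with the
        # larger domain count as x so the undirected weight is well defined
        x, y = sorted((counts[i], counts[j]), reverse=True)
        try:
            raw[(i, j)] = co_domain_score_raw(x, y, z, m)
        except ValueError:
            singular.append((i, j))
    if singular:
        cap = max(raw.values()) if raw else 1.0
        for pair in singular:
            raw[pair] = cap
    if not raw:
        return nx.Graph()

    lo, hi = min(raw.values()), max(raw.values())
    span = hi - lo
    out = nx.Graph()
    for (i, j), r in raw.items():
        w = 1.0 if span == 0 else (r - lo) / span
        out.add_edge(i, j, weight=w)
    return out


def co_complex_score(ci: AbstractSet[str], cj: AbstractSet[str]) -> float:
    """Shared-complex correlation: |ci ∩ cj| / (|ci| * |cj|).

    Both membership sets must be non-empty; bounded by 1 because
    |ci ∩ cj| <= min(|ci|, |cj|) <= |ci| * |cj|.
    """
    if not ci or not cj:
        raise ValueError("both proteins must belong to at least one complex")
    return len(ci & cj) / (len(ci) * len(cj))


def build_co_complex(complexes: AnnotationMap) -> nx.Graph:
    """Build the co-complex network: an edge for every pair sharing a complex."""
    by_complex: dict[str, list[str]] = {}
    for p, cids in complexes.entries.items():
        for c in cids:
            by_complex.setdefault(c, []).append(p)
    pairs: set[tuple[str, str]] = set()
    for members in by_complex.values():
        members.sort()
        pairs.update(combinations(members, 2))
    out = nx.Graph()
    for i, j in pairs:
        w = co_complex_score(complexes.labels(i), complexes.labels(j))
        if w > 0.0:
            out.add_edge(i, j, weight=w)
    return out


def build_triplet(dataset) -> CorrelationTriplet:
    """Build all three correlation networks from a harmonized dataset."""
    return CorrelationTriplet(
        co_neighbor=build_co_neighbor(dataset.pin),
        co_domain=build_co_domain(dataset.domains),
        co_complex=build_co_complex(dataset.complexes),
    )
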