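"""Readers, writers and shared containers for the pipeline's input data.

Four kinds of input are consumed:

* an undirected protein--protein interaction network (PIN), as a plain
  two-column edge list or a BioGRID TAB export;
* protein -> GO-term annotations (two-column text or GAF 2.x);
* protein -> domain assignments (two-column text, e.g. Pfam accessions);
* protein-complex membership, one complex per line (CYC2008 style).

Interaction networks are held as :class:`networkx.Graph` objects with a
``weight`` attribute on every edge.  Annotation-like data (GO terms, domains,
complex memberships) all share one container, :class:`AnnotationMap`.

Identifiers are opaque strings; harmonization across sources is exact string
matching after whitespace trimming.  No online identifier mapping is
performed -- inputs are expected to use one labelling system already.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationMap",
    "Dataset",
    "read_edge_list",
    "read_weighted_edges",
    "read_annotations",
    "read_complexes",
    "write_weighted_edges",
    "write_annotations",
    "write_complexes",
    "harmonize",
]


class FormatError(ValueError):
    """Raised for malformed input files (carries the offending line number)."""


def _detect_delimiter(line: str) -> str:
    """Delimiter auto-detection, limited to tab and comma.

    A line containing both is ambiguous and rejected.
    """
    has_tab = "\t" in line
    has_comma = "," in line
    if has_tab and has_comma:
        raise FormatError("mixed tab/comma delimiters are not supported")
    if has_tab:
        return "\t"
    if has_comma:
        return ","
    # fall back to any-whitespace splitting
    return ""


def _split(line: str, delim: str) -> list[str]:
    parts = line.split(delim) if delim else line.split()
    return [p.strip() for p in parts]


@dataclass(frozen=True)
class AnnotationMap:
    """Mapping of protein identifier -> set of labels.

    One container serves three uses: GO-term annotations, domain
    assignments and protein-complex memberships.  Proteins without any
    label are simply absent (an entry never maps to an empty set).
    """

    entries: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean = {p: frozenset(ls) for p, ls in self.entries.items() if ls}
        object.__setattr__(self, "entries", clean)

    @property
    def label_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for labels in self.entries.values():
            out |= labels
        return frozenset(out)

    def labels(self, protein: str) -> frozenset[str]:
        """Labels of *protein*; empty set if unannotated."""
        return self.entries.get(protein, frozenset())

    def restrict(self, proteins: Iterable[str]) -> "AnnotationMap":
        keep = set(proteins)
        return AnnotationMap({p: ls for p, ls in self.entries.items() if p in keep})

    def without(self, proteins: Iterable[str]) -> "AnnotationMap":
        """Copy with the given proteins' labels masked (used by cross-validation)."""
        drop = set(proteins)
        return AnnotationMap({p: ls for p, ls in self.entries.items() if p not in drop})

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, protein: str) -> bool:
        return protein in self.entries


@dataclass
class Dataset:
    """The four harmonized inputs: PIN plus GO / domain / complex annotations."""

    pin: nx.Graph
    go: AnnotationMap
    domains: AnnotationMap
    complexes: AnnotationMap
    load_report: dict = field(default_factory=dict)


def _new_network() -> nx.Graph:
    return nx.Graph()


def read_edge_list(path: str | Path, dialect: str = "simple2col",
                   include_genetic: bool = True) -> nx.Graph:
    """Read an undirected PIN from *path*.

    ``dialect="simple2col"`` expects two identifier columns per row
    (tab, comma or whitespace separated).  ``dialect="biogrid_tab"``
    expects a header naming the two systematic-name columns of a BioGRID
    TAB export; *include_genetic* optionally drops rows whose
    ``Experimental System Type`` column says ``genetic``.

    Self-interactions and repeated interactions are removed; every kept
    edge gets weight 1.0.  A load report is logged.
    """
    path = Path(path)
    raw_pairs: list[tuple[str, str]] = []
    if dialect == "simple2col":
        raw_pairs = _read_simple_pairs(path)
    elif dialect == "biogrid_tab":
        raw_pairs = _read_biogrid_pairs(path, include_genetic)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    net = _new_network()
    duplicates = 0
    self_loops = 0
    for a, b in raw_pairs:
        if a == b:
            self_loops += 1
            continue
        if net.has_edge(a, b):
            duplicates += 1
            continue
        net.add_edge(a, b, weight=1.0)
    logger.info(
        "loaded %s: %d nodes, %d edges (%d duplicates, %d self-loops dropped)",
        path.name, net.number_of_nodes(), net.number_of_edges(),
        duplicates, self_loops,
    )
    net.graph["load_report"] = {
        "nodes": net.number_of_nodes(),
        "edges": net.number_of_edges(),
        "duplicates_dropped": duplicates,
        "self_loops_dropped": self_loops,
    }
    return net


def _read_simple_pairs(path: Path) -> list[tuple[str, str]]:
    pairs = []
    delim: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if delim is None:
                delim = _detect_delimiter(line)
            parts = _split(line, delim)
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise FormatError(f"{path}:{lineno}: expected two identifier columns")
            pairs.append((parts[0], parts[1]))
    if not pairs:
        raise FormatError(f"{path}: no interactions found")
    return pairs


# Column headers as printed by BioGRID TAB 2/3 exports.
_BIOGRID_A = "Systematic Name Interactor A"
_BIOGRID_B = "Systematic Name Interactor B"
_BIOGRID_TYPE = "Experimental System Type"


def _read_biogrid_pairs(path: Path, include_genetic: bool) -> list[tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise FormatError(f"{path}: empty file")
        header = [h.strip() for h in header_line.split("\t")]
        try:
            ia = header.index(_BIOGRID_A)
            ib = header.index(_BIOGRID_B)
        except ValueError as exc:
            raise FormatError(
                f"{path}: missing systematic-name columns in BioGRID header"
            ) from exc
        itype = header.index(_BIOGRID_TYPE) if _BIOGRID_TYPE in header else None
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = [p.strip() for p in line.rstrip("\n").split("\t")]
            if len(parts) <= max(ia, ib):
                raise FormatError(f"{path}:{lineno}: truncated row")
            if (not include_genetic and itype is not None
                    and len(parts) > itype and parts[itype].lower() == "genetic"):
                continue
            pairs.append((parts[ia], parts[ib]))
    if not pairs:
        raise FormatError(f"{path}: no interactions found")
    return pairs


_GAF_ASPECTS = {"P", "F", "C"}


def read_annotations(path: str | Path, dialect: str = "two_col",
                     aspect: str | None = None) -> AnnotationMap:
    """Read protein -> label annotations.

    ``two_col``: protein and label per row.  ``gaf``: GAF 2.x; column 2 is
    the object identifier, column 5 the ontology term, column 9 the aspect
    (``P``/``F``/``C``); rows are filtered to *aspect* when given, and
    ``!``-comment lines are skipped.
    """
    path = Path(path)
    entries: dict[str, set[str]] = {}
    if dialect == "two_col":
        delim: str | None = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                if delim is None:
                    delim = _detect_delimiter(line)
                parts = _split(line, delim)
                if len(parts) < 2 or not parts[0] or not parts[1]:
                    raise FormatError(f"{path}:{lineno}: expected protein and label")
                entries.setdefault(parts[0], set()).add(parts[1])
    elif dialect == "gaf":
        if aspect is not None and aspect not in _GAF_ASPECTS:
            raise ValueError(f"unknown GO aspect code: {aspect!r}")
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("!"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9:
                    raise FormatError(f"{path}:{lineno}: GAF row has <9 columns")
                if aspect is not None and parts[8].strip() != aspect:
                    continue
                protein = parts[1].strip()
                term = parts[4].strip()
                if protein and term:
                    entries.setdefault(protein, set()).add(term)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    return AnnotationMap({p: frozenset(ls) for p, ls in entries.items()})


def read_complexes(path: str | Path) -> AnnotationMap:
    """Read complex membership, one complex per line, members delimited.

    Lines of the form ``CPX1<TAB>p1 p2 p3`` declare a complex identifier
    (first token ending in nothing special -- a declared id is any first
    column when the line is tab-split into exactly two fields); otherwise
    the 1-based line index names the complex.  Complexes with fewer than
    two members are kept with a warning (membership counts remain defined).
    """
    path = Path(path)
    entries: dict[str, set[str]] = {}
    n_complexes = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if "\t" in line and len(line.split("\t")) == 2:
                cid, member_str = line.split("\t")
                cid = cid.strip()
                members = member_str.split()
            else:
                cid = f"complex_{lineno}"
                members = line.split()
            members = [m.strip() for m in members if m.strip()]
            if not members:
                continue
            if len(members) < 2:
                logger.warning("%s:%d: complex %s has <2 members", path, lineno, cid)
            n_complexes += 1
            for m in members:
                entries.setdefault(m, set()).add(cid)
    return AnnotationMap({p: frozenset(ls) for p, ls in entries.items()})


def write_weighted_edges(net: nx.Graph, path: str | Path) -> None:
    """Write *net* as a three-column TSV (id1, id2, weight), full precision.

    Each undirected edge appears once with id1 < id2 lexicographically;
    rows are sorted so output is canonical and byte-reproducible.
    """
    rows = []
    for a, b, data in net.edges(data=True):
        lo, hi = (a, b) if a <= b else (b, a)
        rows.append((lo, hi, float(data.get("weight", 1.0))))
    rows.sort()
    with open(path, "w") as fh:
        for lo, hi, w in rows:
            fh.write(f"{lo}\t{hi}\t{w!r}\n")
        # isolated nodes would be lost on round-trip; record them explicitly
        isolated = sorted(n for n in net.nodes if net.degree(n) == 0)
        for n in isolated:
            fh.write(f"#node\t{n}\n")


def read_weighted_edges(path: str | Path) -> nx.Graph:
    """Read a three-column weighted edge list written by :func:`write_weighted_edges`."""
    net = _new_network()
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#node\t"):
                net.add_node(line.split("\t")[1])
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
            if w < 0:
                raise FormatError(f"{path}:{lineno}: negative weight")
            if parts[0] != parts[1]:
                net.add_edge(parts[0], parts[1], weight=w)
    return net


def write_annotations(ann: AnnotationMap, path: str | Path) -> None:
    """Write an AnnotationMap as sorted two-column TSV."""
    with open(path, "w") as fh:
        for protein in sorted(ann.entries):
            for label in sorted(ann.entries[protein]):
                fh.write(f"{protein}\t{label}\n")


def write_complexes(ann: AnnotationMap, path: str | Path) -> None:
    """Write complex membership, one ``id<TAB>members`` line per complex."""
    by_complex: dict[str, list[str]] = {}
    for protein, cids in ann.entries.items():
        for cid in cids:
            by_complex.setdefault(cid, []).append(protein)
    with open(path, "w") as fh:
        for cid in sorted(by_complex):
            members = " ".join(sorted(by_complex[cid]))
            fh.write(f"{cid}\t{members}\n")


def harmonize(pin: nx.Graph, go: AnnotationMap, domains: AnnotationMap,
              complexes: AnnotationMap) -> Dataset:
    """Restrict all annotation maps to proteins present in the PIN.

    Unmatched records are counted in the load report and logged, never
    fatal; harmonization never invents nodes.
    """
    nodes = set(pin.nodes)
    report = {}
    out = []
    for name, ann in (("go", go), ("domains", domains), ("complexes", complexes)):
        restricted = ann.restrict(nodes)
        dropped = len(ann) - len(restricted)
        if dropped:
            logger.info("harmonize: dropped %d %s entries absent from the PIN",
                        dropped, name)
        report[f"{name}_entries"] = len(restricted)
        report[f"{name}_dropped"] = dropped
        out.append(restricted)
    report["pin_nodes"] = pin.number_of_nodes()
    report["pin_edges"] = pin.number_of_edges()
    return Dataset(pin=pin, go=out[0], domains=out[1], complexes=out[2],
                   load_report=report)
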