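"""Cross-validation harness: GO filtering, LOOCV, ten-fold CV, curves.

Evaluation follows the standard protocol for network-based function
prediction: the tested proteins stay in every network (topology, domains
and complexes carry no annotation knowledge) -- only their GO labels are
masked while predicting.  Predicted and known term sets are compared
exactly (no ontology-aware partial credit).

Reported quantities:

* per-protein precision / recall / F-measure and their macro averages
  (mean over evaluated proteins), plus pooled micro-averages and the
  harmonic mean of the macro P and R, labelled distinctly;
* match categories -- MP (at least one known function hit), PMP (every
  known function hit), MMP (no hit at all), ZP (no false prediction,
  i.e. a non-empty predicted set fully inside the known set);
* precision--recall and FP/TP curve points as the cutoff K varies;
* a neighbour-counting baseline that ranks functions by how many direct
  PIN neighbours carry them.

Proteins for which no prediction can be made score TP=0, FP=0,
FN=|known| and fall in the MMP category, so every evaluated protein is
accounted for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .data_io import AnnotationMap, Dataset
from .correlation import build_triplet
from .propagation import (DEFAULT_ALPHA, DEFAULT_EPSILON, DEFAULT_MAX_ITER,
                          DEFAULT_TOL, PropagationNetwork,
                          build_propagation_network)
from .prediction import (DEFAULT_BETA, NoCandidatesError, PredictionRecord,
                         predict)

__all__ = [
    "ConfusionCounts",
    "EvalRecord",
    "EvaluationReport",
    "filter_go_terms",
    "compute_prf",
    "match_categories",
    "build_report",
    "prepare_network",
    "loocv",
    "ten_fold_cv",
    "curve_points",
    "nc_baseline",
    "nc_records",
]

DEFAULT_MIN_TERM = 10   # drop GO terms annotating fewer proteins
DEFAULT_MAX_TERM = 200  # ... or more proteins than this


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int


@dataclass
class EvalRecord:
    """One evaluated protein: truth, full ranking, reported prediction."""

    target: str
    known: frozenset[str]
    ranked: tuple[tuple[str, float], ...] = ()
    predicted: frozenset[str] = frozenset()
    k: int = 0
    module_fitness: float = 0.0

    @property
    def counts(self) -> ConfusionCounts:
        tp = len(self.predicted & self.known)
        return ConfusionCounts(tp=tp, fp=len(self.predicted) - tp,
                               fn=len(self.known) - tp)


@dataclass
class EvaluationReport:
    per_protein: list[EvalRecord]
    aggregate: dict[str, float]
    categories: dict[str, int]
    fold_stats: dict[str, float] = field(default_factory=dict)


def filter_go_terms(go: AnnotationMap, min_n: int = DEFAULT_MIN_TERM,
                    max_n: int = DEFAULT_MAX_TERM) -> AnnotationMap:
    """Keep terms annotated to between *min_n* and *max_n* proteins inclusive.

    Proteins left without any surviving term disappear from the map.
    """
    if min_n > max_n:
        raise ValueError("min_n must not exceed max_n")
    counts: dict[str, int] = {}
    for labels in go.entries.values():
        for t in labels:
            counts[t] = counts.get(t, 0) + 1
    keep = {t for t, c in counts.items() if min_n <= c <= max_n}
    return AnnotationMap({p: ls & keep for p, ls in go.entries.items()
                          if ls & keep})


def compute_prf(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall, F-measure with the 0/0 -> 0 convention."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def match_categories(records: Iterable[tuple[frozenset, frozenset]],
                     ) -> dict[str, int]:
    """Count MP / PMP / MMP / ZP over (predicted, known) pairs.

    Every record must have a non-empty known set; MP + MMP equals the
    number of records.
    """
    mp = pmp = mmp = zp = 0
    for pred, known in records:
        if not known:
            raise ValueError("known set must be non-empty")
        hit = len(pred & known)
        if hit:
            mp += 1
        else:
            mmp += 1
        if known <= pred:
            pmp += 1
        if pred and pred <= known:
            zp += 1
    return {"MP": mp, "PMP": pmp, "MMP": mmp, "ZP": zp}


def build_report(records: Sequence[EvalRecord]) -> EvaluationReport:
    """Aggregate per-protein confusion counts into the full report."""
    ps, rs, fs = [], [], []
    tp_tot = fp_tot = fn_tot = 0
    for rec in records:
        c = rec.counts
        p, r, f = compute_prf(c)
        ps.append(p)
        rs.append(r)
        fs.append(f)
        tp_tot += c.tp
        fp_tot += c.fp
        fn_tot += c.fn
    n = len(records)
    macro_p = float(np.mean(ps)) if n else 0.0
    macro_r = float(np.mean(rs)) if n else 0.0
    macro_f = float(np.mean(fs)) if n else 0.0
    micro = compute_prf(ConfusionCounts(tp=tp_tot, fp=fp_tot, fn=fn_tot))
    harm = (2 * macro_p * macro_r / (macro_p + macro_r)
            if macro_p + macro_r else 0.0)
    aggregate = {
        "precision": macro_p,
        "recall": macro_r,
        "f_measure": macro_f,
        "f_of_means": harm,
        "micro_precision": micro[0],
        "micro_recall": micro[1],
        "micro_f_measure": micro[2],
        "n_evaluated": float(n),
        "tp": float(tp_tot), "fp": float(fp_tot), "fn": float(fn_tot),
    }
    categories = match_categories((r.predicted, r.known) for r in records)
    return EvaluationReport(per_protein=list(records), aggregate=aggregate,
                            categories=categories)


def prepare_network(dataset: Dataset, alpha: float = DEFAULT_ALPHA,
                    tol: float = DEFAULT_TOL,
                    max_iter: int = DEFAULT_MAX_ITER,
                    epsilon: float = DEFAULT_EPSILON) -> PropagationNetwork:
    """Correlation triplet + propagation, GO-independent, built once per CV."""
    triplet = build_triplet(dataset)
    return build_propagation_network(triplet, alpha=alpha, tol=tol,
                                     max_iter=max_iter, epsilon=epsilon)


def _predict_masked(v: str, known: frozenset[str], pn: PropagationNetwork,
                    go_visible: AnnotationMap, beta: float) -> EvalRecord:
    try:
        rec: PredictionRecord = predict(v, pn, go_visible, beta=beta)
    except NoCandidatesError:
        return EvalRecord(target=v, known=known)
    return EvalRecord(target=v, known=known, ranked=rec.candidate_functions,
                      predicted=rec.predicted, k=rec.k,
                      module_fitness=rec.module_fitness)


def loocv(dataset: Dataset, pn: PropagationNetwork | None = None,
          beta: float = DEFAULT_BETA, alpha: float = DEFAULT_ALPHA,
          tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
          epsilon: float = DEFAULT_EPSILON,
          min_term: int = DEFAULT_MIN_TERM, max_term: int = DEFAULT_MAX_TERM,
          ) -> EvaluationReport:
    """Leave-one-out cross-validation over all annotated proteins.

    Each annotated protein in turn has its GO labels masked (it stays in
    every network) and is predicted from the remaining annotations.  The
    iteration order is sorted, so the report does not depend on storage
    order.
    """
    if pn is None:
        pn = prepare_network(dataset, alpha=alpha, tol=tol,
                             max_iter=max_iter, epsilon=epsilon)
    go_f = filter_go_terms(dataset.go, min_term, max_term)
    records = []
    for v in sorted(go_f.entries):
        known = go_f.labels(v)
        records.append(_predict_masked(v, known, pn, go_f.without([v]), beta))
    return build_report(records)


def ten_fold_cv(dataset: Dataset, pn: PropagationNetwork | None = None,
                repeats: int = 100, seed: int = 0, n_folds: int = 10,
                beta: float = DEFAULT_BETA, alpha: float = DEFAULT_ALPHA,
                tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
                epsilon: float = DEFAULT_EPSILON,
                min_term: int = DEFAULT_MIN_TERM,
                max_term: int = DEFAULT_MAX_TERM) -> EvaluationReport:
    """Repeated ten-fold cross-validation.

    Per repeat, annotated proteins are partitioned into *n_folds* random
    folds (sizes differing by at most 1); each test fold's annotations
    are masked jointly and its proteins predicted from the rest.
    ``fold_stats`` carries mean and standard deviation of the per-fold
    macro precision / recall / F over all folds x repeats.  The report's
    per-protein records come from the last repeat.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if pn is None:
        pn = prepare_network(dataset, alpha=alpha, tol=tol,
                             max_iter=max_iter, epsilon=epsilon)
    go_f = filter_go_terms(dataset.go, min_term, max_term)
    proteins = sorted(go_f.entries)
    rng = np.random.default_rng(seed)
    fold_p, fold_r, fold_f = [], [], []
    last_records: list[EvalRecord] = []
    for _ in range(repeats):
        perm = rng.permutation(len(proteins))
        folds = np.array_split(perm, n_folds)
        records: list[EvalRecord] = []
        for fold in folds:
            test = [proteins[i] for i in fold]
            visible = go_f.without(test)
            fold_records = [
                _predict_masked(v, go_f.labels(v), pn, visible, beta)
                for v in sorted(test)
            ]
            rep = build_report(fold_records)
            fold_p.append(rep.aggregate["precision"])
            fold_r.append(rep.aggregate["recall"])
            fold_f.append(rep.aggregate["f_measure"])
            records.extend(fold_records)
        last_records = records
    report = build_report(sorted(last_records, key=lambda r: r.target))
    report.fold_stats = {
        "precision_mean": float(np.mean(fold_p)),
        "precision_std": float(np.std(fold_p, ddof=1)) if len(fold_p) > 1 else 0.0,
        "recall_mean": float(np.mean(fold_r)),
        "recall_std": float(np.std(fold_r, ddof=1)) if len(fold_r) > 1 else 0.0,
        "f_measure_mean": float(np.mean(fold_f)),
        "f_measure_std": float(np.std(fold_f, ddof=1)) if len(fold_f) > 1 else 0.0,
        "n_folds": float(len(fold_p)),
    }
    return report


def curve_points(records: Sequence[EvalRecord], k_range: Iterable[int],
                 ) -> dict[str, list[tuple[float, float]]]:
    """Precision--recall and FP/TP curve points as the cutoff K varies.

    For each K, every protein's ranking is truncated at K and the macro
    precision / recall recomputed.  Returns ``{"pr": [(recall, precision),
    ...], "fp_tp": [(K, FP/TP), ...]}``; an FP/TP point is omitted when
    TP is 0 at that K.
    """
    pr: list[tuple[float, float]] = []
    fp_tp: list[tuple[float, float]] = []
    for k in k_range:
        ps, rs = [], []
        tp_tot = fp_tot = 0
        for rec in records:
            pred = frozenset(f for f, _ in rec.ranked[:k])
            tp = len(pred & rec.known)
            fp = len(pred) - tp
            fn = len(rec.known) - tp
            p, r, _ = compute_prf(ConfusionCounts(tp=tp, fp=fp, fn=fn))
            ps.append(p)
            rs.append(r)
            tp_tot += tp
            fp_tot += fp
        pr.append((float(np.mean(rs)) if rs else 0.0,
                   float(np.mean(ps)) if ps else 0.0))
        if tp_tot > 0:
            fp_tp.append((float(k), fp_tot / tp_tot))
    return {"pr": pr, "fp_tp": fp_tp}


def nc_baseline(v: str, pin, go: AnnotationMap) -> list[tuple[str, float]]:
    """Neighbour-counting baseline: score = number of direct PIN
    neighbours of *v* annotated with each function, ranked descending
    (ties by function identifier)."""
    if v not in pin:
        return []
    scores: dict[str, float] = {}
    for u in pin.neighbors(v):
        for f in go.labels(u):
            scores[f] = scores.get(f, 0.0) + 1.0
    return sorted(scores.items(), key=lambda it: (-it[1], it[0]))


def nc_records(dataset: Dataset, min_term: int = DEFAULT_MIN_TERM,
               max_term: int = DEFAULT_MAX_TERM) -> list[EvalRecord]:
    """LOOCV-style records for the neighbour-counting baseline.

    Each annotated protein's labels are masked and its PIN neighbourhood
    vote recorded.  The baseline annotates a target with every function
    its neighbours carry, so ``predicted`` is the full positive-count
    set; curve evaluation re-truncates the ranking at each K.
    """
    go_f = filter_go_terms(dataset.go, min_term, max_term)
    records = []
    for v in sorted(go_f.entries):
        ranked = nc_baseline(v, dataset.pin, go_f.without([v]))
        records.append(EvalRecord(target=v, known=go_f.labels(v),
                                  ranked=tuple(ranked),
                                  predicted=frozenset(f for f, _ in ranked)))
    return records
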