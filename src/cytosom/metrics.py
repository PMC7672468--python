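"""Clustering-quality validation against gated ground truth.

Follows the standard cytometry benchmarking methodology: cluster labels
(e.g. SOM node assignments) are matched to manually gated populations and
summarized by the mean F1 score. Each cluster is greedily assigned to the
population holding the greatest part of that cluster (several clusters may
aggregate onto one population), then per-population precision/recall/F1
are computed event-wise on the aggregated clusters and averaged
(unweighted) over all ground-truth populations. This is deliberately the
simple greedy matching, not the best-case assignment optimization some
benchmarks use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np

__all__ = [
    "ContingencyTable",
    "contingency",
    "greedy_assign",
    "mean_f1",
    "evaluate_clustering",
]


@dataclass
class ContingencyTable:
    """Cluster × population event-count matrix over gated events."""

    counts: np.ndarray  # C × P int64
    cluster_ids: list
    population_ids: list

    @property
    def n_events(self) -> int:
        return int(self.counts.sum())

    def normalized_rows(self) -> np.ndarray:
        """Row-normalized counts (confusion-matrix style view)."""
        tot = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.counts / tot, 0.0)


def contingency(cluster_labels: Sequence, truth_labels: Sequence,
                ungated: Hashable | None = None) -> ContingencyTable:
    """Tally events by (cluster, population).

    Events whose truth label equals ``ungated`` are excluded before the
    tally — unassigned/ungated cells should not count for or against any
    cluster. Ids are sorted, which fixes the canonical tie-break order.
    """
    cl = np.asarray(cluster_labels)
    tr = np.asarray(truth_labels)
    if cl.shape != tr.shape or cl.ndim != 1:
        raise ValueError(
            f"label vectors must be equal-length 1-D ({cl.shape} vs {tr.shape})"
        )
    if ungated is not None:
        keep = tr != ungated
        cl, tr = cl[keep], tr[keep]
    if cl.size == 0:
        warnings.warn("no gated events; contingency table is empty",
                      RuntimeWarning, stacklevel=2)
        return ContingencyTable(np.zeros((0, 0), dtype=np.int64), [], [])
    cids, ci = np.unique(cl, return_inverse=True)
    pids, pi = np.unique(tr, return_inverse=True)
    counts = np.zeros((len(cids), len(pids)), dtype=np.int64)
    np.add.at(counts, (ci, pi), 1)
    return ContingencyTable(counts=counts, cluster_ids=list(cids),
                            population_ids=list(pids))


def greedy_assign(table: ContingencyTable) -> dict:
    """Map each nonempty cluster to the population covering most of it.

    Row-wise argmax of the counts (equivalently of within-cluster
    fractions); ties go to the lowest population index in the table's
    canonical (sorted) order. Clusters may share a population.
    """
    if table.counts.size == 0:
        raise ValueError("cannot assign clusters of an empty table")
    best = np.argmax(table.counts, axis=1)  # first maximum → lowest index
    return {
        table.cluster_ids[c]: table.population_ids[best[c]]
        for c in range(table.counts.shape[0])
        if table.counts[c].sum() > 0
    }


def mean_f1(table: ContingencyTable, assignment: dict | None = None,
            weighted: bool = False, include_unmatched: bool = True) -> float:
    """Mean F1 between aggregated clusters and ground-truth populations.

    Clusters mapped to the same population are aggregated into one
    predicted population; per population p, precision = TP/(TP+FP) and
    recall = TP/(TP+FN) are computed event-wise and F1_p = 2PR/(P+R)
    (0 when P+R = 0). The default is the unweighted mean over all
    ground-truth populations, counting populations no cluster was assigned
    to as F1 = 0 (set ``include_unmatched=False`` to drop them, or
    ``weighted=True`` for an event-count-weighted mean).
    """
    if table.counts.size == 0:
        raise ValueError("mean F1 of an empty table is undefined")
    if assignment is None:
        assignment = greedy_assign(table)
    P = len(table.population_ids)
    pop_pos = {p: i for i, p in enumerate(table.population_ids)}
    # aggregate rows by assigned population
    pred = np.zeros((P, P), dtype=np.int64)  # predicted-pop × true-pop
    matched = np.zeros(P, dtype=bool)
    for c, row in zip(table.cluster_ids, table.counts):
        if row.sum() == 0:
            continue
        q = pop_pos[assignment[c]]
        pred[q] += row
        matched[q] = True

    tp = np.diag(pred).astype(np.float64)
    fp = pred.sum(axis=1) - tp
    fn = pred.sum(axis=0) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    f1 = np.where(matched, f1, 0.0)

    sel = np.ones(P, dtype=bool) if include_unmatched else matched
    if not np.any(sel):
        return 0.0
    if weighted:
        w = table.counts.sum(axis=0).astype(np.float64)[sel]
        return float((f1[sel] * w).sum() / w.sum()) if w.sum() > 0 else 0.0
    return float(f1[sel].mean())


def evaluate_clustering(cluster_labels: Sequence, truth_labels: Sequence,
                        ungated: Hashable | None = None) -> dict:
    """Full greedy-F1 report: mean F1, per-population F1, confusion view."""
    table = contingency(cluster_labels, truth_labels, ungated=ungated)
    assignment = greedy_assign(table)
    # per-population F1 via the same aggregation as mean_f1
    P = len(table.population_ids)
    pop_pos = {p: i for i, p in enumerate(table.population_ids)}
    pred = np.zeros((P, P), dtype=np.int64)
    for c, row in zip(table.cluster_ids, table.counts):
        if row.sum() > 0:
            pred[pop_pos[assignment[c]]] += row
    tp = np.diag(pred).astype(np.float64)
    fp = pred.sum(axis=1) - tp
    fn = pred.sum(axis=0) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    return {
        "mean_f1": mean_f1(table, assignment),
        "per_population_f1": {
            str(p): float(f1[i]) for i, p in enumerate(table.population_ids)
        },
        "assignment": {str(k): str(v) for k, v in assignment.items()},
        "n_events": table.n_events,
        "normalized_confusion": table.normalized_rows().tolist(),
    }
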