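"""Precision/recall machinery against a gold standard of known interactions.

The evaluable universe is the set of ordered non-self gene pairs over the
evaluable genes; interactions absent from the gold standard are treated as
negatives (a closed world, as ChIP-derived standards are conventionally
scored).  Early metrics report the curve at the smallest prediction cutoff
reaching a partial recall threshold, emphasizing the top-ranked —
experimentally most actionable — interactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .io_formats import GoldStandard, RankedEdgeList, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PRCurve",
    "EvalSummary",
    "precision_recall",
    "average_precision",
    "early_metrics",
    "accuracy_at_cutoff",
    "random_control",
    "evaluate",
    "compare_average_precision",
]


@dataclass
class PRCurve:
    """Cumulative precision/recall over prediction ranks 1..m.

    P is the number of gold edges in the evaluable universe and M the
    universe size G*(G-1) over evaluable genes.
    """

    k: np.ndarray
    tp: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    P: int
    M: int

    def __post_init__(self) -> None:
        if self.P <= 0:
            raise ValidationError("curve needs at least one positive")
        if np.any(np.diff(self.recall) < 0):
            raise ValidationError("recall must be non-decreasing")
        if np.any(self.tp > np.minimum(self.k, self.P)):
            raise ValidationError("tp cannot exceed min(k, P)")


@dataclass
class EvalSummary:
    average_precision: float
    early_precision: float
    early_recall: float
    early_accuracy: float
    accuracy: float
    recall_threshold: float
    accuracy_cutoff: int


def precision_recall(
    predicted: RankedEdgeList, gold: GoldStandard, gene_ids=None
) -> PRCurve:
    """Cumulative PR curve of a ranked prediction against the gold standard.

    ``gene_ids``, when given, restricts the evaluable universe to the
    analyzed gene set; otherwise every gene mentioned by the predictions or
    the gold standard is evaluable.  Predictions and gold edges outside
    the universe are excluded symmetrically.
    """
    if gene_ids is None:
        genes = {g for r, t in gold.edges for g in (r, t)}
        genes |= {g for r, t, _, _ in predicted.records for g in (r, t)}
    else:
        genes = set(gene_ids)
    gold_edges = {
        (r, t) for r, t in gold.edges if r in genes and t in genes
    }
    if not gold_edges:
        raise ValidationError("no gold edges within the evaluable universe")
    pred = [
        (r, t)
        for r, t, _, _ in predicted.records
        if r in genes and t in genes
    ]
    P = len(gold_edges)
    G = len(genes)
    M = G * (G - 1)
    hits = np.fromiter(
        ((r, t) in gold_edges for r, t in pred), dtype=bool, count=len(pred)
    )
    tp = np.cumsum(hits)
    k = np.arange(1, len(pred) + 1)
    return PRCurve(
        k=k,
        tp=tp,
        precision=tp / k if len(pred) else np.array([]),
        recall=tp / P if len(pred) else np.array([]),
        P=P,
        M=M,
    )


def average_precision(curve: PRCurve) -> float:
    """AP = sum of precision at each rank where a positive is gained, / P."""
    if len(curve.k) == 0:
        return 0.0
    gained = np.diff(np.concatenate([[0], curve.tp])) > 0
    return float(curve.precision[gained].sum() / curve.P)


def _accuracy(curve: PRCurve, i: int) -> float:
    k = int(curve.k[i])
    tp = int(curve.tp[i])
    tn = (curve.M - k) - (curve.P - tp)
    return (tp + tn) / curve.M


def early_metrics(curve: PRCurve, recall_threshold: float):
    """Precision, recall and accuracy at the earliest rank reaching recall.

    ``k*`` is the smallest cutoff with recall >= threshold; when the curve
    never reaches the threshold the metrics at the final rank are returned
    with a warning.
    """
    if not 0 < recall_threshold <= 1:
        raise ValidationError("recall threshold must be in (0, 1]")
    if len(curve.k) == 0:
        raise ValidationError("empty prediction list")
    reached = np.nonzero(curve.recall >= recall_threshold)[0]
    if len(reached) == 0:
        logger.warning(
            "recall threshold %.3g unreachable (final recall %.3g); "
            "reporting metrics at the final rank",
            recall_threshold,
            curve.recall[-1],
        )
        i = len(curve.k) - 1
    else:
        i = int(reached[0])
    return (
        float(curve.precision[i]),
        float(curve.recall[i]),
        float(_accuracy(curve, i)),
    )


def accuracy_at_cutoff(curve: PRCurve, k: int) -> float:
    """(tp + tn)/M at cutoff k, tn = (M - k) - (P - tp(k))."""
    if not 1 <= k <= len(curve.k):
        raise ValidationError(f"cutoff {k} outside 1..{len(curve.k)}")
    return float(_accuracy(curve, k - 1))


def random_control(gene_ids, n_edges: int, seed: int = 0) -> RankedEdgeList:
    """A uniformly random network: n_edges ordered non-self pairs, random order."""
    gene_ids = list(gene_ids)
    G = len(gene_ids)
    M = G * (G - 1)
    if n_edges > M:
        raise ValidationError(f"cannot draw {n_edges} edges from {M} pairs")
    rng = np.random.default_rng(seed)
    idx = rng.choice(M, size=n_edges, replace=False)
    edges = []
    for x in idx:
        i, r = divmod(int(x), G - 1)
        j = r if r < i else r + 1
        edges.append((gene_ids[i], gene_ids[j]))
    order = rng.permutation(n_edges)
    return RankedEdgeList.from_scores(
        (edges[i][0], edges[i][1], float(n_edges - pos))
        for pos, i in enumerate(order)
    )


def evaluate(
    predicted: RankedEdgeList,
    gold: GoldStandard,
    recall_threshold: float = 0.1,
    at_k: int | None = None,
    gene_ids=None,
) -> EvalSummary:
    """One-call summary: AP, early metrics, and accuracy at a cutoff.

    The accuracy cutoff defaults to P, the gold-standard size within the
    evaluable universe (capped at the number of predictions).
    """
    curve = precision_recall(predicted, gold, gene_ids)
    ep, er, ea = early_metrics(curve, recall_threshold)
    if at_k is None:
        at_k = min(curve.P, len(curve.k))
    return EvalSummary(
        average_precision=average_precision(curve),
        early_precision=ep,
        early_recall=er,
        early_accuracy=ea,
        accuracy=accuracy_at_cutoff(curve, at_k),
        recall_threshold=recall_threshold,
        accuracy_cutoff=at_k,
    )


def compare_average_precision(ap_a, ap_b):
    """Welch two-sample t-test on replicate average precisions.

    Returns (mean_a, sd_a, mean_b, sd_b, t, p).  Used to compare a method's
    replicate APs against another method or the random control.
    """
    a = np.asarray(ap_a, dtype=float)
    b = np.asarray(ap_b, dtype=float)
    t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
    return (
        float(a.mean()),
        float(a.std(ddof=1)),
        float(b.mean()),
        float(b.std(ddof=1)),
        float(t),
        float(p),
    )
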