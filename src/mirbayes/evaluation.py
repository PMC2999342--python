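"""Evaluation of ranked target predictions.

Precision-recall curves over every rank cut, cumulative sums of an
auxiliary per-gene measurement (e.g. protein-level down-regulation)
over the top-k predictions, and the classical "overlap" baseline that
calls targets as the intersection of score-positive and down-regulated
genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import EvaluationError
from .io_formats import ExpressionProfile, ScoreTable, align_genes

logger = logging.getLogger(__name__)

__all__ = ["PRCurve", "CumulativeFoldCurve", "OverlapResult", "pr_curve", "cumulative_fold_curve", "overlap_baseline", "rank_only_records"]


@dataclass
class PRCurve:
    """Precision and recall at every rank cut, plus the trapezoid AUC."""

    recall: np.ndarray
    precision: np.ndarray
    auc_pr: float


@dataclass
class CumulativeFoldCurve:
    """Cumulative sum of an auxiliary measurement over top-k predictions."""

    k: np.ndarray
    cumsum: np.ndarray


@dataclass
class OverlapResult:
    """Single-point precision/recall of the intersection baseline."""

    precision: float  # NaN when the predicted set is empty
    recall: float
    n_predicted: int


def _ranked_ids(ranked) -> list[str]:
    return [r if isinstance(r, str) else r.gene_id for r in ranked]


def pr_curve(ranked, truth: set[str]) -> PRCurve:
    """Precision-recall curve of a ranked gene list against a truth set.

    At cut k: precision = |top-k intersect truth| / k and recall =
    |top-k intersect truth| / |truth|. The area is the trapezoid rule
    over recall, with no interpolation.
    """
    if not truth:
        raise ValueError("truth set must be non-empty")
    ids = _ranked_ids(ranked)
    if not ids:
        raise ValueError("ranked list must be non-empty")
    hits = np.array([g in truth for g in ids], dtype=float)
    tp = np.cumsum(hits)
    k = np.arange(1, len(ids) + 1)
    precision = tp / k
    recall = tp / len(truth)
    auc = float(np.trapezoid(precision, recall))
    return PRCurve(recall=recall, precision=precision, auc_pr=auc)


def cumulative_fold_curve(
    ranked, aux_measurements: dict[str, float], k_max: int | None = None
) -> CumulativeFoldCurve:
    """Cumulative sum of aux values over the highest-ranked genes.

    Genes absent from the auxiliary map are skipped (with a warning);
    point k sums the k highest-ranked genes that do have a measurement.
    """
    ids = _ranked_ids(ranked)
    values = [aux_measurements[g] for g in ids if g in aux_measurements]
    n_missing = len(ids) - len(values)
    if not values:
        raise EvaluationError("no ranked gene has an auxiliary measurement")
    if n_missing:
        logger.warning("%d ranked genes lack auxiliary measurements; skipped", n_missing)
    if k_max is not None:
        values = values[:k_max]
    cumsum = np.cumsum(values)
    return CumulativeFoldCurve(k=np.arange(1, len(values) + 1), cumsum=cumsum)


def overlap_baseline(
    scores: ScoreTable,
    score_cut: float,
    profile: ExpressionProfile,
    down_cut: float,
    truth: set[str],
) -> OverlapResult:
    """Intersection baseline: predict genes with s >= score_cut AND e <= down_cut.

    True targets that are not down-regulated are necessarily missed —
    the structural failure mode of requiring down-regulation.
    """
    if not truth:
        raise ValueError("truth set must be non-empty")
    aligned = align_genes(profile, scores)
    predicted = {g for g, e, s in aligned if s >= score_cut and e <= down_cut}
    if not predicted:
        return OverlapResult(precision=math.nan, recall=0.0, n_predicted=0)
    tp = len(predicted & truth)
    return OverlapResult(
        precision=tp / len(predicted),
        recall=tp / len(truth),
        n_predicted=len(predicted),
    )


def rank_only_records(gene_ids, values, descending: bool = True) -> list[str]:
    """Rank gene ids by a single evidence value (baseline rankers).

    ``descending=True`` ranks larger values first (score-only baseline);
    ``descending=False`` ranks smaller first (expression-only baseline,
    where stronger down-regulation should come first). Ties break
    lexicographically.
    """
    values = np.asarray(values, dtype=float)
    key = -values if descending else values
    order = np.lexsort((np.asarray(gene_ids, dtype=object), key))
    return [gene_ids[i] for i in order]
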