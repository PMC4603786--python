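"""Benchmark metrics: per-drug ROC AUC, enrichment factors, cutoff curves.

Ranking quality of a proteome screen is assessed per drug.  The AUC is
the rank-based (Mann-Whitney) probability that a true target outscores a
decoy, with ties counted one half.  The enrichment factor EF_x is the
fraction of all true targets recovered in the top x of the ranked list
divided by x, so EF_x = 1 means random and EF_x = 1/x means every true
target sits in the top fraction.  Precision/recall-vs-cutoff curves
average per-drug values over drugs that still have at least one
prediction at that cutoff — which is what makes average precision sag at
very high cutoffs, as drugs with perfect small predictions drop out of
the average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .screen import ScreeningHit
from .sidefx import InteractionSet


def precision_recall(
    predicted: frozenset | set,
    truth: frozenset | set,
) -> tuple[float | None, float | None]:
    """Set-based precision and recall.

    precision = |predicted & truth| / |predicted|, None if no predictions;
    recall = |predicted & truth| / |truth|, None if the truth is empty.
    Undefined values are returned as None, never coerced to 0.
    """
    tp = len(set(predicted) & set(truth))
    precision = tp / len(predicted) if predicted else None
    recall = tp / len(truth) if truth else None
    return precision, recall


def enrichment_factor(
    ranked: Sequence[ScreeningHit],
    truth: set[str] | frozenset[str],
    x: float,
) -> float:
    """Enrichment factor within the top x fraction of the ranked library.

    EF_x = (true positives in the top ceil(x*N) entries / |truth|) / x.
    Ceiling rounding makes the top 1% of 3,576 targets 36 entries.
    """
    if not truth:
        raise ValueError("truth set is empty")
    if not 0.0 < x <= 1.0:
        raise ValueError("x must be in (0, 1]")
    n = len(ranked)
    top = math.ceil(x * n)
    hits_in_top = sum(1 for h in ranked[:top] if h.target_id in truth)
    return (hits_in_top / len(truth)) / x


def auc_per_drug(
    ranked: Sequence[ScreeningHit],
    truth: set[str] | frozenset[str],
) -> float | None:
    """Mann-Whitney AUC of true targets vs decoys in one drug's ranking.

    Fraction of (positive, negative) pairs in which the positive's mTC is
    higher, ties counted 1/2.  Degenerate truth (no positives or no
    negatives in the ranking) returns None.
    """
    scores = np.array([h.mtc for h in ranked], dtype=float)
    is_pos = np.array([h.target_id in truth for h in ranked], dtype=bool)
    n_pos = int(is_pos.sum())
    n_neg = len(ranked) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    # midrank sum identity: U = R_pos - n_pos(n_pos+1)/2
    ranks = rankdata(scores)
    u = ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass
class EvalCurve:
    """Mean per-drug precision/recall at each score cutoff."""

    cutoffs: list[float]
    mean_precision: list[float | None]
    mean_recall: list[float | None]
    n_drugs_with_predictions: list[int]


def cutoff_curve(
    per_drug_hits: Mapping[str, Sequence[ScreeningHit]],
    truth: InteractionSet,
    cutoffs: Sequence[float],
) -> EvalCurve:
    """Precision/recall vs mTC cutoff, macro-averaged per drug.

    At each cutoff, a drug's predictions are its hits with mTC >= cutoff
    (inclusive).  Per-drug precision and recall are averaged over drugs
    with >= 1 prediction; that count is reported per cutoff, and a cutoff
    where no drug predicts yields None averages.
    """
    cutoffs = list(cutoffs)
    if any(b < a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be ascending")
    mean_p: list[float | None] = []
    mean_r: list[float | None] = []
    counts: list[int] = []
    for c in cutoffs:
        ps, rs = [], []
        for drug, hits in per_drug_hits.items():
            drug_truth = truth.targets_of(drug)
            if not drug_truth:
                continue
            predicted = {h.target_id for h in hits if h.mtc >= c}
            if not predicted:
                continue
            p, r = precision_recall(predicted, drug_truth)
            ps.append(p)
            rs.append(r)
        counts.append(len(ps))
        mean_p.append(sum(ps) / len(ps) if ps else None)
        mean_r.append(sum(rs) / len(rs) if rs else None)
    return EvalCurve(cutoffs, mean_p, mean_r, counts)


def observed_precision_by_truth_count(
    per_drug_precision: Mapping[str, float],
    truth: InteractionSet,
    bins: Sequence[int],
) -> dict[tuple[int, int], float]:
    """Mean observed precision binned by each drug's known-target count.

    ``bins`` gives ascending left edges; drug with k known targets falls
    in [edge_i, edge_{i+1}) and the last bin is open-ended.  Empty bins
    are omitted.  Because the truth list is incomplete in real data, the
    precision observed against it underestimates true precision, and the
    gap narrows for drugs with many known targets — this view makes that
    visible.
    """
    bins = list(bins)
    if any(b <= a for a, b in zip(bins, bins[1:])):
        raise ValueError("bins must be strictly ascending")
    edges = bins + [None]
    acc: dict[tuple[int, int], list[float]] = {}
    for drug, prec in per_drug_precision.items():
        k = len(truth.targets_of(drug))
        for lo, hi in zip(edges[:-1], edges[1:]):
            if k >= lo and (hi is None or k < hi):
                acc.setdefault((lo, -1 if hi is None else hi), []).append(prec)
                break
    return {b: sum(v) / len(v) for b, v in sorted(acc.items())}


def true_target_ranks(
    per_drug_hits: Mapping[str, Sequence[ScreeningHit]],
    truth: InteractionSet,
) -> tuple[float, float]:
    """Average rank of true targets: per-drug-then-over-drugs and pooled.

    Returns (mean over drugs of each drug's mean true-target rank, mean
    over all true (drug, target) pairs).  Both conventions are emitted
    because summary tables are ambiguous about which they use.
    """
    per_drug_means, pooled = [], []
    for drug, hits in per_drug_hits.items():
        ranks = [h.rank for h in hits if h.target_id in truth.targets_of(drug)]
        if ranks:
            per_drug_means.append(sum(ranks) / len(ranks))
            pooled.extend(ranks)
    if not pooled:
        return math.nan, math.nan
    return sum(per_drug_means) / len(per_drug_means), sum(pooled) / len(pooled)


def random_selection_precision(n_interactions: int, n_drugs: int, n_targets: int) -> float:
    """Expected precision of picking targets uniformly at random, in percent.

    The density of true pairs in the full drug x target grid:
    100 * n_interactions / (n_drugs * n_targets).
    """
    if n_drugs <= 0 or n_targets <= 0:
        raise ValueError("counts must be positive")
    return 100.0 * n_interactions / (n_drugs * n_targets)
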