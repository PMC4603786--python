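"""Target side-effect inference, drug side-effect prediction, killing index.

The inference rule is deterministic: if a protein target binds drugs
D_1..D_k with k > 1, the side effects associated with the target are the
terms shared by *all* of those drugs (set intersection).  A drug's
predicted side effects are then the union over its targets' inferred
sets.  Because every inferred term was present in every supporting
drug's record, re-predicting a drug from relations built on all drugs
(the consistency test) can never produce a false positive; the jackknife
test, which rebuilds the relations with the query drug's record held
out, measures genuine predictive power.

The killing index kappa of a drug counts its targets whose inferred side
effects include at least one of eight serious terms (death, sudden
death, sudden cardiac death, cardiac death, cancer, hemorrhagic strokes,
heart failure, congestive heart failure).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: default list of serious side-effect terms behind the killing index
SERIOUS_SIDE_EFFECTS = frozenset(
    {
        "death",
        "sudden death",
        "sudden cardiac death",
        "cardiac death",
        "cancer",
        "hemorrhagic strokes",
        "heart failure",
        "congestive heart failure",
    }
)

_WS = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Canonical form of a side-effect term: lowercased, whitespace-collapsed."""
    out = _WS.sub(" ", term.strip()).lower()
    if not out:
        raise ValueError("empty side-effect term")
    return out


class InteractionSet:
    """A set of (drug_id, target_id) interaction pairs with both indexings."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._pairs: set[tuple[str, str]] = set()
        self._by_drug: dict[str, set[str]] = {}
        self._by_target: dict[str, set[str]] = {}
        for drug, target in pairs:
            self.add(drug, target)

    def add(self, drug: str, target: str) -> None:
        if (drug, target) in self._pairs:
            return
        self._pairs.add((drug, target))
        self._by_drug.setdefault(drug, set()).add(target)
        self._by_target.setdefault(target, set()).add(drug)

    def targets_of(self, drug: str) -> frozenset[str]:
        return frozenset(self._by_drug.get(drug, ()))

    def drugs_of(self, target: str) -> frozenset[str]:
        return frozenset(self._by_target.get(target, ()))

    @property
    def drugs(self) -> frozenset[str]:
        return frozenset(self._by_drug)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(self._by_target)

    def pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._pairs)

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._pairs

    def without_drug(self, drug: str) -> "InteractionSet":
        return InteractionSet(p for p in self._pairs if p[0] != drug)


def load_side_effect_table(path) -> dict[str, frozenset[str]]:
    """Read a two-column TSV (drug_id, side_effect_term) into a mapping."""
    table: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.rstrip("\n").startswith("drug_id"):
            raise ValueError(f"{path}: expected header starting with 'drug_id'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                drug, term = line.split("\t")
                table.setdefault(drug, set()).add(normalize_term(term))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return {d: frozenset(s) for d, s in table.items()}


def normalize_side_effect_table(
    table: Mapping[str, Iterable[str]]
) -> dict[str, frozenset[str]]:
    return {d: frozenset(normalize_term(t) for t in terms) for d, terms in table.items()}


def infer_target_side_effects(
    interactions: InteractionSet,
    drug_se: Mapping[str, frozenset[str]],
) -> dict[str, tuple[frozenset[str], int]]:
    """Infer per-target side effects by intersecting the binders' records.

    For each target with >= 2 interacting drugs that *have* side-effect
    records, the target's term set is the intersection of those drugs'
    sets; the supporting drug count is stored alongside.  Targets with
    fewer than 2 annotated binders, or whose intersection is empty, are
    omitted.  A binder missing from ``drug_se`` is ignored (not treated
    as an empty set, which would annihilate the intersection).
    """
    if len(interactions) == 0:
        raise ValueError("interaction set is empty")
    out: dict[str, tuple[frozenset[str], int]] = {}
    for target in interactions.targets:
        annotated = [d for d in interactions.drugs_of(target) if d in drug_se]
        skipped = len(interactions.drugs_of(target)) - len(annotated)
        if skipped:
            logger.debug("target %s: %d binders without side-effect records ignored", target, skipped)
        if len(annotated) < 2:
            continue
        common: frozenset[str] = frozenset.intersection(*(drug_se[d] for d in annotated))
        if common:
            out[target] = (common, len(annotated))
    return out


def predict_drug_side_effects(
    drug_id: str,
    interactions: InteractionSet,
    target_se: Mapping[str, tuple[frozenset[str], int]],
) -> frozenset[str]:
    """Union of inferred side effects over the drug's targets."""
    terms: set[str] = set()
    for target in interactions.targets_of(drug_id):
        if target in target_se:
            terms |= target_se[target][0]
    return frozenset(terms)


@dataclass
class BenchmarkResult:
    """Per-drug precision/recall plus macro averages.

    Macro averages are taken over drugs with >= 1 predicted term (their
    count is ``n_drugs_with_predictions``); drugs with no prediction are
    excluded rather than counted as zeros.
    """

    per_drug: dict[str, tuple[float, float]]
    macro_precision: float
    macro_recall: float
    n_drugs_with_predictions: int
    n_drugs_evaluated: int


def _aggregate(per_drug: dict[str, tuple[float, float]], n_eval: int) -> BenchmarkResult:
    if per_drug:
        mp = sum(p for p, _ in per_drug.values()) / len(per_drug)
        mr = sum(r for _, r in per_drug.values()) / len(per_drug)
    else:
        mp = mr = math.nan
    return BenchmarkResult(per_drug, mp, mr, len(per_drug), n_eval)


def consistency_test(
    interactions: InteractionSet,
    drug_se: Mapping[str, frozenset[str]],
) -> BenchmarkResult:
    """Rebuild each drug's side effects from relations built on all drugs.

    Target-side-effect relations are inferred from the full table, then
    every annotated drug is re-predicted and scored against its own known
    set.  By construction the predictions are subsets of the known sets,
    so per-drug precision is 1 wherever defined.
    """
    target_se = infer_target_side_effects(interactions, drug_se)
    per_drug: dict[str, tuple[float, float]] = {}
    n_eval = 0
    for drug, known in drug_se.items():
        if not known:
            continue
        n_eval += 1
        predicted = predict_drug_side_effects(drug, interactions, target_se)
        if not predicted:
            continue
        tp = len(predicted & known)
        per_drug[drug] = (tp / len(predicted), tp / len(known))
    return _aggregate(per_drug, n_eval)


def jackknife_test(
    interactions: InteractionSet,
    drug_se: Mapping[str, frozenset[str]],
) -> BenchmarkResult:
    """Leave-one-drug-out benchmark of side-effect prediction.

    For each drug, relations are rebuilt with that drug's side-effect
    record removed, the drug is re-predicted, and the prediction scored
    against the held-out record.
    """
    if len(drug_se) < 2:
        raise ValueError("jackknife requires at least two annotated drugs")
    per_drug: dict[str, tuple[float, float]] = {}
    n_eval = 0
    for drug, known in drug_se.items():
        if not known:
            continue
        n_eval += 1
        reduced = {d: s for d, s in drug_se.items() if d != drug}
        target_se = infer_target_side_effects(interactions, reduced)
        predicted = predict_drug_side_effects(drug, interactions, target_se)
        if not predicted:
            continue
        tp = len(predicted & known)
        per_drug[drug] = (tp / len(predicted), tp / len(known))
    return _aggregate(per_drug, n_eval)


def killing_index(
    drug_id: str,
    interactions: InteractionSet,
    target_se: Mapping[str, tuple[frozenset[str], int]],
    serious: frozenset[str] = SERIOUS_SIDE_EFFECTS,
) -> int:
    """Number of the drug's targets with at least one serious side effect.

    A target with several serious terms still contributes 1: kappa counts
    targets, not terms, so kappa <= the drug's target count always.
    """
    serious = frozenset(normalize_term(t) for t in serious)
    return sum(
        1
        for target in interactions.targets_of(drug_id)
        if target in target_se and target_se[target][0] & serious
    )


@dataclass
class KappaCurve:
    """Cumulative fraction of flagged drugs among those with kappa >= t."""

    thresholds: list[int]
    fractions: list[float]
    cohort_sizes: list[int]
    pearson_r: float


def kappa_fraction_curve(
    flags: Mapping[str, bool],
    kappas: Mapping[str, int],
) -> KappaCurve:
    """Fraction of flagged (withdrawn/illicit/investigational) drugs vs kappa.

    For each threshold t in 0..max(kappa), computes the flagged fraction
    among drugs with kappa >= t; thresholds whose cohort is empty are
    omitted.  Also reports the Pearson correlation of the curve with the
    threshold (NaN when fewer than 2 points or a constant curve).
    """
    drugs = sorted(set(flags) & set(kappas))
    if not drugs:
        raise ValueError("no drugs common to flags and kappas")
    kmax = max(kappas[d] for d in drugs)
    thresholds, fractions, sizes = [], [], []
    for t in range(kmax + 1):
        cohort = [d for d in drugs if kappas[d] >= t]
        if not cohort:
            continue
        thresholds.append(t)
        fractions.append(sum(bool(flags[d]) for d in cohort) / len(cohort))
        sizes.append(len(cohort))
    if len(thresholds) >= 2 and len(set(fractions)) > 1:
        from scipy.stats import pearsonr

        r = float(pearsonr(thresholds, fractions).statistic)
    else:
        r = math.nan
    return KappaCurve(thresholds, fractions, sizes, r)
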