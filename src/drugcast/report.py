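"""End-to-end reports: proteome screen and side-effect/killing-index views.

These tie the modules into the two user-facing workflows: (a) screen a
compound against a target library and flag predicted interactions; (b)
predict a compound's side effects and killing index from its flagged
targets and a drug-side-effect table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .chem import CompoundRecord, tanimoto
from .config import RunConfig
from .screen import (
    ExclusionPolicy,
    ScreeningHit,
    TargetRecord,
    apply_exclusions,
    screen_proteome,
    sequence_identity,
)
from .sidefx import (
    SERIOUS_SIDE_EFFECTS,
    InteractionSet,
    infer_target_side_effects,
    killing_index,
    predict_drug_side_effects,
)

logger = logging.getLogger(__name__)


@dataclass
class ScreenReport:
    query_id: str
    hits: list[ScreeningHit]
    n_predicted: int
    exclusion_audit: dict[str, int] | None


def audit_exclusions(
    query: CompoundRecord,
    library: Sequence[TargetRecord],
    policy: ExclusionPolicy,
    sequences: Mapping[str, str] | None,
) -> dict[str, int]:
    """Recompute the benchmark filter and assert no leaking ligand survives.

    For every target, re-applies the exclusion policy and verifies that
    each surviving template ligand has TC <= the TC cutoff to the query
    and (where sequences are known) source-protein identity <= the
    identity cutoff to the target.  Raises AssertionError on violation;
    returns counts of ligands checked and removed.
    """
    sequences = sequences or {}
    checked = removed = 0
    for target in library:
        kept = apply_exclusions(query, target, target.template_ligands, policy, sequences)
        removed += len(target.template_ligands) - len(kept)
        target_seq = target.sequence or sequences.get(target.target_id)
        for lig in kept:
            checked += 1
            tc = tanimoto(lig.compound.fingerprint, query.fingerprint)
            assert tc <= policy.ligand_tc_cutoff, (
                f"ligand {lig.compound.compound_id} survives with TC {tc:.3f}"
            )
            src_seq = sequences.get(lig.source_protein_id)
            if src_seq is not None and target_seq is not None:
                ident = sequence_identity(src_seq, target_seq)
                assert ident <= policy.seq_identity_cutoff, (
                    f"source {lig.source_protein_id} survives at {ident:.1f}% identity"
                )
    return {"ligands_checked": checked, "ligands_removed": removed}


def run_screen_report(
    query: CompoundRecord,
    library: Sequence[TargetRecord],
    config: RunConfig = RunConfig(),
    sequences: Mapping[str, str] | None = None,
) -> ScreenReport:
    """Rank every library target for the query and flag predictions."""
    policy = ExclusionPolicy(
        seq_identity_cutoff=config.seq_identity_cutoff,
        ligand_tc_cutoff=config.ligand_tc_cutoff,
        enabled=config.benchmark,
    )
    hits = screen_proteome(
        query, library, policy, w=config.w,
        mtc_cutoff=config.mtc_cutoff, sequences=sequences,
    )
    n_pred = sum(h.predicted for h in hits)
    if n_pred == 0:
        logger.warning("no interaction flagged at mTC cutoff %.3f", config.mtc_cutoff)
    audit = None
    if config.benchmark:
        audit = audit_exclusions(query, library, policy, sequences)
    return ScreenReport(query.compound_id, hits, n_pred, audit)


@dataclass
class SideEffectReport:
    query_id: str
    predicted_targets: list[str]
    side_effects: dict[str, list[str]]  # term -> supporting targets
    kappa: int
    kappa_targets: list[str]


def run_sidefx_report(
    query: CompoundRecord,
    library: Sequence[TargetRecord],
    drug_se: Mapping[str, frozenset[str]],
    known_interactions: InteractionSet,
    config: RunConfig = RunConfig(),
    serious: frozenset[str] = SERIOUS_SIDE_EFFECTS,
    sequences: Mapping[str, str] | None = None,
) -> SideEffectReport:
    """Predict the query's side effects and killing index.

    The query's targets are the screen hits at the configured mTC cutoff.
    Target side effects are inferred from the known drug-target table
    and the drug-side-effect table; the query's predicted side effects
    are the union over its flagged targets, each term listed with the
    targets supporting it, and kappa counts flagged targets whose
    inferred set touches the serious list.
    """
    screen_rep = run_screen_report(query, library, config, sequences)
    predicted_targets = [h.target_id for h in screen_rep.hits if h.predicted]
    target_se = infer_target_side_effects(known_interactions, dict(drug_se))
    query_interactions = InteractionSet(
        list(known_interactions.pairs())
        + [(query.compound_id, t) for t in predicted_targets]
    )
    terms: dict[str, list[str]] = {}
    for t in predicted_targets:
        if t in target_se:
            for term in target_se[t][0]:
                terms.setdefault(term, []).append(t)
    kappa = killing_index(query.compound_id, query_interactions, target_se, serious)
    serious_norm = {s.lower() for s in serious}
    kappa_targets = sorted(
        t for t in predicted_targets
        if t in target_se and target_se[t][0] & serious_norm
    )
    return SideEffectReport(
        query.compound_id,
        predicted_targets,
        {k: sorted(v) for k, v in sorted(terms.items())},
        kappa,
        kappa_targets,
    )


def write_hits_tsv(report: ScreenReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("drug_id\ttarget_id\trank\tmtc\tbest_channel\tbest_template_ligand\tpredicted\n")
        for h in report.hits:
            fh.write(
                f"{report.query_id}\t{h.target_id}\t{h.rank}\t{h.mtc:.6f}\t"
                f"{h.best_channel or '-'}\t{h.best_template_ligand or '-'}\t{int(h.predicted)}\n"
            )


def read_hits_tsv(path) -> dict[str, list[ScreeningHit]]:
    out: dict[str, list[ScreeningHit]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("drug_id"):
            raise ValueError(f"{path}: expected ranked-hits header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                drug, tid, rank, mtc, channel, lig, pred = line.split("\t")
                hit = ScreeningHit(
                    tid, float(mtc), int(rank),
                    None if channel == "-" else channel,
                    None if lig == "-" else lig,
                    bool(int(pred)),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.setdefault(drug, []).append(hit)
    return out
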