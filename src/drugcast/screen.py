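"""Proteome-wide virtual target screening with the mTC score.

A query compound is scored against every protein target in a library.
Each target carries template ligands — small molecules associated with
the target because they bind evolutionarily related template proteins —
partitioned into three evidence channels (holo PDB structures, and
virtual holo templates with ligands from DrugBank or ChEMBL).  The
target score, mTC, is the best weighted Tanimoto similarity between the
query and any template ligand:

    mTC = max_l [ (1 - w) * TC(L_l, query) + w * 1(L_l is a true ligand) ]

with w = 0.1 by default, so experimentally confirmed ("true") ligands of
the target are up-weighted.  Each channel is scored independently and
the best channel score is the target score.

In benchmark mode, an :class:`ExclusionPolicy` removes template ligands
that would leak the answer: ligands nearly identical to the query
(TC > 0.99), ligands whose source protein is too similar in sequence to
the target under evaluation (identity > 95% or > 30%), and the query
compound itself.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .chem import CompoundRecord, Fingerprint, tanimoto

logger = logging.getLogger(__name__)

#: the three template-ligand evidence channels
CHANNELS = ("PDB_HOLO", "VIRTUAL_HOLO_DRUGBANK", "VIRTUAL_HOLO_CHEMBL")


@dataclass(frozen=True)
class TemplateLigand:
    """A template ligand anchoring similarity for one target."""

    compound: CompoundRecord
    is_true_ligand: bool
    source_protein_id: str
    channel: str

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")


@dataclass
class TargetRecord:
    """A protein target with its channel-partitioned template-ligand set."""

    target_id: str
    template_ligands: tuple[TemplateLigand, ...] = ()
    sequence: str | None = None
    disease_annotations: frozenset[str] = frozenset()

    def ligands_in_channel(self, channel: str) -> tuple[TemplateLigand, ...]:
        return tuple(l for l in self.template_ligands if l.channel == channel)


@dataclass(frozen=True)
class ScreeningHit:
    target_id: str
    mtc: float
    rank: int = 0
    best_channel: str | None = None
    best_template_ligand: str | None = None
    predicted: bool = False


@dataclass(frozen=True)
class ExclusionPolicy:
    """Benchmark-mode leakage filter.

    seq_identity_cutoff is a percentage (e.g. 95 or 30); ligand_tc_cutoff
    a Tanimoto similarity.  Both comparisons are strict (> cutoff removes).
    With ``enabled=False`` (prediction mode) nothing is filtered.
    """

    seq_identity_cutoff: float = 95.0
    ligand_tc_cutoff: float = 0.99
    enabled: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.seq_identity_cutoff <= 100.0:
            raise ValueError("seq_identity_cutoff must be in [0, 100]")
        if not 0.0 <= self.ligand_tc_cutoff <= 1.0:
            raise ValueError("ligand_tc_cutoff must be in [0, 1]")


def mtc_score(query: Fingerprint, ligands: Iterable[TemplateLigand], w: float = 0.1) -> float:
    """Best weighted Tanimoto of the query over a template-ligand set.

    Returns ``max_l (1-w) * TC(l, query) + w * [l is true ligand]``, or 0
    for an empty set, so a target with no template ligands still ranks
    (at the bottom).  ``w`` in [0, 1]; w = 0 reduces to plain max-TC.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must be in [0, 1]")
    best = 0.0
    for lig in ligands:
        s = (1.0 - w) * tanimoto(lig.compound.fingerprint, query) + (
            w if lig.is_true_ligand else 0.0
        )
        if s > best:
            best = s
    return best


@functools.lru_cache(maxsize=65536)
def _identity_cached(a: str, b: str) -> float:
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    alignment = aligner.align(a, b)[0]
    matches = sum(
        1
        for ca, cb in zip(alignment[0], alignment[1])
        if ca == cb and ca != "-"
    )
    return 100.0 * matches / min(len(a), len(b))


def sequence_identity(a: str, b: str) -> float:
    """Percent identity from one global alignment (BLOSUM62, gap 11/1).

    Identity = 100 * matches / min(len(a), len(b)), the usual convention
    for "sequence identity > cutoff" homology filters.
    """
    a, b = a.strip().upper(), b.strip().upper()
    if not a or not b:
        raise ValueError("empty sequence")
    allowed = set("ACDEFGHIKLMNPQRSTVWYX")
    bad = (set(a) | set(b)) - allowed
    if bad:
        raise ValueError(f"non-amino-acid letters in sequence: {sorted(bad)}")
    return _identity_cached(a, b)


def apply_exclusions(
    query: CompoundRecord,
    target: TargetRecord,
    ligands: Iterable[TemplateLigand],
    policy: ExclusionPolicy,
    sequences: Mapping[str, str] | None = None,
) -> list[TemplateLigand]:
    """Filter template ligands under the benchmark-mode exclusion policy.

    Removes ligands (i) that are the query compound itself, (ii) with
    TC > ligand_tc_cutoff to the query, and (iii) whose source protein has
    sequence identity > seq_identity_cutoff to the target.  A source
    protein with no sequence available is treated as unknown identity:
    the ligand is retained and a warning logged.  With the policy
    disabled, the input set is returned unchanged.
    """
    ligands = list(ligands)
    if not policy.enabled:
        return ligands
    sequences = sequences or {}
    target_seq = target.sequence or sequences.get(target.target_id)
    kept: list[TemplateLigand] = []
    for lig in ligands:
        if lig.compound.compound_id == query.compound_id:
            continue
        if tanimoto(lig.compound.fingerprint, query.fingerprint) > policy.ligand_tc_cutoff:
            continue
        src_seq = sequences.get(lig.source_protein_id)
        if src_seq is not None and target_seq is not None:
            if sequence_identity(src_seq, target_seq) > policy.seq_identity_cutoff:
                continue
        elif target_seq is not None:
            logger.warning(
                "no sequence for source protein %s; ligand %s retained",
                lig.source_protein_id,
                lig.compound.compound_id,
            )
        kept.append(lig)
    return kept


def score_target(
    query: CompoundRecord,
    target: TargetRecord,
    policy: ExclusionPolicy = ExclusionPolicy(),
    w: float = 0.1,
    sequences: Mapping[str, str] | None = None,
) -> ScreeningHit:
    """Score one target: per-channel mTC after exclusions, best channel wins.

    The returned hit is unranked (rank 0).  Ties between channels go to
    the earlier channel in :data:`CHANNELS`; ties between ligands inside
    a channel to the lexicographically smaller compound_id.
    """
    best_score = 0.0
    best_channel: str | None = None
    best_ligand: str | None = None
    for channel in CHANNELS:
        ligs = apply_exclusions(
            query, target, target.ligands_in_channel(channel), policy, sequences
        )
        for lig in sorted(ligs, key=lambda l: l.compound.compound_id):
            s = (1.0 - w) * tanimoto(lig.compound.fingerprint, query.fingerprint) + (
                w if lig.is_true_ligand else 0.0
            )
            if s > best_score:
                best_score, best_channel, best_ligand = s, channel, lig.compound.compound_id
    return ScreeningHit(
        target_id=target.target_id,
        mtc=best_score,
        best_channel=best_channel,
        best_template_ligand=best_ligand,
    )


def screen_proteome(
    query: CompoundRecord,
    library: Sequence[TargetRecord],
    policy: ExclusionPolicy = ExclusionPolicy(),
    w: float = 0.1,
    mtc_cutoff: float | None = None,
    sequences: Mapping[str, str] | None = None,
) -> list[ScreeningHit]:
    """Screen a query compound against every target in the library.

    Returns one hit per target, sorted by mTC descending with ties broken
    by ascending target_id, ranks 1..N.  If ``mtc_cutoff`` is given, hits
    with mTC >= cutoff (inclusive) carry ``predicted=True``.
    """
    if not library:
        raise ValueError("target library is empty")
    hits = [score_target(query, t, policy, w, sequences) for t in library]
    hits.sort(key=lambda h: (-h.mtc, h.target_id))
    return [
        replace(
            h,
            rank=i,
            predicted=(mtc_cutoff is not None and h.mtc >= mtc_cutoff),
        )
        for i, h in enumerate(hits, start=1)
    ]
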