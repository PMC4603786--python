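"""Synthetic-world generator with planted ground truth.

Builds a miniature drug/target universe in which every downstream
question has a known answer: which drug truly binds which target, which
side effects each target latently carries, and therefore what a perfect
screen or a perfect side-effect inference should return.

The generative model, in order:

1. Targets get latent side-effect sets sampled from a term catalog;
   a fraction additionally carry one of the eight serious terms.
2. True drug-target interactions are sampled with a long-tailed
   (log-normal) targets-per-drug count; a configurable share of the
   probability mass is concentrated on a "hub" subset of targets so
   that many targets have several binders (the regime the intersection
   inference rule needs).
3. A drug's side-effect record is the union of its targets' latent
   sets, plus noise terms at a configured rate, minus dropout.
4. Each true interaction plants template ligands on its target: a
   close copy of the drug's fingerprint (low bit-flip rate, true-ligand
   flag, source protein highly similar in sequence to the target) and a
   remote copy (higher bit-flip, unflagged, mid-identity source);
   random decoy ligands with low-identity sources round out the set.
5. Optionally a fraction of true interactions is hidden from the
   labeled truth table (kept in the planted truth), emulating the
   incompleteness of real interaction databases.

The defaults describe a desk-scale world that keeps every structural
feature of the real inputs (channel partition, true-ligand flags,
homologous sources, noisy annotations) without their volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .chem import N_BITS, CompoundRecord, Fingerprint, write_fingerprint_table
from .screen import CHANNELS, TargetRecord, TemplateLigand
from .sidefx import SERIOUS_SIDE_EFFECTS, InteractionSet

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class WorldParams:
    """Knobs of the synthetic universe (see module docstring for roles)."""

    n_targets: int = 60
    n_drugs: int = 40
    n_decoy_compounds: int = 120
    n_decoy_ligands_per_target: int = 3
    fp_popcount: int = 128            # on-bits per random fingerprint
    fp_bitflip_rate: float = 0.02     # per-bit flip rate of close template copies
    remote_bitflip_rate: float = 0.10 # of remote (unflagged) template copies
    se_catalog_size: int = 80
    se_per_target_min: int = 2
    se_per_target_max: int = 6
    se_noise_rate: float = 0.05       # extra random terms per drug record
    se_dropout_rate: float = 0.05     # chance each true term is missing
    sharing_fraction: float = 0.5     # interaction mass directed at hub targets
    hub_fraction: float = 0.2         # share of targets that are hubs
    serious_rate: float = 0.15        # chance a target carries a serious term
    serious_proportional_to_degree: bool = False
    promiscuity_mean: float = 3.0     # mean targets per drug (log-normal)
    promiscuity_sigma: float = 0.8
    truth_completeness: float = 1.0   # labeled fraction of true interactions
    seq_length: int = 120
    close_source_identity: float = 0.98
    remote_source_identity: float = 0.60
    decoy_source_identity: float = 0.30
    tc_floor: float = 0.5             # min TC of a drug to its best template
    disjoint_latent: bool = False     # give targets non-overlapping latent sets
    pair_share_cap: int | None = None # max targets any two drugs may share

    def validate(self) -> None:
        if self.se_per_target_max > self.se_catalog_size:
            raise ValueError("per-target side-effect count exceeds catalog size")
        if self.disjoint_latent and self.se_catalog_size < self.n_targets * self.se_per_target_max:
            raise ValueError(
                "disjoint latent sets need catalog >= n_targets * se_per_target_max"
            )
        if self.pair_share_cap is not None and self.pair_share_cap < 1:
            raise ValueError("pair_share_cap must be >= 1")
        if self.se_per_target_min < 1 or self.se_per_target_min > self.se_per_target_max:
            raise ValueError("invalid per-target side-effect range")
        for name in (
            "fp_bitflip_rate", "remote_bitflip_rate", "se_noise_rate",
            "se_dropout_rate", "sharing_fraction", "hub_fraction",
            "truth_completeness",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.n_targets, self.n_drugs, self.n_decoy_compounds) < 1:
            raise ValueError("counts must be positive")
        if not 0 < self.fp_popcount <= N_BITS:
            raise ValueError("fp_popcount out of range")


@dataclass
class SyntheticWorld:
    params: WorldParams
    seed: int
    compounds: dict[str, CompoundRecord]
    targets: list[TargetRecord]
    sequences: dict[str, str]
    interactions: InteractionSet          # labeled truth (possibly incomplete)
    true_interactions: InteractionSet     # complete planted truth
    drug_se: dict[str, frozenset[str]]
    latent_target_se: dict[str, frozenset[str]]
    drug_ids: list[str]
    target_ids: list[str]

    def drug(self, drug_id: str) -> CompoundRecord:
        return self.compounds[drug_id]


def _random_fingerprint(rng: np.random.Generator, popcount: int) -> Fingerprint:
    on = rng.choice(N_BITS, size=popcount, replace=False)
    return Fingerprint.from_on_bits(on.tolist())


def _flip_bits(fp: Fingerprint, rate: float, rng: np.random.Generator) -> Fingerprint:
    bits = fp.bits.copy()
    flips = rng.random(N_BITS) < rate
    return Fingerprint(bits ^ flips)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_to_identity(seq: str, identity: float, rng: np.random.Generator) -> str:
    """Substitute positions of ``seq`` so exact identity is ~``identity``.

    Mutates round((1 - identity) * len) positions to a different residue;
    no indels, so a global alignment recovers the identity within ~1%.
    """
    n_mut = round((1.0 - identity) * len(seq))
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    chars = list(seq)
    for p in positions:
        choices = [a for a in AMINO_ACIDS if a != chars[p]]
        chars[p] = choices[rng.integers(len(choices))]
    return "".join(chars)


def make_world(params: WorldParams = WorldParams(), seed: int = 0) -> SyntheticWorld:
    """Materialize a synthetic world; same params + seed give the same world."""
    params.validate()
    rng = np.random.default_rng(seed)
    p = params

    target_ids = [f"T{i:04d}" for i in range(p.n_targets)]
    drug_ids = [f"D{i:04d}" for i in range(p.n_drugs)]
    decoy_ids = [f"X{i:04d}" for i in range(p.n_decoy_compounds)]

    # (1) latent target side effects
    catalog = [f"se{i:04d}" for i in range(p.se_catalog_size)]
    serious = sorted(SERIOUS_SIDE_EFFECTS)
    latent: dict[str, set[str]] = {}
    if p.disjoint_latent:
        shuffled = list(rng.permutation(catalog))
        pos = 0
        for t in target_ids:
            k = int(rng.integers(p.se_per_target_min, p.se_per_target_max + 1))
            latent[t] = set(shuffled[pos : pos + k])
            pos += k
    else:
        for t in target_ids:
            k = int(rng.integers(p.se_per_target_min, p.se_per_target_max + 1))
            latent[t] = set(rng.choice(catalog, size=k, replace=False))

    # (2) true interactions: long-tailed promiscuity, hub-weighted targets.
    # With pair_share_cap set, no two drugs may share more than that many
    # targets (cap 1 makes the intersection inference rule provably exact
    # on zero-noise worlds with disjoint latent sets).
    n_hubs = max(1, round(p.hub_fraction * p.n_targets))
    weights = np.full(p.n_targets, (1.0 - p.sharing_fraction) / p.n_targets)
    weights[:n_hubs] += p.sharing_fraction / n_hubs
    weights /= weights.sum()
    true_pairs: list[tuple[str, str]] = []
    targets_of_drug: dict[str, set[int]] = {}
    mu = np.log(p.promiscuity_mean) - p.promiscuity_sigma**2 / 2
    for d in drug_ids:
        k = int(np.clip(round(rng.lognormal(mu, p.promiscuity_sigma)), 1, p.n_targets))
        if p.pair_share_cap is None:
            chosen = set(int(i) for i in rng.choice(p.n_targets, size=k, replace=False, p=weights))
        else:
            chosen = set()
            attempts = 0
            while len(chosen) < k and attempts < 50 * k:
                attempts += 1
                cand = int(rng.choice(p.n_targets, p=weights))
                if cand in chosen:
                    continue
                trial = chosen | {cand}
                if all(
                    len(trial & other) <= p.pair_share_cap
                    for other in targets_of_drug.values()
                ):
                    chosen = trial
        targets_of_drug[d] = chosen
        true_pairs.extend((d, target_ids[i]) for i in sorted(chosen))
    true_interactions = InteractionSet(true_pairs)

    # serious-term injection, optionally scaled with target degree;
    # under disjoint_latent each serious term is used at most once
    max_deg = max((len(true_interactions.drugs_of(t)) for t in target_ids), default=1)
    serious_pool = list(serious)
    for t in target_ids:
        if p.serious_proportional_to_degree:
            rate = p.serious_rate * len(true_interactions.drugs_of(t)) / max(1, max_deg)
        else:
            rate = p.serious_rate
        if rng.random() < rate:
            if p.disjoint_latent:
                if not serious_pool:
                    continue
                term = serious_pool.pop(int(rng.integers(len(serious_pool))))
            else:
                term = serious[int(rng.integers(len(serious)))]
            latent[t].add(term)
    latent_frozen = {t: frozenset(s) for t, s in latent.items()}

    # (3) drug side-effect records: union + noise - dropout
    drug_se: dict[str, frozenset[str]] = {}
    full_vocab = catalog + serious
    for d in drug_ids:
        terms = set()
        for t in true_interactions.targets_of(d):
            terms |= latent[t]
        if p.se_noise_rate > 0 and terms:
            n_noise = rng.binomial(len(terms), p.se_noise_rate)
            extra = rng.choice(full_vocab, size=n_noise, replace=False)
            terms |= set(extra)
        if p.se_dropout_rate > 0:
            terms = {s for s in terms if rng.random() >= p.se_dropout_rate}
        drug_se[d] = frozenset(terms)

    # (4) compounds, sequences and template ligands
    compounds: dict[str, CompoundRecord] = {}
    for cid in drug_ids + decoy_ids:
        compounds[cid] = CompoundRecord(cid, _random_fingerprint(rng, p.fp_popcount))
    sequences: dict[str, str] = {}
    for t in target_ids:
        sequences[t] = _random_sequence(rng, p.seq_length)

    targets: list[TargetRecord] = []
    for t in target_ids:
        ligands: list[TemplateLigand] = []
        for d in sorted(true_interactions.drugs_of(t)):
            close_id = f"{d}.tpl.{t}"
            close_fp = _flip_bits(compounds[d].fingerprint, p.fp_bitflip_rate, rng)
            compounds[close_id] = CompoundRecord(close_id, close_fp)
            src_close = f"src.{t}.{d}.hi"
            sequences[src_close] = mutate_to_identity(
                sequences[t], p.close_source_identity, rng
            )
            ligands.append(
                TemplateLigand(
                    compounds[close_id], True, src_close,
                    CHANNELS[int(rng.integers(len(CHANNELS)))],
                )
            )
            remote_id = f"{d}.rtpl.{t}"
            remote_fp = _flip_bits(compounds[d].fingerprint, p.remote_bitflip_rate, rng)
            compounds[remote_id] = CompoundRecord(remote_id, remote_fp)
            src_remote = f"src.{t}.{d}.mid"
            sequences[src_remote] = mutate_to_identity(
                sequences[t], p.remote_source_identity, rng
            )
            ligands.append(
                TemplateLigand(
                    compounds[remote_id], False, src_remote,
                    CHANNELS[int(rng.integers(len(CHANNELS)))],
                )
            )
        src_lo = f"src.{t}.lo"
        sequences[src_lo] = mutate_to_identity(sequences[t], p.decoy_source_identity, rng)
        for x in rng.choice(decoy_ids, size=p.n_decoy_ligands_per_target, replace=False):
            ligands.append(
                TemplateLigand(
                    compounds[str(x)], False, src_lo,
                    CHANNELS[int(rng.integers(len(CHANNELS)))],
                )
            )
        targets.append(TargetRecord(t, tuple(ligands), sequence=sequences[t]))

    # (5) truth-label incompleteness
    if p.truth_completeness < 1.0:
        labeled = [
            pair for pair in sorted(true_interactions.pairs())
            if rng.random() < p.truth_completeness
        ]
        interactions = InteractionSet(labeled)
    else:
        interactions = InteractionSet(sorted(true_interactions.pairs()))

    world = SyntheticWorld(
        params=p, seed=seed, compounds=compounds, targets=targets,
        sequences=sequences, interactions=interactions,
        true_interactions=true_interactions, drug_se=drug_se,
        latent_target_se=latent_frozen, drug_ids=drug_ids, target_ids=target_ids,
    )
    _check_learnable(world)
    return world


def _check_learnable(world: SyntheticWorld) -> None:
    """Every true interaction's drug must resemble a template of its target."""
    from .chem import tanimoto

    by_target = {t.target_id: t for t in world.targets}
    for d, t in world.true_interactions.pairs():
        fps = [l.compound.fingerprint for l in by_target[t].template_ligands]
        best = max((tanimoto(world.compounds[d].fingerprint, f) for f in fps), default=0.0)
        if best < world.params.tc_floor:
            raise ValueError(
                f"planted interaction ({d}, {t}) is not learnable: best template "
                f"TC {best:.2f} < floor {world.params.tc_floor}; lower the bit-flip rate"
            )


def plant_status_flags(
    kappas: dict[str, int],
    rng: np.random.Generator,
    base_rate: float = 0.1,
    slope: float = 0.0,
) -> dict[str, bool]:
    """Plant withdrawn/illicit/investigational flags, optionally kappa-linked.

    P(flag) = clip(base_rate + slope * kappa, 0, 1); slope 0 gives flags
    independent of the killing index.
    """
    return {
        d: bool(rng.random() < min(1.0, max(0.0, base_rate + slope * k)))
        for d, k in sorted(kappas.items())
    }


# ---------------------------------------------------------------------------
# fixture emission / loading


def emit_fixtures(world: SyntheticWorld, directory) -> dict[str, Path]:
    """Write the world as the plain-text tables the CLI consumes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fingerprints": directory / "fingerprints.tsv",
        "template_ligands": directory / "template_ligands.tsv",
        "interactions": directory / "interactions.tsv",
        "side_effects": directory / "side_effects.tsv",
        "sequences": directory / "sequences.fasta",
        "planted_truth": directory / "planted_truth.tsv",
        "latent_side_effects": directory / "latent_side_effects.tsv",
        "manifest": directory / "manifest.txt",
    }
    write_fingerprint_table(
        [world.compounds[c] for c in sorted(world.compounds)], paths["fingerprints"]
    )
    with open(paths["template_ligands"], "w") as fh:
        fh.write("target_id\tcompound_id\tchannel\tis_true_ligand\tsource_protein_id\n")
        for t in world.targets:
            for l in t.template_ligands:
                fh.write(
                    f"{t.target_id}\t{l.compound.compound_id}\t{l.channel}\t"
                    f"{int(l.is_true_ligand)}\t{l.source_protein_id}\n"
                )
    with open(paths["interactions"], "w") as fh:
        fh.write("drug_id\ttarget_id\n")
        for d, t in sorted(world.interactions.pairs()):
            fh.write(f"{d}\t{t}\n")
    with open(paths["planted_truth"], "w") as fh:
        fh.write("drug_id\ttarget_id\n")
        for d, t in sorted(world.true_interactions.pairs()):
            fh.write(f"{d}\t{t}\n")
    with open(paths["side_effects"], "w") as fh:
        fh.write("drug_id\tside_effect_term\n")
        for d in sorted(world.drug_se):
            for term in sorted(world.drug_se[d]):
                fh.write(f"{d}\t{term}\n")
    with open(paths["latent_side_effects"], "w") as fh:
        fh.write("target_id\tside_effect_term\n")
        for t in sorted(world.latent_target_se):
            for term in sorted(world.latent_target_se[t]):
                fh.write(f"{t}\t{term}\n")
    with open(paths["sequences"], "w") as fh:
        for sid in sorted(world.sequences):
            fh.write(f">{sid}\n{world.sequences[sid]}\n")
    with open(paths["manifest"], "w") as fh:
        fh.write(f"seed={world.seed}\n")
        for k, v in asdict(world.params).items():
            fh.write(f"{k}={v}\n")
        fh.write(f"n_compounds={len(world.compounds)}\n")
        fh.write(f"n_labeled_interactions={len(world.interactions)}\n")
        fh.write(f"n_true_interactions={len(world.true_interactions)}\n")
    return paths


def load_template_ligand_table(path, compounds: dict[str, CompoundRecord]) -> list[TargetRecord]:
    """Rebuild TargetRecords from a template-ligand TSV + compound table."""
    by_target: dict[str, list[TemplateLigand]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["target_id", "compound_id", "channel", "is_true_ligand", "source_protein_id"]
        if header != expected:
            raise ValueError(f"{path}: expected columns {expected}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                tid, cid, channel, true_flag, src = line.split("\t")
                lig = TemplateLigand(compounds[cid], bool(int(true_flag)), src, channel)
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            by_target.setdefault(tid, []).append(lig)
    return [TargetRecord(t, tuple(ligs)) for t, ligs in sorted(by_target.items())]


def load_interaction_table(path) -> InteractionSet:
    pairs = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("drug_id"):
            raise ValueError(f"{path}: expected header starting with 'drug_id'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                d, t = line.split("\t")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            pairs.append((d, t))
    return InteractionSet(pairs)


def load_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
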