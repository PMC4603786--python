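# Methods

## Scope and model

drugcast implements ligand-homology virtual target screening and
deterministic side-effect inference. The underlying assumptions are:

1. **Chemical similarity implies shared binding.** If a query compound
   is similar (Tanimoto of 1024-bit fingerprints) to a small molecule
   known or inferred to bind a target, the query plausibly binds that
   target too. Nothing here estimates binding affinity; the output is a
   ranking with an optional interaction flag.
2. **Side effects are target-mediated.** A drug's side effects are
   assumed to decompose over its protein targets, so terms shared by
   all binders of a target can be attributed to the target, and a
   drug's side effects re-assemble as the union over its targets.

## The mTC score

For a target with template-ligand set {L_l} (each ligand carrying a
true-ligand flag t_l ∈ {0,1}) and query fingerprint q:

    mTC = max_l (1 − w) · TC(L_l, q) + w · t_l,      w = 0.1 default.

The form is a convex combination: it stays in [0, 1], reduces to plain
max-Tanimoto at w = 0, and makes an identical true ligand score exactly
1. Each of the three evidence channels (`PDB_HOLO`,
`VIRTUAL_HOLO_DRUGBANK`, `VIRTUAL_HOLO_CHEMBL`) is scored separately
and the best channel wins, with the winning channel and template ligand
recorded on the hit. An empty template set scores 0 rather than being
unrankable, so every target appears in every ranking (required for
per-drug AUC over a fixed library). Ties in the final ranking break by
ascending target id; ties between channels by channel declaration
order; between ligands by compound id — all rankings are fully
deterministic and invariant to library order.

The interaction flag uses an inclusive comparison (mTC ≥ cutoff,
default 0.90).

## Fingerprints

1024-bit hashed-path (Daylight-style) fingerprints computed by RDKit
(`RDKFingerprint`, `fpSize=1024`), the scheme recorded on every
`Fingerprint`. SMILES are canonicalized before fingerprinting so
textual variants coincide. Exact bit patterns are scheme-defined;
nothing downstream depends on particular bits, only on the Tanimoto
contract. Two all-zero fingerprints have Tanimoto 0 by convention (not
NaN) so featureless molecules never crash a ranking.

## Benchmark-mode exclusions

To emulate prediction of *novel* interactions, benchmark mode removes,
per (query, target) evaluation: the query compound itself if it appears
as a template ligand; template ligands with TC > 0.99 to the query; and
template ligands whose source protein has sequence identity > the
cutoff (95% default, 30% for the remote-homology regime) to the target.
Both comparisons are strict, exactly as the cutoffs are stated.
Sequence identity comes from one global alignment (Biopython
`PairwiseAligner`, BLOSUM62, gap open 11 / extend 1) as
100 · matches / min(len a, len b) — the common convention for homology
filters; a missing source-protein sequence leaves the ligand in place
with a logged warning (unknown identity is not treated as disqualifying).
`report.audit_exclusions` re-applies the filter after a benchmark screen
and asserts no surviving ligand violates either rule.

## Evaluation conventions

* **AUC per drug**: Mann–Whitney form on the mTC scores (midranks, so
  tied scores count ½). Degenerate truth (no positives or no negatives)
  yields no value rather than a fake 0.5.
* **EF_x**: (true positives in the top ⌈x·N⌉ / |truth|) / x. Ceiling
  rounding is pinned by the bookkeeping identity that the top 1% of a
  3,576-entry ranking is 36 entries.
* **Curves**: per-drug precision/recall macro-averaged over drugs with
  ≥ 1 prediction at the cutoff, with that count reported. Excluding
  no-prediction drugs (rather than counting zeros) is what produces the
  characteristic high-cutoff sag in mean precision as drugs with small,
  perfect prediction sets drop out of the average. Micro-averaging is
  deliberately not the default anywhere.
* **Observed vs true precision**: precision measured against an
  incomplete truth list underestimates true precision (a "false
  positive" may be an unlabeled true target). The binned
  `observed_precision_by_truth_count` view and the generator's
  `truth_completeness` parameter exist to make this gap measurable: a
  perfect predictor on a world with completeness p shows observed
  precision ≈ p.

## Side-effect inference

`infer_target_side_effects` intersects the records of a target's
annotated binders; targets with fewer than two annotated binders, or an
empty intersection, are omitted. Binders missing from the side-effect
table are ignored rather than treated as empty sets — one unannotated
binder must not erase a target's side effects. Terms are free strings
compared after lowercasing and whitespace collapsing; no ontology
mapping is attempted. The killing index counts *targets* whose inferred
set touches the serious-term list, not serious terms, so κ is bounded
by the drug's target count. The consistency test's zero-false-positive
property is a theorem (every inferred term is in every supporting
drug's record), and is asserted as such across many random worlds; the
jackknife test is the honest estimate of predictive power.

## Pocket extraction and alignment

A pocket is the chain-ordered set of residues with any heavy atom
within 4.5 Å, or Cα within 8 Å, of the ligand's heavy atoms. Alignment
of a target Cα trace onto a pocket is heuristic and sequence-order
dependent:

1. enumerate order-compatible residue triplets (target triplets capped
   at a 30-residue sequence span by default) whose three inter-Cα
   distances each agree within 1 Å;
2. Kabsch-superpose each seed (hand-written SVD Kabsch with proper-
   rotation correction; near-collinear seeds are rejected on triangle
   area);
3. grow the alignment with an order-preserving pairing of residues
   within 1 Å after superposition, re-superpose on the grown set, and
   iterate to a fixed point (cap 100 iterations; an oscillating
   refinement is cut at the cap);
4. return the best-scoring fixed point over all seeds, processed in
   order of increasing seed distance mismatch, deduplicated by
   near-identical transforms and capped (500 seeds default; `None`
   for exhaustive).

The growth pairing is a dynamic program maximizing the number of
matched pairs with total matched distance as tie-break (an LCS on the
admissibility relation d ≤ 1 Å). A greedy two-pointer sweep was
considered and rejected: it can commit to a near pair that blocks two
later pairs, whereas the DP is optimal, deterministic and equally
order-preserving.

The alignment score is
`Σ_pairs [ 1/(1 + (d_i/3 Å)²) + 0.5 · B62(a_i, b_i)/11 ]`, mixing a
distance kernel with BLOSUM62 sequence similarity (11 is the matrix's
largest entry). The functional form of this ranking score is a design
choice of this package; the constants (d₀ = 3 Å, weight 0.5) are
exposed as module constants. For multi-segment targets,
`best_segment_pocket` aligns every (segment, pocket) pair and keeps the
best score, ties to input order.

## The synthetic world

The generator plants: latent per-target side-effect sets from a term
catalog (80 terms default, 2–6 per target), true drug–target
interactions with a long-tailed log-normal promiscuity (mean 3 targets
per drug, σ = 0.8 — the long-tail shape of real drug promiscuity at
desk scale), drug records as noisy unions of their targets' latent sets
(5% noise and dropout), and per-interaction template ligands: a close
copy of the drug's fingerprint (2% bit-flip, true-ligand flag, source
protein at ~98% sequence identity to the target) plus a remote copy
(10% bit-flip, unflagged, ~60% identity source) and random decoy
ligands from ~30%-identity sources. This makes benchmark-mode
exclusions meaningful: the 95% cutoff removes the close copies but the
remote evidence survives, while a 30% cutoff removes both. Sequences
are generated by mutating the target sequence to requested exact
identities (substitutions only, so global alignment recovers the
requested identity within ~1%). A `truth_completeness` < 1 hides a
fraction of true interactions from the labeled table while keeping them
in the planted truth.

Two structural options exist for regimes where inference results are
provable rather than statistical: `disjoint_latent` assigns
non-overlapping latent sets, and `pair_share_cap=1` forbids any two
drugs from sharing more than one target. Under both, with zero noise,
exact recovery of every ≥2-binder target's latent set is a theorem; in
unconstrained worlds it is not (when all binders of a target co-bind a
second target, the second target's terms survive the intersection),
which is a genuine property of the inference rule on dense interaction
graphs, not an implementation artifact. Recovery benchmarks therefore
run on the structured regime and soundness (zero false positives) on
unconstrained ones.

What the generator does **not** emulate: real chemical space (compound
fingerprints are random bit vectors, not molecules), real side-effect
term frequencies or co-occurrence, binding-site structure behind the
fingerprint similarity, and realistic proteome scale. Passing tests
demonstrate correctness of the algorithms and their stated guarantees
under the planted model — not field performance on real drug–target
data.

## Problem sizes and numerical choices

Default test and acceptance worlds use 10–60 targets, 8–40 drugs and
15–120 decoy compounds — large enough for every code path (multi-binder
targets, hub sharing, channel competition, exclusion filtering) while
keeping the full suite and the acceptance run in seconds. Determinism:
all randomness flows from one `numpy` `default_rng` seed per world;
identical parameters and seed give byte-identical fixture files.
Floating-point conventions: Tanimoto and mTC are exact rational
arithmetic on bit counts; Kabsch RMSD is reported from the minimized
superposition and cross-checked against the stored transform to 1e-6 Å
in tests; undefined precision/recall/AUC values are `None`, never
silently 0.

## Known limitations

* The mTC functional form is one reasonable convex realization of a
  weighted best-match score; it is isolated behind `mtc_score` so an
  alternative weighting could be swapped in.
* Sequence identity depends mildly on the alignment parametrization;
  the BLOSUM62/11/1 global convention is fixed but different gap
  schemes can move identity a few percent near a cutoff.
* The triplet alignment is a heuristic: with aggressive seed caps on
  very large chains it can miss the global optimum; `max_seeds=None`
  restores exhaustive behavior at cubic cost.
* Side-effect inference is binary — no ranking or probability per
  term — and inherits any bias in the input interaction table.
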