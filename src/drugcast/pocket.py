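"""Binding-pocket extraction and heuristic structure-pocket alignment.

A pocket model of a holo template is the ordered set of C-alpha atoms of
residues close to the bound ligand: residues with any heavy atom within
4.5 A of a ligand heavy atom, plus residues whose C-alpha lies within
8 A of a ligand heavy atom.

The alignment of a target C-alpha trace onto a pocket is heuristic and
sequence-order dependent: every order-compatible pair of residue
triplets whose three inter-C-alpha distances agree within 1 A seeds a
rigid superposition; the alignment is then grown with an
order-preserving pairing of residues within 1 A of each other after
superposition, re-superposed on the grown set, and iterated to a fixed
point.  The best-scoring fixed point over all seeds is returned, scored
by a mixed structural/sequence term over the aligned pairs:

    score = sum_i [ 1 / (1 + (d_i / d0)^2) + c * B62(a_i, b_i) / 11 ]

with d0 = 3 A and c = 0.5, where B62 is the BLOSUM62 substitution value
(11 is its largest entry).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# pocket-extraction distance cutoffs (Angstrom)
HEAVY_ATOM_CUTOFF = 4.5
CA_CUTOFF = 8.0

# alignment heuristic parameters
SEED_DISTANCE_TOL = 1.0   # max |d_target - d_pocket| per triplet edge (A)
PAIR_DISTANCE_TOL = 1.0   # max residual distance for a residue pair (A)
SCORE_D0 = 3.0
SCORE_SEQ_WEIGHT = 0.5
DEFAULT_MAX_SPAN = 30     # max residue-index span of a seed triplet
DEFAULT_MAX_ITER = 100
DEFAULT_MAX_SEEDS = 500


@dataclass(frozen=True, eq=False)
class Residue:
    """One residue: 1-based chain index, one-letter type, C-alpha, heavy atoms."""

    index: int
    aa: str
    ca: np.ndarray
    heavy_atoms: np.ndarray | None = None  # (n, 3) incl. side chain, may be None for traces

    def __post_init__(self) -> None:
        ca = np.asarray(self.ca, dtype=float)
        if ca.shape != (3,) or not np.all(np.isfinite(ca)):
            raise ValueError(f"residue {self.index}: bad C-alpha coordinate")
        object.__setattr__(self, "ca", ca)
        if self.heavy_atoms is not None:
            ha = np.asarray(self.heavy_atoms, dtype=float)
            if ha.ndim != 2 or ha.shape[1] != 3 or not np.all(np.isfinite(ha)):
                raise ValueError(f"residue {self.index}: bad heavy-atom coordinates")
            object.__setattr__(self, "heavy_atoms", ha)


@dataclass
class StructureModel:
    """Ordered residues of one chain segment."""

    residues: list[Residue]
    segment_id: str = "seg1"

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, eq=False)
class LigandCoordinates:
    """Heavy-atom coordinates of a bound ligand."""

    coords: np.ndarray
    ligand_id: str = "LIG"

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 1 or not np.all(np.isfinite(c)):
            raise ValueError("ligand must have >= 1 finite heavy-atom coordinate")
        object.__setattr__(self, "coords", c)


@dataclass
class PocketModel:
    """Ordered C-alpha residues defining a ligand-binding pocket."""

    residues: list[Residue]
    source_ligand_id: str = ""
    source_template_id: str = ""

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignmentResult:
    """An order-preserving correspondence with its rigid transform.

    ``pairs`` holds positional indices (target position, pocket position);
    the transform maps target coordinates onto the pocket frame as
    ``x @ rotation.T + translation``.
    """

    pairs: list[tuple[int, int]]
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    score: float

    @property
    def n_aligned(self) -> int:
        return len(self.pairs)


def extract_pocket(
    template: StructureModel,
    ligand: LigandCoordinates,
    heavy_cutoff: float = HEAVY_ATOM_CUTOFF,
    ca_cutoff: float = CA_CUTOFF,
) -> PocketModel:
    """Residues near the ligand: heavy atom <= 4.5 A or C-alpha <= 8 A.

    Chain order is preserved; residues without stored heavy atoms are
    judged on the C-alpha rule alone.
    """
    lig = ligand.coords
    picked: list[Residue] = []
    for res in template.residues:
        near = False
        if res.heavy_atoms is not None and len(res.heavy_atoms):
            d = np.linalg.norm(res.heavy_atoms[:, None, :] - lig[None, :, :], axis=2)
            near = bool(d.min() <= heavy_cutoff)
        if not near:
            near = bool(np.linalg.norm(lig - res.ca, axis=1).min() <= ca_cutoff)
        if near:
            picked.append(Residue(res.index, res.aa, res.ca))
    return PocketModel(picked, source_ligand_id=ligand.ligand_id,
                       source_template_id=template.segment_id)


def kabsch_superpose(
    moving: np.ndarray, fixed: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns (R, t, rmsd) with the proper rotation R (no reflection) and
    translation t minimizing RMSD of ``moving @ R.T + t`` to ``fixed``.
    Requires >= 3 non-collinear points for a unique rotation.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must be equal-shape (n, 3) arrays")
    n = moving.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    a = moving - mc
    b = fixed - fc
    # degenerate (collinear) sets leave the rotation underdetermined
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 or np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    t = fc - rot @ mc
    moved = moving @ rot.T + t
    rmsd = float(np.sqrt(((moved - fixed) ** 2).sum() / n))
    return rot, t, rmsd


def _blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


_B62 = None
_B62_MAX = 11.0


def _seq_sim(a: str, b: str) -> float:
    global _B62
    if _B62 is None:
        _B62 = _blosum62()
    try:
        return float(_B62[a, b]) / _B62_MAX
    except (KeyError, IndexError):
        return 0.0


def alignment_score(
    target: StructureModel,
    pocket: PocketModel,
    pairs: Sequence[tuple[int, int]],
    rotation: np.ndarray,
    translation: np.ndarray,
) -> float:
    if not pairs:
        return 0.0
    t_xyz = target.ca_coords[[i for i, _ in pairs]] @ rotation.T + translation
    p_xyz = pocket.ca_coords[[j for _, j in pairs]]
    d = np.linalg.norm(t_xyz - p_xyz, axis=1)
    struct = (1.0 / (1.0 + (d / SCORE_D0) ** 2)).sum()
    seq = sum(
        _seq_sim(target.residues[i].aa, pocket.residues[j].aa) for i, j in pairs
    )
    return float(struct + SCORE_SEQ_WEIGHT * seq)


def _order_preserving_pairs(
    moved_target: np.ndarray, pocket_xyz: np.ndarray, tol: float
) -> list[tuple[int, int]]:
    """Maximum order-preserving matching of residues within ``tol``.

    Dynamic program over the (target, pocket) grid maximizing the number
    of matched pairs, with total matched distance as the deterministic
    tie-break; equivalent to a longest-common-subsequence on the
    admissibility relation d(i, j) <= tol.
    """
    n, m = len(moved_target), len(pocket_xyz)
    d = np.linalg.norm(moved_target[:, None, :] - pocket_xyz[None, :, :], axis=2)
    ok = d <= tol
    # best[i][j]: (n_pairs, -total_dist) achievable from suffix (i:, j:)
    count = np.zeros((n + 1, m + 1), dtype=int)
    dist = np.zeros((n + 1, m + 1), dtype=float)
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            best_c, best_d = count[i + 1][j], dist[i + 1][j]
            if count[i][j + 1] > best_c or (
                count[i][j + 1] == best_c and dist[i][j + 1] < best_d
            ):
                best_c, best_d = count[i][j + 1], dist[i][j + 1]
            if ok[i, j]:
                c2, d2 = count[i + 1][j + 1] + 1, dist[i + 1][j + 1] + d[i, j]
                if c2 > best_c or (c2 == best_c and d2 < best_d):
                    best_c, best_d = c2, d2
            count[i][j], dist[i][j] = best_c, best_d
    pairs: list[tuple[int, int]] = []
    i = j = 0
    while i < n and j < m:
        if (
            ok[i, j]
            and count[i][j] == count[i + 1][j + 1] + 1
            and abs(dist[i][j] - (dist[i + 1][j + 1] + d[i, j])) < 1e-9
        ):
            pairs.append((i, j))
            i += 1
            j += 1
        elif count[i + 1][j] > count[i][j + 1] or (
            count[i + 1][j] == count[i][j + 1] and dist[i + 1][j] <= dist[i][j + 1]
        ):
            i += 1
        else:
            j += 1
    return pairs


def _triangle_area(p: np.ndarray) -> float:
    return 0.5 * float(np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0])))


def _enumerate_triplets(coords: np.ndarray, max_span: int | None) -> list[tuple[int, int, int]]:
    n = len(coords)
    out = []
    for i, j, k in itertools.combinations(range(n), 3):
        if max_span is not None and k - i > max_span:
            continue
        out.append((i, j, k))
    return out


def align_pocket(
    target: StructureModel,
    pocket: PocketModel,
    max_span: int | None = DEFAULT_MAX_SPAN,
    max_iter: int = DEFAULT_MAX_ITER,
    max_seeds: int | None = DEFAULT_MAX_SEEDS,
) -> AlignmentResult:
    """Align a target C-alpha trace onto a pocket by triplet seeding.

    Every order-compatible (target, pocket) triplet pair whose three
    inter-C-alpha distances each agree within 1 A is a candidate seed.
    Seeds are processed in order of increasing total distance mismatch,
    deduplicated by near-identical rigid transforms, and capped at
    ``max_seeds`` (None for exhaustive).  Each seed is superposed, grown
    with order-preserving pairing within 1 A, re-superposed and iterated
    to a fixed point (or ``max_iter``); the best-scoring fixed point
    wins.  No admissible seed yields an empty alignment with score 0.
    """
    if len(target) < 3 or len(pocket) < 3:
        raise ValueError("target and pocket both need >= 3 residues")
    t_xyz = target.ca_coords
    p_xyz = pocket.ca_coords

    t_triplets = _enumerate_triplets(t_xyz, max_span)
    p_triplets = _enumerate_triplets(p_xyz, None)
    if not t_triplets or not p_triplets:
        return AlignmentResult([], np.eye(3), np.zeros(3), 0.0, 0.0)

    def edge_lengths(xyz, triplets):
        tr = np.asarray(triplets)
        a, b, c = xyz[tr[:, 0]], xyz[tr[:, 1]], xyz[tr[:, 2]]
        return np.stack(
            [
                np.linalg.norm(a - b, axis=1),
                np.linalg.norm(a - c, axis=1),
                np.linalg.norm(b - c, axis=1),
            ],
            axis=1,
        )

    td = edge_lengths(t_xyz, t_triplets)
    pd = edge_lengths(p_xyz, p_triplets)
    diff = np.abs(td[:, None, :] - pd[None, :, :])
    compatible = np.all(diff <= SEED_DISTANCE_TOL, axis=2)
    ti, pi = np.nonzero(compatible)
    if len(ti) == 0:
        return AlignmentResult([], np.eye(3), np.zeros(3), 0.0, 0.0)
    mismatch = diff[ti, pi].sum(axis=1)
    order = np.argsort(mismatch, kind="stable")
    ti, pi = ti[order], pi[order]
    if max_seeds is not None:
        ti, pi = ti[:max_seeds], pi[:max_seeds]

    best: AlignmentResult | None = None
    seen_transforms: set[tuple] = set()
    for a, b in zip(ti, pi):
        seed_t = list(t_triplets[a])
        seed_p = list(p_triplets[b])
        if _triangle_area(t_xyz[seed_t]) < 1e-3 or _triangle_area(p_xyz[seed_p]) < 1e-3:
            continue
        pairs = list(zip(seed_t, seed_p))
        try:
            rot, tr, _ = kabsch_superpose(t_xyz[seed_t], p_xyz[seed_p])
        except ValueError:
            continue
        key = tuple(np.round(np.concatenate([rot.ravel(), tr]), 1))
        if key in seen_transforms:
            continue
        seen_transforms.add(key)

        prev_pairs: list[tuple[int, int]] = []
        result_pairs = pairs
        for it in range(max_iter):
            moved = t_xyz @ rot.T + tr
            new_pairs = _order_preserving_pairs(moved, p_xyz, PAIR_DISTANCE_TOL)
            if len(new_pairs) < 3:
                result_pairs = new_pairs
                break
            if new_pairs == result_pairs or new_pairs == prev_pairs:
                result_pairs = new_pairs
                break
            prev_pairs, result_pairs = result_pairs, new_pairs
            try:
                rot, tr, _ = kabsch_superpose(
                    t_xyz[[i for i, _ in new_pairs]], p_xyz[[j for _, j in new_pairs]]
                )
            except ValueError:
                break
        else:
            logger.debug("alignment iteration cap (%d) hit", max_iter)

        if len(result_pairs) < 3:
            continue
        rot_f, tr_f, rmsd = kabsch_superpose(
            t_xyz[[i for i, _ in result_pairs]], p_xyz[[j for _, j in result_pairs]]
        )
        score = alignment_score(target, pocket, result_pairs, rot_f, tr_f)
        if best is None or score > best.score:
            best = AlignmentResult(result_pairs, rot_f, tr_f, rmsd, score)
    if best is None:
        return AlignmentResult([], np.eye(3), np.zeros(3), 0.0, 0.0)
    return best


def best_segment_pocket(
    target_segments: Sequence[StructureModel],
    pockets: Sequence[PocketModel],
    **align_kwargs,
) -> tuple[StructureModel, PocketModel, AlignmentResult]:
    """Best-scoring (segment, pocket) pair over all combinations.

    Ties go to the earlier segment, then the earlier pocket, in input
    order, so the choice is deterministic.
    """
    if not target_segments or not pockets:
        raise ValueError("need at least one segment and one pocket")
    best = None
    for seg in target_segments:
        for pk in pockets:
            res = align_pocket(seg, pk, **align_kwargs)
            if best is None or res.score > best[2].score:
                best = (seg, pk, res)
    return best


# ---------------------------------------------------------------------------
# PDB I/O


def read_structure_pdb(path, segment_id: str | None = None) -> StructureModel:
    """Read the first model / first chain of a PDB file as a StructureModel.

    Keeps the highest-occupancy altLoc, skips waters and heteroatoms;
    residues without a C-alpha are dropped.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import protein_letters_3to1

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(iter(structure))
    chain = next(iter(model))
    residues: list[Residue] = []
    for res in chain:
        hetflag = res.id[0]
        if hetflag != " ":
            continue
        if "CA" not in res:
            continue
        heavy = np.array(
            [atom.coord for atom in res if atom.element != "H"], dtype=float
        )
        aa = protein_letters_3to1.get(res.get_resname().upper(), "X")
        residues.append(Residue(res.id[1], aa, np.array(res["CA"].coord, dtype=float), heavy))
    return StructureModel(residues, segment_id or chain.id)


def read_ligand_pdb(path, het_code: str) -> LigandCoordinates:
    """Heavy-atom coordinates of the named HETATM residue (waters excluded)."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(iter(structure))
    coords = []
    for chain in model:
        for res in chain:
            if res.get_resname().strip() == het_code and res.get_resname() != "HOH":
                coords.extend(atom.coord for atom in res if atom.element != "H")
    if not coords:
        raise ValueError(f"ligand {het_code!r} not found in {path}")
    return LigandCoordinates(np.array(coords, dtype=float), het_code)


def write_alignment_tsv(
    result: AlignmentResult, target: StructureModel, pocket: PocketModel, path
) -> None:
    """Correspondence table in original author residue numbering."""
    with open(path, "w") as fh:
        fh.write("target_residue\ttarget_aa\tpocket_residue\tpocket_aa\tdistance\n")
        moved = target.ca_coords @ result.rotation.T + result.translation
        for i, j in result.pairs:
            d = float(np.linalg.norm(moved[i] - pocket.ca_coords[j]))
            fh.write(
                f"{target.residues[i].index}\t{target.residues[i].aa}\t"
                f"{pocket.residues[j].index}\t{pocket.residues[j].aa}\t{d:.3f}\n"
            )
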