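"""Pocket extraction, Kabsch superposition and triplet-seed alignment."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from drugcast.pocket import (
    AlignmentResult,
    LigandCoordinates,
    PocketModel,
    Residue,
    StructureModel,
    align_pocket,
    best_segment_pocket,
    extract_pocket,
    kabsch_superpose,
    read_ligand_pdb,
    read_structure_pdb,
)

AAS = "ACDEFGHIKLMNPQRSTVWY"


def helix(n, seed=0, start_index=1, radius=5.0, rise=1.5):
    """A helical C-alpha trace: non-degenerate, realistic spacing."""
    ts = np.arange(n, dtype=float)
    coords = np.stack([np.cos(ts) * radius, np.sin(ts) * radius, ts * rise], axis=1)
    residues = [
        Residue(start_index + i, AAS[i % len(AAS)], coords[i]) for i in range(n)
    ]
    return StructureModel(residues)


def random_rigid(seed):
    rot = Rotation.random(random_state=seed).as_matrix()
    t = np.random.default_rng(seed).normal(0, 10, 3)
    return rot, t


def transform_model(model, rot, t, start_index=1):
    return StructureModel(
        [
            Residue(start_index + i, r.aa, r.ca @ rot.T + t)
            for i, r in enumerate(model.residues)
        ]
    )


class TestExtractPocket:
    def _residue(self, index, ca, side_chain=None):
        heavy = np.vstack([[ca]] + ([side_chain] if side_chain is not None else []))
        return Residue(index, "A", np.asarray(ca, float), heavy)

    def test_far_ligand_gives_empty_pocket(self):
        model = helix(10)
        ligand = LigandCoordinates(np.array([[100.0, 100.0, 100.0]]))
        full = StructureModel(
            [Residue(r.index, r.aa, r.ca, r.ca[None, :]) for r in model.residues]
        )
        assert len(extract_pocket(full, ligand)) == 0

    def test_side_chain_contact_rule(self):
        # C-alpha at 9 A but a side-chain atom at 4.4 A -> included
        lig = LigandCoordinates(np.array([[0.0, 0.0, 0.0]]))
        res = self._residue(1, [9.0, 0.0, 0.0], side_chain=[[4.4, 0.0, 0.0]])
        model = StructureModel([res])
        assert len(extract_pocket(model, lig)) == 1
        # at 4.6 A and C-alpha 9 A -> excluded by both rules
        res2 = self._residue(1, [9.0, 0.0, 0.0], side_chain=[[4.6, 0.0, 0.0]])
        assert len(extract_pocket(StructureModel([res2]), lig)) == 0

    def test_ca_distance_boundary(self):
        lig = LigandCoordinates(np.array([[0.0, 0.0, 0.0]]))
        inside = self._residue(1, [7.9, 0.0, 0.0])
        outside = self._residue(2, [8.1, 0.0, 0.0])
        model = StructureModel([inside, outside])
        pk = extract_pocket(model, lig)
        assert [r.index for r in pk.residues] == [1]

    def test_chain_order_preserved(self):
        lig = LigandCoordinates(np.array([[0.0, 0.0, 0.0]]))
        residues = [self._residue(i, [2.0 + 0.1 * i, 0, 0]) for i in (3, 7, 12)]
        pk = extract_pocket(StructureModel(residues), lig)
        assert [r.index for r in pk.residues] == [3, 7, 12]

    def test_zero_atom_ligand_rejected(self):
        with pytest.raises(ValueError):
            LigandCoordinates(np.zeros((0, 3)))


class TestKabsch:
    def test_identity_on_identical_sets(self):
        pts = helix(6).ca_coords
        rot, t, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-9)

    def test_recovers_rigid_transform(self):
        pts = helix(8).ca_coords
        rot_true = Rotation.from_rotvec(np.deg2rad(37) * np.array([1, 2, 2]) / 3).as_matrix()
        moved = pts @ rot_true.T + np.array([5.0, -2.0, 7.0])
        _, _, rmsd = kabsch_superpose(pts, moved)
        assert rmsd < 1e-9

    def test_no_reflection(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 3))
        b = a.copy()
        b[:, 0] *= -1  # mirrored set
        rot, _, _ = kabsch_superpose(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_matches_scipy_align_vectors_oracle(self):
        rng = np.random.default_rng(3)
        for seed in range(20):
            a = rng.normal(size=(7, 3))
            b = rng.normal(size=(7, 3))
            rot, t, rmsd = kabsch_superpose(a, b)
            r_sp, ssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
            rmsd_sp = np.sqrt(((((a - a.mean(0)) @ r_sp.as_matrix().T) - (b - b.mean(0))) ** 2).sum() / len(a))
            assert rmsd == pytest.approx(rmsd_sp, abs=1e-9)

    def test_optimal_against_random_transforms(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        _, _, best = kabsch_superpose(a, b)
        for seed in range(200):
            rot, t = random_rigid(seed)
            rmsd = np.sqrt((((a @ rot.T + t) - b) ** 2).sum() / len(a))
            assert best <= rmsd + 1e-12

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.stack([np.arange(4.0), np.zeros(4), np.zeros(4)], axis=1)
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)


class TestAlignPocket:
    def _pocket(self, n=9, seed=0):
        model = helix(n, seed=seed)
        return PocketModel(model.residues)

    def test_self_alignment_is_identity(self):
        pk = self._pocket()
        target = StructureModel(list(pk.residues))
        res = align_pocket(target, pk)
        assert res.pairs == [(i, i) for i in range(len(pk))]
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_copy_recovers_correspondence(self):
        pk = self._pocket()
        rot, t = random_rigid(5)
        target = transform_model(StructureModel(list(pk.residues)), rot, t)
        res = align_pocket(target, pk)
        assert res.pairs == [(i, i) for i in range(len(pk))]
        assert res.rmsd < 1e-6

    def test_planted_pocket_in_decoy_chain(self):
        pk = self._pocket(n=8)
        rot, t = random_rigid(6)
        core = pk.ca_coords @ rot.T + t
        rng = np.random.default_rng(6)
        before = core[0] + rng.normal(0, 1, size=(4, 3)) + np.array([40.0, 0, 0])
        after = core[-1] + rng.normal(0, 1, size=(4, 3)) - np.array([40.0, 0, 0])
        chain = np.vstack([before, core, after])
        residues = [
            Residue(i + 1, (list("GGGG") + [r.aa for r in pk.residues] + list("GGGG"))[i], chain[i])
            for i in range(len(chain))
        ]
        res = align_pocket(StructureModel(residues), pk)
        assert res.pairs == [(4 + i, i) for i in range(len(pk))]
        assert res.rmsd < 1e-6

    def test_no_admissible_seed_scores_zero(self):
        pk = self._pocket(n=5)
        # stretched chain: all inter-CA distances far from the pocket's
        stretched = StructureModel(
            [Residue(i + 1, "A", np.array([40.0 * i, 0.0, 0.0])) for i in range(5)]
        )
        res = align_pocket(stretched, pk)
        assert res.pairs == [] and res.score == 0.0

    def test_score_and_rmsd_rigid_invariance(self):
        pk = self._pocket(n=8)
        base = helix(14, seed=1)
        ref = align_pocket(base, pk)
        for seed in range(3):
            rot, t = random_rigid(seed + 30)
            moved = transform_model(base, rot, t)
            res = align_pocket(moved, pk)
            assert res.score == pytest.approx(ref.score, abs=1e-6)
            assert res.rmsd == pytest.approx(ref.rmsd, abs=1e-6)

    def test_rmsd_consistent_with_stored_transform(self):
        pk = self._pocket(n=8)
        target = helix(14, seed=1)
        res = align_pocket(target, pk)
        assert res.n_aligned >= 3
        moved = target.ca_coords @ res.rotation.T + res.translation
        d = [
            np.sum((moved[i] - pk.ca_coords[j]) ** 2) for i, j in res.pairs
        ]
        assert np.sqrt(np.mean(d)) == pytest.approx(res.rmsd, abs=1e-6)

    def test_correspondence_is_order_preserving(self):
        pk = self._pocket(n=8)
        res = align_pocket(helix(14, seed=2), pk)
        ti = [i for i, _ in res.pairs]
        pj = [j for _, j in res.pairs]
        assert ti == sorted(ti) and len(set(ti)) == len(ti)
        assert pj == sorted(pj) and len(set(pj)) == len(pj)


class TestBestSegmentPocket:
    def test_planted_segment_wins(self):
        pk = PocketModel(helix(8).residues)
        rot, t = random_rigid(8)
        planted = transform_model(StructureModel(list(pk.residues)), rot, t)
        rng = np.random.default_rng(9)
        decoy = StructureModel(
            [Residue(i + 1, "G", rng.normal(0, 12, 3)) for i in range(8)]
        )
        seg, chosen_pk, res = best_segment_pocket([decoy, planted], [pk])
        assert seg is planted
        assert res.rmsd < 1e-6

    def test_tie_breaks_to_first(self):
        pk = PocketModel(helix(8).residues)
        seg_a = StructureModel(list(pk.residues), segment_id="a")
        seg_b = StructureModel(list(pk.residues), segment_id="b")
        seg, _, _ = best_segment_pocket([seg_a, seg_b], [pk])
        assert seg is seg_a


PDB_RECORD = "{kind:<6}{serial:>5} {name:^4}{alt:1}{res:<3} {chain:1}{resseq:>4}{icode:1}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}          {elem:>2}\n"


def write_tiny_pdb(path):
    """Three alanines around the origin plus one ligand heteroatom."""
    lines = []
    serial = 1
    ca_positions = [(0.0, 0.0, 0.0), (3.8, 0.0, 0.0), (7.6, 1.0, 0.0)]
    for i, (x, y, z) in enumerate(ca_positions, start=1):
        for name, dx, elem in (("N", -1.0, "N"), ("CA", 0.0, "C"), ("CB", 0.8, "C")):
            lines.append(
                PDB_RECORD.format(
                    kind="ATOM", serial=serial, name=name, alt="", res="ALA",
                    chain="A", resseq=i, icode="", x=x + dx, y=y, z=z,
                    occ=1.0, b=0.0, elem=elem,
                )
            )
            serial += 1
    lines.append(
        PDB_RECORD.format(
            kind="HETATM", serial=serial, name="C1", alt="", res="LIG",
            chain="A", resseq=99, icode="", x=2.0, y=2.0, z=0.0,
            occ=1.0, b=0.0, elem="C",
        )
    )
    lines.append("END\n")
    path.write_text("".join(lines))


def test_pdb_round_trip(tmp_path):
    pdb = tmp_path / "tiny.pdb"
    write_tiny_pdb(pdb)
    model = read_structure_pdb(pdb)
    assert [r.index for r in model.residues] == [1, 2, 3]
    assert [r.aa for r in model.residues] == ["A", "A", "A"]
    lig = read_ligand_pdb(pdb, "LIG")
    assert lig.coords.shape == (1, 3)
    pk = extract_pocket(model, lig)
    assert len(pk) >= 2  # residues 1 and 2 are within 4.5 A of the ligand
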