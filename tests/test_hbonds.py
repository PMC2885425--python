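"""Hydrogen-bond detection, occupancy, symmetry collapsing and pair
correlation."""

import math

import numpy as np
import pytest

from oligorder.hbonds import (HBondCriteria, HBondOccupancy, correlation_matrices, detect_hbonds,
                              hbond_correlation, occupancy_matrix, simultaneous_probability)
from oligorder.model import (AtomRecord, EnsembleTrajectory, LigandPolarGroups, OligomerSnapshot,
                             PolarGroup)
from oligorder.synthetic import HBondSeriesSpec, sample_hbond_series


def atom(name, elem, chain, resi, xyz, sym=""):
    return AtomRecord(atom_name=name, element=elem, chain_id=chain, residue_name="ALA",
                      residue_index=resi, coordinates=np.array(xyz, float), symmetry_class=sym)


def donor_acceptor(d_ho: float, angle_deg: float) -> OligomerSnapshot:
    """One N-H donor and one acceptor O at a prescribed H-O distance and
    N-H...O angle."""
    n = atom("N", "N", "A", 1, [0.0, 1.0, 0.0])
    h = atom("H", "H", "A", 1, [0.0, 0.0, 0.0])
    # N-H points -y from N; O placed so the angle at H is `angle_deg`
    theta = math.radians(180.0 - angle_deg)
    o = atom("O", "O", "B", 1, [d_ho * math.sin(theta), -d_ho * math.cos(theta), 0.0])
    ca_a = atom("CA", "C", "A", 1, [1.5, 1.0, 0])
    ca_a2 = atom("CA", "C", "A", 2, [4.5, 1.0, 0])
    ca_a3 = atom("CA", "C", "A", 3, [7.5, 1.0, 0])
    ca_b = atom("CA", "C", "B", 1, [1.5, -9, 0])
    ca_b2 = atom("CA", "C", "B", 2, [4.5, -9, 0])
    ca_b3 = atom("CA", "C", "B", 3, [7.5, -9, 0])
    return OligomerSnapshot([n, h, ca_a, ca_a2, ca_a3, o, ca_b, ca_b2, ca_b3], ["A", "B"])


class TestDetection:
    @pytest.mark.parametrize("d,angle,expected", [
        (1.9, 180.0, True),    # ideal colinear bond
        (2.6, 180.0, False),   # distance fails
        (1.9, 120.0, False),   # angle fails
        (2.5, 180.0, False),   # tie on distance is a non-bond
        (1.9, 130.0, False),   # tie on angle is a non-bond
        (2.49, 131.0, True),   # just inside both criteria
    ])
    def test_criteria_boundaries(self, d, angle, expected):
        bonds = detect_hbonds(donor_acceptor(d, angle))
        assert bool(bonds) is expected

    def test_same_residue_pairs_never_reported(self):
        snap = donor_acceptor(1.9, 180.0)
        # move the acceptor into the donor residue
        moved = [a if a.atom_name != "O" else
                 atom("O", "O", "A", 1, a.coordinates) for a in snap.atoms]
        assert not detect_hbonds(OligomerSnapshot(moved, ["A", "B"]))

    def test_matches_all_pairs_oracle_on_random_frames(self):
        rng = np.random.default_rng(3)
        criteria = HBondCriteria()
        for trial in range(5):
            atoms = []
            for i in range(20):
                chain = "A" if i < 10 else "B"
                n_xyz = rng.uniform(0, 15, 3)
                h_dir = rng.normal(size=3)
                h_dir /= np.linalg.norm(h_dir)
                atoms.append(atom("N", "N", chain, i + 1, n_xyz))
                atoms.append(atom("H", "H", chain, i + 1, n_xyz + h_dir))
                atoms.append(atom("O", "O", chain, i + 1, rng.uniform(0, 15, 3)))
                atoms.append(atom("CA", "C", chain, i + 1, rng.uniform(0, 15, 3)))
            snap = OligomerSnapshot(atoms, ["A", "B"])
            got = {(id(n), id(a)) for n, h, a in detect_hbonds(snap, criteria)}
            # independent scalar oracle over all donor/acceptor pairs
            expected = set()
            by_res = {}
            for a in atoms:
                by_res.setdefault((a.chain_id, a.residue_index), {})[a.atom_name] = a
            for (cid, ri), res in by_res.items():
                n, h = res["N"], res["H"]
                for (cid2, rj), res2 in by_res.items():
                    if (cid, ri) == (cid2, rj):
                        continue
                    o = res2["O"]
                    d = np.linalg.norm(o.coordinates - h.coordinates)
                    v1 = n.coordinates - h.coordinates
                    v2 = o.coordinates - h.coordinates
                    ang = math.degrees(math.acos(np.clip(
                        v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)))
                    if d < 2.5 and ang > 130.0:
                        expected.add((id(n), id(o)))
            assert got == expected

    def test_rigid_transform_invariance(self):
        snap = donor_acceptor(2.2, 150.0)
        assert len(detect_hbonds(snap)) == 1
        rng = np.random.default_rng(9)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        moved = snap.with_coordinates(snap.coordinates() @ q.T + rng.uniform(-30, 30, 3))
        assert len(detect_hbonds(moved)) == 1


def tiny_ligand_system(acceptor_via="OX2"):
    """One peptide N-H donating to one of the ligand carboxylate oxygens."""
    pep = [
        atom("N", "N", "A", 1, [0.0, 1.0, 0.0]), atom("H", "H", "A", 1, [0.0, 0.0, 0.0]),
        atom("CA", "C", "A", 1, [1.5, 1.5, 0]), atom("C", "C", "A", 1, [2.5, 1.0, 0]),
        atom("O", "O", "A", 1, [2.5, 2.2, 0]),
        atom("CA", "C", "A", 2, [4.5, 1.5, 0]), atom("CA", "C", "A", 3, [7.5, 1.5, 0]),
    ]
    bonded = [0.0, -1.9, 0.0]
    parked = [12.0, -8.0, 0.0]
    lig = [
        atom("CC", "C", "L", 1, [0.0, -3.2, 0.0]),
        atom("OX1", "O", "L", 1, parked if acceptor_via == "OX2" else bonded, sym="carbox"),
        atom("OX2", "O", "L", 1, bonded if acceptor_via == "OX2" else parked, sym="carbox"),
    ]
    snap = OligomerSnapshot(pep + lig, ["A"], "L")
    groups = LigandPolarGroups([PolarGroup("CO3", "acceptor", ["OX1", "OX2"])])
    return snap, groups


class TestOccupancy:
    def test_symmetry_equivalent_oxygens_collapse(self):
        for via in ("OX1", "OX2"):
            snap, groups = tiny_ligand_system(acceptor_via=via)
            traj = EnsembleTrajectory(snap, snap.coordinates()[None])
            occ = occupancy_matrix(traj, polar_groups=groups)
            assert occ.pair_labels == ["CO3-NH"]
            assert occ.matrix[0, 0] == 1  # either oxygen satisfies the OR-collapsed row

    def test_no_ligand_yields_backbone_counts_only(self, single_frame_traj):
        occ = occupancy_matrix(single_frame_traj)
        assert occ.pair_labels == []
        assert occ.inter_counts[0] > 0  # the ideal sheet is H-bonded between strands
        assert occ.intra_counts[0] == 0  # extended strands have no internal bonds

    def test_undeclared_group_atom_rejected(self, single_frame_traj):
        groups = LigandPolarGroups([PolarGroup("XX1", "acceptor", ["NOPE"])])
        with pytest.raises(ValueError):
            occupancy_matrix(single_frame_traj, polar_groups=groups)

    def test_scripted_frames_reproduced(self):
        snap, groups = tiny_ligand_system()
        base = snap.coordinates()
        away = base.copy()
        lig_rows = [i for i, a in enumerate(snap.atoms) if a.is_ligand]
        away[lig_rows] += np.array([0.0, -50.0, 0.0])
        frames = np.stack([base, away, base, away, base])
        occ = occupancy_matrix(EnsembleTrajectory(snap, frames), polar_groups=groups)
        assert occ.matrix[0].tolist() == [1, 0, 1, 0, 1]

    def test_residue_rows_or_to_group_row(self):
        snap, groups = tiny_ligand_system()
        traj = EnsembleTrajectory(snap, snap.coordinates()[None])
        g = occupancy_matrix(traj, polar_groups=groups, resolution="group")
        r = occupancy_matrix(traj, polar_groups=groups, resolution="residue")
        combined = (r.matrix.sum(axis=0) > 0).astype(int)
        assert combined.tolist() == g.matrix[0].tolist()


def series_occupancy(h_i, h_j):
    T = len(h_i)
    return HBondOccupancy(pair_labels=["bond_i", "bond_j"], matrix=np.stack([h_i, h_j]),
                          intra_counts=np.zeros(T, int), inter_counts=np.zeros(T, int))


class TestCorrelation:
    def test_always_formed_pair(self):
        occ = series_occupancy(np.ones(10, np.uint8), np.ones(10, np.uint8))
        c, phi = hbond_correlation(occ, "bond_i", "bond_j")
        assert c == 1.0
        assert np.isnan(phi)  # constant series have no defined phi

    def test_disjoint_series(self):
        h_i = np.array([1, 0, 1, 0], np.uint8)
        occ = series_occupancy(h_i, 1 - h_i)
        c, phi = hbond_correlation(occ, 0, 1)
        assert c == 0.0 and phi == pytest.approx(-1.0)

    def test_generator_joint_probability_recovered(self):
        spec = HBondSeriesSpec(T=10 ** 5, p_i=0.3, p_j=0.4, p_ij=0.2, seed=11)
        occ = series_occupancy(*sample_hbond_series(spec))
        c, _ = hbond_correlation(occ, 0, 1)
        assert abs(c - 0.2) <= 3 * np.sqrt(0.2 * 0.8 / spec.T)

    def test_estimator_unbiased_over_seeds(self):
        p_ij, T, n_seeds = 0.2, 2000, 200
        ests = []
        for s in range(n_seeds):
            occ = series_occupancy(*sample_hbond_series(
                HBondSeriesSpec(T=T, p_i=0.3, p_j=0.4, p_ij=p_ij, seed=s)))
            ests.append(correlation_matrices(occ)[0][0, 1])
        se_mean = np.sqrt(p_ij * (1 - p_ij) / T / n_seeds)
        assert abs(np.mean(ests) - p_ij) <= 3 * se_mean

    def test_matrix_properties(self):
        rng = np.random.default_rng(4)
        h = (rng.random((5, 300)) < 0.4).astype(np.uint8)
        occ = HBondOccupancy(pair_labels=[f"b{i}" for i in range(5)], matrix=h,
                             intra_counts=np.zeros(300, int), inter_counts=np.zeros(300, int))
        c, _ = correlation_matrices(occ)
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), h.mean(axis=1))  # c_ii is the marginal
        for i in range(5):
            for j in range(5):
                assert c[i, j] <= min(c[i, i], c[j, j]) + 1e-12
                assert c[i, j] >= 0


class TestSimultaneous:
    def test_singleton_is_marginal(self):
        h_i = np.array([1, 1, 0, 0, 1], np.uint8)
        occ = series_occupancy(h_i, np.ones(5, np.uint8))
        assert simultaneous_probability(occ, ["bond_i"]) == pytest.approx(0.6)

    def test_monotone_in_set_size(self):
        rng = np.random.default_rng(6)
        h = (rng.random((3, 500)) < 0.5).astype(np.uint8)
        occ = HBondOccupancy(pair_labels=["a", "b", "c"], matrix=h,
                             intra_counts=np.zeros(500, int), inter_counts=np.zeros(500, int))
        p1 = simultaneous_probability(occ, ["a"])
        p2 = simultaneous_probability(occ, ["a", "b"])
        p3 = simultaneous_probability(occ, ["a", "b", "c"])
        assert p1 >= p2 >= p3

    def test_scripted_triple_fraction(self):
        # three bonds co-occur in exactly 50 of 1000 frames
        m = np.zeros((3, 1000), np.uint8)
        m[:, :50] = 1
        m[0, 50:400] = 1
        m[1, 50:300] = 1
        occ = HBondOccupancy(pair_labels=["a", "b", "c"], matrix=m,
                             intra_counts=np.zeros(1000, int), inter_counts=np.zeros(1000, int))
        assert simultaneous_probability(occ, ["a", "b", "c"]) == pytest.approx(0.05)

    def test_unknown_label_rejected(self):
        occ = series_occupancy(np.ones(3, np.uint8), np.ones(3, np.uint8))
        with pytest.raises(KeyError):
            simultaneous_probability(occ, ["nope"])
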