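"""Nonbonded pair energies: closed forms, truncation, additivity and
brute-force oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oligorder.energetics import (COULOMB_CONSTANT, NonbondParams, apply_toy_params,
                                  energy_histogram, inter_peptide_energies, ligand_residue_vdw,
                                  pair_energy)
from oligorder.model import AtomRecord, EnsembleTrajectory, OligomerSnapshot
from tests.conftest import make_bead


def brute_force_energy(atoms_a, atoms_b, params: NonbondParams) -> float:
    """Independent scalar double-loop reference."""
    total = 0.0
    for a in atoms_a:
        for b in atoms_b:
            r = float(np.linalg.norm(a.coordinates - b.coordinates))
            if r > params.cutoff:
                continue
            eps = np.sqrt((a.lj_epsilon or 0.0) * (b.lj_epsilon or 0.0))
            rmin = (a.lj_rmin_half or 0.0) + (b.lj_rmin_half or 0.0)
            e = 0.0
            if rmin > 0 and eps > 0:
                e += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
            e += params.coulomb_constant * (a.partial_charge or 0.0) * (b.partial_charge or 0.0) \
                / (params.dielectric * r)
            if params.truncation == "shift":
                e *= (1 - (r / params.cutoff) ** 2) ** 2
            total += e
    return total


def random_groups(rng, n=20, scale=8.0):
    """Two random bead groups with every cross-group pair at least 1 A
    apart (keeps magnitudes away from the r^-12 singularity so absolute
    oracle comparison is meaningful)."""
    while True:
        xa = rng.uniform(0, scale, (n, 3))
        xb = rng.uniform(0, scale, (n, 3)) + np.array([3.0, 0, 0])
        if np.linalg.norm(xa[:, None] - xb[None, :], axis=2).min() > 1.0:
            break
    mk = lambda chain, xyz, i: make_bead(f"X{i}", chain, i + 1, xyz,
                                         q=rng.uniform(-0.5, 0.5), eps=rng.uniform(0, 0.3),
                                         rmh=rng.uniform(0.5, 1.5))
    return ([mk("A", xa[i], i) for i in range(n)], [mk("B", xb[i], i) for i in range(n)])


class TestPairEnergy:
    def test_coulomb_closed_form(self):
        a = [make_bead("A1", "A", 1, [0, 0, 0], q=1.0)]
        b = [make_bead("B1", "B", 1, [3.320716, 0, 0], q=1.0)]
        assert pair_energy(a, b) == pytest.approx(100.0, abs=1e-4)

    def test_beyond_cutoff_is_zero(self):
        a = [make_bead("A1", "A", 1, [0, 0, 0], q=1.0, eps=0.3, rmh=2.0)]
        b = [make_bead("B1", "B", 1, [8.0, 0, 0], q=1.0, eps=0.3, rmh=2.0)]
        assert pair_energy(a, b) == 0.0

    def test_lj_minimum_is_minus_epsilon(self):
        a = [make_bead("A1", "A", 1, [0, 0, 0], eps=0.25, rmh=1.6)]
        b = [make_bead("B1", "B", 1, [3.2, 0, 0], eps=0.25, rmh=1.6)]
        assert pair_energy(a, b) == pytest.approx(-0.25, abs=1e-12)

    def test_overlapping_atoms_rejected(self):
        a = [make_bead("A1", "A", 1, [0, 0, 0], q=1.0)]
        b = [make_bead("B1", "B", 1, [0.05, 0, 0], q=1.0)]
        with pytest.raises(ValueError, match="nonphysical"):
            pair_energy(a, b)

    @pytest.mark.parametrize("truncation", ["hard", "shift"])
    def test_matches_brute_force_oracle(self, truncation):
        rng = np.random.default_rng(7)
        params = NonbondParams(truncation=truncation)
        for _ in range(5):
            ga, gb = random_groups(rng)
            assert pair_energy(ga, gb, params) == pytest.approx(
                brute_force_energy(ga, gb, params), abs=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10 ** 6))
    def test_symmetry_and_rigid_invariance(self, seed):
        rng = np.random.default_rng(seed)
        ga, gb = random_groups(rng, n=6)
        e = pair_energy(ga, gb)
        assert pair_energy(gb, ga) == pytest.approx(e, abs=1e-9)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        t = rng.uniform(-20, 20, 3)
        def moved(group):
            out = []
            for a in group:
                out.append(make_bead(a.atom_name, a.chain_id, a.residue_index,
                                     q @ a.coordinates + t, q=a.partial_charge,
                                     eps=a.lj_epsilon, rmh=a.lj_rmin_half))
            return out
        assert pair_energy(moved(ga), moved(gb)) == pytest.approx(e, abs=1e-9)

    def test_truncation_boundary(self):
        params = NonbondParams(cutoff=7.5)
        mk = lambda x: ([make_bead("A1", "A", 1, [0, 0, 0], q=0.5)],
                        [make_bead("B1", "B", 1, [x, 0, 0], q=0.5)])
        inside = pair_energy(*mk(7.49), params)
        outside = pair_energy(*mk(7.51), params)
        assert inside == pytest.approx(COULOMB_CONSTANT * 0.25 / 7.49, abs=1e-12)
        assert outside == 0.0


def snapshot_of(groups, ligand_chain=None, n_res=1):
    atoms = [a for g in groups for a in g]
    chains = sorted({a.chain_id for a in atoms if a.chain_id != ligand_chain})
    return OligomerSnapshot(atoms, chains, ligand_chain)


class TestInterPeptide:
    def _collinear_trimer(self, spacing=6.0):
        """A at 0, B at `spacing`, C at 2x: A-C beyond the 7.5 cutoff."""
        mk = lambda chain, x: [make_bead("CA", chain, i + 1, [x + 0.8 * i, 0, 0],
                                         q=0.2, eps=0.2, rmh=1.5) for i in range(3)]
        return mk("A", 0.0), mk("B", spacing), mk("C", 2 * spacing)

    def test_center_sums_edges(self):
        ga, gb, gc = self._collinear_trimer()
        snap = snapshot_of([ga, gb, gc])
        traj = EnsembleTrajectory(snap, snap.coordinates()[None])
        prof = inter_peptide_energies(traj)
        e_ab = pair_energy(ga, gb)
        e_bc = pair_energy(gb, gc)
        assert pair_energy(ga, gc) == 0.0
        assert prof.per_peptide[0].tolist() == pytest.approx([e_ab, e_ab + e_bc, e_bc], abs=1e-10)
        # additivity: E_p equals the row sum of the pair matrix, exactly
        assert np.array_equal(prof.per_peptide, prof.pair_matrix.sum(axis=2))
        assert np.allclose(prof.pair_matrix, prof.pair_matrix.transpose(0, 2, 1))

    def test_far_apart_chains_all_zero(self):
        mk = lambda chain, x: [make_bead("CA", chain, 1, [x, 0, 0], q=1.0, eps=0.3, rmh=2.0)]
        snap = snapshot_of([mk("A", 0.0), mk("B", 20.0), mk("C", 40.0)])
        traj = EnsembleTrajectory(snap, snap.coordinates()[None])
        assert not inter_peptide_energies(traj).per_peptide.any()

    def test_ligand_never_contributes(self):
        ga, gb, gc = self._collinear_trimer()
        without = snapshot_of([ga, gb, gc])
        lig = [make_bead("L1", "L", 1, [6.0, 1.5, 0], q=1.0, eps=0.5, rmh=2.0)]
        with_lig = snapshot_of([ga, gb, gc, lig], ligand_chain="L")
        e0 = inter_peptide_energies(EnsembleTrajectory(without, without.coordinates()[None]))
        e1 = inter_peptide_energies(EnsembleTrajectory(with_lig, with_lig.coordinates()[None]))
        assert np.array_equal(e0.pair_matrix, e1.pair_matrix)


class TestLigandResidueVdw:
    def _liganded(self, lig_x):
        pep = [make_bead("CA", "A", i + 1, [3.8 * i, 0, 0], eps=0.2, rmh=1.6) for i in range(3)] \
            + [make_bead("CA", "B", i + 1, [3.8 * i, 30, 0], eps=0.2, rmh=1.6) for i in range(3)] \
            + [make_bead("CA", "C", i + 1, [3.8 * i, 60, 0], eps=0.2, rmh=1.6) for i in range(3)]
        lig = [make_bead("L1", "L", 1, [lig_x, 3.2, 0], eps=0.2, rmh=1.6)]
        return snapshot_of([pep, lig], ligand_chain="L")

    def test_out_of_contact_frames_skipped(self):
        near = self._liganded(0.0)
        far = self._liganded(500.0)
        frames = np.stack([near.coordinates(), far.coordinates()])
        traj = EnsembleTrajectory(near, frames)
        prof = ligand_residue_vdw(traj)
        assert prof.frames_used == 1
        # the mean equals the contact-frame energy, not half of it
        single = ligand_residue_vdw(EnsembleTrajectory(near, near.coordinates()[None]))
        assert prof.mean_vdw == pytest.approx(single.mean_vdw, abs=1e-12)

    def test_never_in_contact_flagged_undefined(self):
        far = self._liganded(500.0)
        prof = ligand_residue_vdw(EnsembleTrajectory(far, far.coordinates()[None]))
        assert prof.frames_used == 0 and not prof.defined
        assert np.isnan(prof.mean_vdw).all()

    def test_two_frame_hand_calculation(self):
        snap = self._liganded(0.0)
        frames = np.stack([snap.coordinates(), snap.coordinates()])
        frames[1, -1, 1] = 4.0  # move the ligand bead in frame 2
        traj = EnsembleTrajectory(snap, frames)
        prof = ligand_residue_vdw(traj)
        lig = snap.ligand_atoms()
        res_a1 = [a for a in snap.atoms if a.chain_id == "A" and a.residue_index == 1]
        e1 = pair_energy(lig, res_a1)
        moved = [make_bead("L1", "L", 1, [0, 4.0, 0], eps=0.2, rmh=1.6)]
        e2 = pair_energy(moved, res_a1)
        idx = prof.residues.index(("A", 1, "ALA"))
        assert prof.mean_vdw[idx] == pytest.approx((e1 + e2) / 2, abs=1e-10)

    def test_no_ligand_rejected(self, single_frame_traj):
        with pytest.raises(ValueError):
            ligand_residue_vdw(single_frame_traj)


class TestEnergyHistogram:
    def test_three_events_per_frame_and_normalization(self):
        pep = snapshot_of([[make_bead("CA", c, 1, [x, 0, 0], q=0.3, eps=0.2, rmh=1.5)]
                           for c, x in (("A", 0), ("B", 4), ("C", 8))])
        traj = EnsembleTrajectory(pep, pep.coordinates()[None])
        prof = inter_peptide_energies(traj)
        edges, freqs = energy_histogram(prof)
        assert freqs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_single_bin(self):
        pep = snapshot_of([[make_bead("CA", c, 1, [x, 0, 0])] for c, x in
                           (("A", 0), ("B", 40), ("C", 80))])
        traj = EnsembleTrajectory(pep, pep.coordinates()[None])
        edges, freqs = energy_histogram(inter_peptide_energies(traj))
        assert (freqs > 0).sum() == 1 and freqs.max() == 1.0
        nz = np.nonzero(freqs)[0][0]
        assert edges[nz] <= 0 <= edges[nz + 1]

    def test_ordered_mixture_center_vs_edge_modes(self):
        from oligorder.synthetic import SheetSpec, build_sheet_trimer
        frames = []
        snap0 = None
        for s in range(30):
            snap = build_sheet_trimer(SheetSpec(positional_noise_sigma=0.2, seed=s))
            if snap0 is None:
                snap0 = snap
                apply_toy_params(snap0.atoms)
            frames.append(snap.coordinates())
        traj = EnsembleTrajectory(snap0, np.stack(frames))
        prof = inter_peptide_energies(traj)
        edge = prof.per_peptide[:, [0, 2]].mean()
        center = prof.per_peptide[:, 1].mean()
        assert center == pytest.approx(2 * edge, rel=0.2)
        assert center < edge < 0
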