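"""Pairwise nonbonded energetics between chains.

The interaction energy between two atom groups is the sum over atom
pairs within a hard distance cutoff (default 7.5 Angstrom) of a 12-6
Lennard-Jones term in CHARMM Rmin convention plus a Coulomb term,

    E = sum_{r_ij <= rc} eps_ij [ (Rmin_ij/r)^12 - 2 (Rmin_ij/r)^6 ]
                         + C q_i q_j / (D r),

with Lorentz-Berthelot combining (eps_ij = sqrt(eps_i eps_j),
Rmin_ij = Rmin_i/2 + Rmin_j/2) and C = 332.0716 kcal*A/(mol*e^2).  Only
inter-chain terms are ever evaluated, so no bonded exclusions are
needed.  The per-peptide "interaction energy with the other two" used to
profile oligomer order is the row sum of the pair matrix, always
excluding the ligand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import AtomRecord, EnsembleTrajectory

log = logging.getLogger("oligorder.energetics")

__all__ = [
    "NonbondParams",
    "InterPeptideEnergyProfile",
    "LigandResidueVdwProfile",
    "pair_energy",
    "inter_peptide_energies",
    "ligand_residue_vdw",
    "energy_histogram",
    "apply_toy_params",
    "TOY_ATOM_PARAMS",
]

COULOMB_CONSTANT = 332.0716  # kcal*A/(mol*e^2), CHARMM convention
MIN_CONTACT = 0.1            # Angstrom; closer pairs are nonphysical input

#: minimal Calpha-level bead parameter set for synthetic ensembles whose
#: files carry no force-field parameters: one interaction site per
#: residue (the CA atom) with a generic bead Lennard-Jones well and a
#: residue-type net charge; all other atoms are inert.  Deliberately
#: generic — energy *distribution shapes*, not absolute magnitudes, are
#: the analysis target.
TOY_BEAD_LJ = (0.30, 2.60)  # epsilon kcal/mol, Rmin/2 A
TOY_RESIDUE_CHARGES: dict[str, float] = {
    "LYS": +0.1, "ARG": +0.1, "HIS": +0.05,
    "ASP": -0.1, "GLU": -0.1,
}
# kept for backward-compatible introspection of the bead model
TOY_ATOM_PARAMS = {"CA": (0.0, *TOY_BEAD_LJ)}


def apply_toy_params(atoms: Sequence["AtomRecord"], overwrite: bool = False) -> None:
    """Fill in the Calpha-bead toy parameter set in place.

    Peptide CA atoms (and ligand carbons, treated as ligand beads) get
    the bead LJ well; CA beads carry the residue-type charge; everything
    else is inert.  Atoms that already have parameters keep them unless
    ``overwrite``.
    """
    eps, rmh = TOY_BEAD_LJ
    for a in atoms:
        if a.partial_charge is not None and not overwrite:
            continue
        if a.atom_name == "CA" and not a.is_ligand:
            a.partial_charge = TOY_RESIDUE_CHARGES.get(a.residue_name, 0.0)
            a.lj_epsilon, a.lj_rmin_half = eps, rmh
        elif a.is_ligand and a.element.upper() == "C":
            a.partial_charge, a.lj_epsilon, a.lj_rmin_half = 0.0, eps, rmh
        else:
            a.partial_charge, a.lj_epsilon, a.lj_rmin_half = 0.0, 0.0, 0.0


@dataclass
class NonbondParams:
    """Nonbonded interaction settings.

    ``truncation`` is "hard" (plain cutoff) or "shift" (energies scaled
    by (1 - (r/rc)^2)^2 so they vanish smoothly at the cutoff).
    """

    cutoff: float = 7.5
    coulomb_constant: float = COULOMB_CONSTANT
    dielectric: float = 1.0
    truncation: str = "hard"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")
        if self.truncation not in ("hard", "shift"):
            raise ValueError(f"truncation must be 'hard' or 'shift', got {self.truncation!r}")


def _group_params(atoms: Sequence[AtomRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Charges, LJ epsilon and Rmin/2 arrays with zero-filled defaults."""
    q = np.array([a.partial_charge or 0.0 for a in atoms], dtype=float)
    eps = np.array([a.lj_epsilon or 0.0 for a in atoms], dtype=float)
    rmh = np.array([a.lj_rmin_half or 0.0 for a in atoms], dtype=float)
    if np.any(eps < 0):
        raise ValueError("negative Lennard-Jones epsilon")
    return q, eps, rmh


def _pair_energy_arrays(xa: np.ndarray, qa: np.ndarray, ea: np.ndarray, ra: np.ndarray,
                        xb: np.ndarray, qb: np.ndarray, eb: np.ndarray, rb: np.ndarray,
                        params: NonbondParams, vdw_only: bool = False) -> float:
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    if np.any(d < MIN_CONTACT):
        i, j = np.unravel_index(int(np.argmin(d)), d.shape)
        raise ValueError(f"overlapping atoms (r = {d[i, j]:.3f} A < {MIN_CONTACT}): nonphysical input")
    mask = d <= params.cutoff
    if not np.any(mask):
        return 0.0
    r = d[mask]
    rmin = (ra[:, None] + rb[None, :])[mask]
    eps = np.sqrt(ea[:, None] * eb[None, :])[mask]
    s6 = np.zeros_like(r)
    nz = rmin > 0
    s6[nz] = (rmin[nz] / r[nz]) ** 6
    e = eps * (s6 ** 2 - 2.0 * s6)
    if not vdw_only:
        e = e + params.coulomb_constant * (qa[:, None] * qb[None, :])[mask] / (params.dielectric * r)
    if params.truncation == "shift":
        e = e * (1.0 - (r / params.cutoff) ** 2) ** 2
    return float(e.sum())


def pair_energy(atoms_a: Sequence[AtomRecord], atoms_b: Sequence[AtomRecord],
                params: Optional[NonbondParams] = None) -> float:
    """Nonbonded energy (kcal/mol) between two disjoint atom groups.

    Symmetric in its arguments; zero when every pair lies beyond the
    cutoff.  Atoms without charges or LJ parameters contribute nothing.
    """
    params = params or NonbondParams()
    xa = np.array([a.coordinates for a in atoms_a])
    xb = np.array([a.coordinates for a in atoms_b])
    if xa.size == 0 or xb.size == 0:
        return 0.0
    qa, ea, ra = _group_params(atoms_a)
    qb, eb, rb = _group_params(atoms_b)
    return _pair_energy_arrays(xa, qa, ea, ra, xb, qb, eb, rb, params)


@dataclass
class InterPeptideEnergyProfile:
    """Per-frame inter-peptide energies.

    ``pair_matrix[t, p, q]`` is the energy of peptide p with peptide q in
    frame t (symmetric, zero diagonal); ``per_peptide[t, p]`` is the row
    sum, i.e. the energy of peptide p with all other peptides.  Ligand
    terms are excluded by construction.
    """

    chain_ids: list[str]
    pair_matrix: np.ndarray   # (T, P, P)
    per_peptide: np.ndarray   # (T, P)


def inter_peptide_energies(traj: EnsembleTrajectory,
                           params: Optional[NonbondParams] = None) -> InterPeptideEnergyProfile:
    """Pairwise and per-peptide nonbonded energies for every frame,
    never touching the ligand."""
    params = params or NonbondParams()
    topo = traj.topology
    cids = list(topo.peptide_chain_ids)
    if len(cids) < 2:
        raise ValueError("need at least 2 peptide chains")
    masks = [np.array([a.chain_id == cid for a in topo.atoms]) for cid in cids]
    groups = [[a for a in topo.atoms if a.chain_id == cid] for cid in cids]
    gp = [_group_params(g) for g in groups]

    P = len(cids)
    pair = np.zeros((traj.n_frames, P, P))
    for t in range(traj.n_frames):
        xyz = traj.frames[t]
        for p in range(P):
            for q in range(p + 1, P):
                e = _pair_energy_arrays(xyz[masks[p]], *gp[p], xyz[masks[q]], *gp[q], params)
                pair[t, p, q] = pair[t, q, p] = e
    per = pair.sum(axis=2)
    log.info("inter-peptide energies: %d frames x %d peptides, mean E_p = %.2f kcal/mol",
             traj.n_frames, P, float(per.mean()))
    return InterPeptideEnergyProfile(chain_ids=cids, pair_matrix=pair, per_peptide=per)


@dataclass
class LigandResidueVdwProfile:
    """Mean ligand-residue van der Waals energies over contact frames.

    Frames in which the ligand touches no residue at all are excluded
    from the averages; ``frames_used`` counts the rest.  ``mean_vdw`` is
    NaN-filled (undefined) when no frame had any contact.
    """

    residues: list[tuple[str, int, str]]  # (chain, residue_index, residue_name)
    mean_vdw: np.ndarray                  # (n_residues,), kcal/mol
    frames_used: int

    @property
    def defined(self) -> bool:
        return self.frames_used > 0


def ligand_residue_vdw(traj: EnsembleTrajectory,
                       params: Optional[NonbondParams] = None) -> LigandResidueVdwProfile:
    """Per-residue mean Lennard-Jones energy between the ligand and each
    peptide residue, averaged only over frames with at least one nonzero
    ligand-residue interaction."""
    params = params or NonbondParams()
    topo = traj.topology
    if topo.ligand_chain_id is None:
        raise ValueError("trajectory has no ligand chain")
    lig = topo.ligand_atoms()
    lig_mask = np.array([a.is_ligand for a in topo.atoms])
    lig_gp = _group_params(lig)

    residues: list[tuple[str, int, str]] = []
    res_masks = []
    res_gps = []
    for cid in topo.peptide_chain_ids:
        for ridx in topo.residue_indices(cid):
            group = [a for a in topo.atoms if a.chain_id == cid and a.residue_index == ridx]
            residues.append((cid, ridx, group[0].residue_name))
            res_masks.append(np.array([a.chain_id == cid and a.residue_index == ridx for a in topo.atoms]))
            res_gps.append(_group_params(group))

    per_frame = np.zeros((traj.n_frames, len(residues)))
    for t in range(traj.n_frames):
        xyz = traj.frames[t]
        for r, (mask, gp) in enumerate(zip(res_masks, res_gps)):
            per_frame[t, r] = _pair_energy_arrays(xyz[lig_mask], *lig_gp, xyz[mask], *gp,
                                                  params, vdw_only=True)
    contact = np.abs(per_frame).sum(axis=1) > 0
    frames_used = int(contact.sum())
    if frames_used == 0:
        mean = np.full(len(residues), np.nan)
    else:
        mean = per_frame[contact].mean(axis=0)
    log.info("ligand-residue vdW profile: %d/%d contact frames", frames_used, traj.n_frames)
    return LigandResidueVdwProfile(residues=residues, mean_vdw=mean, frames_used=frames_used)


def energy_histogram(profile: InterPeptideEnergyProfile,
                     bin_width: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Frequency histogram of per-(frame, peptide) interaction energies.

    Bin edges are aligned to multiples of ``bin_width`` (kcal/mol) so
    zero sits on an edge; frequencies sum to 1.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    values = profile.per_peptide.ravel()
    if values.size == 0:
        raise ValueError("empty energy profile")
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts / counts.sum()
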