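"""Binding-mode extraction and RMSD leader clustering.

Recurring ligand-peptide binding conformations are defined by a set of
simultaneously formed hydrogen bonds: frames where every required
labeled bond is present are extracted and clustered on heavy-atom RMSD
with a deterministic leader (first-fit) algorithm at a 1.5 Angstrom
cutoff.  The RMSD atom set is the ligand's heavy atoms plus the peptide
heavy atoms near the ligand in the first selected frame, with declared
symmetry-equivalent atoms excluded so that chemically indistinguishable
flips (e.g. swapped carboxylate oxygens) do not split clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .hbonds import HBondOccupancy
from .model import EnsembleTrajectory, OligomerSnapshot

log = logging.getLogger("oligorder.modes")

__all__ = [
    "ModeSelectionSpec",
    "BindingModeCluster",
    "select_mode_frames",
    "superpose",
    "cluster_modes",
]


@dataclass
class ModeSelectionSpec:
    """How binding-mode frames are selected and clustered.

    ``required_pairs`` are occupancy row labels that must be formed
    simultaneously; ``atom_selection_radius`` picks peptide heavy atoms
    near the ligand; ``rmsd_cutoff`` is the leader-clustering threshold.
    ``contact_reference`` chooses whether "near the ligand" is evaluated
    on the first selected frame (default) or on the union over frames.
    """

    required_pairs: list[str]
    atom_selection_radius: float = 4.5
    rmsd_cutoff: float = 1.5
    contact_reference: str = "first_frame"  # or "any_frame"

    def __post_init__(self) -> None:
        if not self.required_pairs:
            raise ValueError("required_pairs must be non-empty")
        if self.atom_selection_radius <= 0 or self.rmsd_cutoff <= 0:
            raise ValueError("radius and cutoff must be positive")
        if self.contact_reference not in ("first_frame", "any_frame"):
            raise ValueError("contact_reference must be 'first_frame' or 'any_frame'")


@dataclass
class BindingModeCluster:
    """One binding mode: member frames (trajectory indices), its share of
    the selected frames, the medoid representative and the mean
    member-to-member RMSD."""

    member_frames: list[int]
    frequency: float
    representative_frame: int
    representative: OligomerSnapshot
    mean_internal_rmsd: float

    @property
    def size(self) -> int:
        return len(self.member_frames)


def select_mode_frames(occupancy: HBondOccupancy, spec: ModeSelectionSpec) -> np.ndarray:
    """Frame indices where all required hydrogen bonds are simultaneously
    formed.  An empty selection is allowed (with a warning)."""
    idx = [occupancy.index(label) for label in spec.required_pairs]
    mask = np.all(occupancy.matrix[idx] == 1, axis=0)
    frames = np.nonzero(mask)[0]
    if frames.size == 0:
        log.warning("no frame forms all of %s simultaneously", spec.required_pairs)
    return frames


def superpose(reference: np.ndarray, mobile: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto
    ``reference`` (Kabsch algorithm).

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` best fits the reference; the
    rotation is proper (determinant +1).
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError(f"coordinate sets must share shape (n, 3); got {ref.shape} vs {mob.shape}")
    if ref.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    a = ref - ref_c
    b = mob - mob_c
    h = b.T @ a
    u, s, vt = np.linalg.svd(h)
    # rank-deficient (collinear/planar-degenerate) sets have no unique fit
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) coordinate set: superposition is ill-defined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ref_c - rot @ mob_c
    moved = b @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return rot, trans, rmsd


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return superpose(a, b)[2]


def _cluster_atom_indices(traj: EnsembleTrajectory, frames: Sequence[int],
                          spec: ModeSelectionSpec,
                          symmetry_exclusions: Optional[Sequence[str]] = None) -> np.ndarray:
    """Heavy-atom RMSD set: all ligand heavy atoms plus peptide heavy
    atoms within the selection radius of any ligand atom (in the first
    selected frame, or in any frame), minus declared symmetry classes."""
    topo = traj.topology
    atoms = topo.atoms
    excluded = set(symmetry_exclusions or [])
    lig_idx = np.array([i for i, a in enumerate(atoms) if a.is_ligand and a.is_heavy])
    pep_idx = np.array([i for i, a in enumerate(atoms)
                        if not a.is_ligand and a.is_heavy and a.chain_id in topo.peptide_chain_ids])
    if lig_idx.size == 0:
        raise ValueError("trajectory has no ligand heavy atoms")

    check_frames = [frames[0]] if spec.contact_reference == "first_frame" else list(frames)
    near = np.zeros(pep_idx.size, dtype=bool)
    for t in check_frames:
        xyz = traj.frames[t]
        d = np.linalg.norm(xyz[pep_idx][:, None, :] - xyz[lig_idx][None, :, :], axis=2)
        near |= (d.min(axis=1) <= spec.atom_selection_radius)

    sel = np.concatenate([lig_idx, pep_idx[near]])
    # drop symmetry-equivalent atoms: the named classes, or every
    # declared class when none are named explicitly
    def drop(i: int) -> bool:
        sc = atoms[i].symmetry_class
        return bool(sc) and (sc in excluded if excluded else True)

    return np.sort(np.array([i for i in sel if not drop(i)]))


def cluster_modes(traj: EnsembleTrajectory, frames: Sequence[int], spec: ModeSelectionSpec,
                  symmetry_exclusions: Optional[Sequence[str]] = None) -> list[BindingModeCluster]:
    """Leader clustering of selected frames on the binding-site heavy
    atoms.

    Frames are visited in trajectory order; each joins the first
    existing cluster whose leader lies within ``rmsd_cutoff`` after
    optimal superposition, otherwise it founds a new cluster.  Clusters
    are re-ranked by size (ties by first appearance); the representative
    is the medoid (minimum mean RMSD to co-members, ties broken by
    lowest frame index).  Atoms in declared symmetry classes are
    excluded from the RMSD set; by default every declared class is
    excluded.
    """
    frames = [int(f) for f in frames]
    if not frames:
        raise ValueError("no frames to cluster")
    sel = _cluster_atom_indices(traj, frames, spec, symmetry_exclusions)
    if sel.size < 3:
        raise ValueError(f"binding-site atom set has {sel.size} heavy atoms; need >= 3")
    log.info("clustering %d frames on %d heavy atoms (cutoff %.2f A)",
             len(frames), sel.size, spec.rmsd_cutoff)

    coords = {t: traj.frames[t][sel] for t in frames}
    leaders: list[int] = []
    members: list[list[int]] = []
    for t in frames:
        for k, lead in enumerate(leaders):
            if _rmsd(coords[lead], coords[t]) <= spec.rmsd_cutoff:
                members[k].append(t)
                break
        else:
            leaders.append(t)
            members.append([t])

    order = sorted(range(len(leaders)), key=lambda k: (-len(members[k]), frames.index(leaders[k])))
    out: list[BindingModeCluster] = []
    n_sel = len(frames)
    for k in order:
        mem = members[k]
        if len(mem) == 1:
            med, mean_rmsd = mem[0], 0.0
        else:
            dists = np.zeros((len(mem), len(mem)))
            for a in range(len(mem)):
                for b in range(a + 1, len(mem)):
                    dists[a, b] = dists[b, a] = _rmsd(coords[mem[a]], coords[mem[b]])
            mean_to_others = dists.sum(axis=1) / (len(mem) - 1)
            med = mem[int(np.argmin(mean_to_others))]  # argmin takes the lowest index on ties
            mean_rmsd = float(dists[np.triu_indices(len(mem), 1)].mean())
        out.append(BindingModeCluster(
            member_frames=mem, frequency=len(mem) / n_sel,
            representative_frame=med, representative=traj.snapshot(med),
            mean_internal_rmsd=mean_rmsd))
    return out
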