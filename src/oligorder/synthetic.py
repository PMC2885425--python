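"""Synthetic conformational ensembles with known ground truth.

These generators emulate the study conditions of implicit-solvent
aggregation simulations of three heptapeptide replicas in a cubic box at
5 mg/ml, with or without one small-molecule ligand: idealized parallel or
antiparallel beta-sheet trimers, disordered random-coil trimers, ordered/
disordered mixtures, planted ligand binding poses, and correlated binary
hydrogen-bond time series.  Every generator is a pure function of its
spec (seed included), and stochastic outputs always return their
ground-truth labels so downstream estimators can be validated without
peeking.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import AtomRecord, EnsembleTrajectory, LigandPolarGroups, OligomerSnapshot, PolarGroup

log = logging.getLogger("oligorder.synthetic")

__all__ = [
    "SheetSpec",
    "MixtureSpec",
    "HBondSeriesSpec",
    "build_sheet_trimer",
    "build_disordered_trimer",
    "build_mixture_trajectory",
    "build_ligand_pose_trajectory",
    "sample_hbond_series",
    "concentration_to_box_side",
    "build_ligand_template",
    "default_ligand_polar_groups",
    "attach_ligand",
    "derive_seed",
    "SEGMENT_SEQUENCES",
    "AVERAGE_RESIDUE_MASSES",
]

#: default heptapeptide windows of the amyloid-beta central region,
#: taken from the canonical Abeta sequence (overridable everywhere)
SEGMENT_SEQUENCES = {
    (14, 20): "HQKLVFF",
    (16, 22): "KLVFFAE",
    (18, 24): "VFFAEDV",
}

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: average (dehydrated) residue masses in Da; one water is added per chain
AVERAGE_RESIDUE_MASSES = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

_WATER_MASS = 18.01528
_DALTON_G = 1.66053906660e-24  # g per Da


def derive_seed(seed: int, label: str) -> int:
    """A stable sub-seed (< 2^31) for an independent random stream."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class SheetSpec:
    """An idealized in-register three-strand beta sheet.

    The geometry constants are textbook beta-sheet values: 3.8 Angstrom
    consecutive Calpha spacing along each extended strand and 4.8
    Angstrom between strand axes, with strands stacked along the
    hydrogen-bonding direction.  ``positional_noise_sigma`` is the
    standard deviation of isotropic Gaussian noise added per coordinate.
    """

    n_strands: int = 3
    strand_length: int = 7
    arrangement: str = "parallel"  # or "antiparallel"
    ca_spacing: float = 3.8
    inter_strand_spacing: float = 4.8
    positional_noise_sigma: float = 0.0
    seed: int = 0
    sequence: Optional[str] = None
    first_residue_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ca_spacing <= 0 or self.inter_strand_spacing <= 0:
            raise ValueError("spacings must be positive")
        if self.positional_noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.arrangement not in ("parallel", "antiparallel"):
            raise ValueError(f"arrangement must be parallel or antiparallel, got {self.arrangement!r}")
        if self.sequence is None:
            self.sequence = SEGMENT_SEQUENCES[(14, 20)] if self.strand_length == 7 else "A" * self.strand_length
        if len(self.sequence) != self.strand_length:
            raise ValueError("sequence length does not match strand_length")
        if self.first_residue_index is None:
            self.first_residue_index = 14 if self.sequence == SEGMENT_SEQUENCES[(14, 20)] else 1


@dataclass
class MixtureSpec:
    """A trajectory mixing ordered sheet frames with disordered coils.

    ``ordered_fraction`` is the exact (deterministically rounded) share
    of sheet frames; frame order is shuffled by the seed.
    """

    n_frames: int
    ordered_fraction: float
    sheet: SheetSpec = field(default_factory=SheetSpec)
    disordered_seed: int = 1
    box_side: float = 98.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ordered_fraction <= 1.0):
            raise ValueError("ordered_fraction must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class HBondSeriesSpec:
    """Two correlated binary hydrogen-bond time series.

    Frames are i.i.d. draws from the bivariate Bernoulli with marginals
    ``p_i``, ``p_j`` and joint probability ``p_ij``, which must satisfy
    the Frechet bounds max(0, p_i + p_j - 1) <= p_ij <= min(p_i, p_j).
    """

    T: int
    p_i: float
    p_j: float
    p_ij: float
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_i", "p_j", "p_ij"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        lo = max(0.0, self.p_i + self.p_j - 1.0)
        hi = min(self.p_i, self.p_j)
        if not (lo - 1e-12 <= self.p_ij <= hi + 1e-12):
            raise ValueError(f"p_ij = {self.p_ij} violates Frechet bounds [{lo}, {hi}]")
        if self.T < 1:
            raise ValueError("T must be >= 1")


# ---------------------------------------------------------------------------
# sheet builder
# ---------------------------------------------------------------------------

def _strand_atoms(spec: SheetSpec, strand: int) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Idealized extended-strand backbone for one strand of the sheet.

    Axes: x = strand axis, y = hydrogen-bond (stacking) direction,
    z = pleat.  The amide H and carbonyl O of peptide unit i point along
    (-1)^(i + strand) * y, so adjacent strands present donors and
    acceptors to each other and form near-linear N-H...O bonds.
    """
    L = spec.strand_length
    pleat = 0.7
    dx = math.sqrt(spec.ca_spacing ** 2 - (2 * pleat) ** 2)
    names, coords = [], []
    for i in range(L):
        sigma = -1.0 if (i + strand) % 2 else 1.0
        x0 = i * dx
        n = np.array([x0 - 0.6, 0.4 * sigma, 0.0])
        h = n + np.array([0.0, sigma, 0.0])          # N-H length 1.0
        ca = np.array([x0, 0.0, pleat * (1 if i % 2 == 0 else -1)])
        c = np.array([x0 + 0.6, 0.4 * sigma, 0.0])
        o = c + np.array([0.0, 1.23 * sigma, 0.0])   # C=O length 1.23
        for name, elem, xyz in (("N", "N", n), ("H", "H", h), ("CA", "C", ca),
                                ("C", "C", c), ("O", "O", o)):
            names.append((name, elem))
            coords.append(xyz)
    coords = np.array(coords)
    if spec.arrangement == "antiparallel" and strand % 2 == 1:
        # mirror the strand axis; H/O directions are parity-symmetric
        coords[:, 0] = (L - 1) * dx - coords[:, 0]
    # half-residue stagger of alternate strands: donors face acceptors
    # while carbonyl oxygens of facing strands stay apart
    coords[:, 0] += (strand % 2) * 0.5 * dx
    coords[:, 1] += strand * spec.inter_strand_spacing
    return names, coords


def build_sheet_trimer(spec: SheetSpec) -> OligomerSnapshot:
    """An in-register beta-sheet oligomer (default: three strands).

    At zero noise all Calpha(i) -> Calpha(i+2) vectors are exactly
    parallel, so the nematic order parameter is 1; Gaussian positional
    noise degrades order smoothly.  Deterministic for a fixed seed.
    """
    if spec.strand_length < 3:
        raise ValueError("strand_length must be >= 3 (no molecular vector otherwise)")
    rng = np.random.default_rng(spec.seed)
    chain_ids = [chr(ord("A") + k) for k in range(spec.n_strands)]
    atoms: list[AtomRecord] = []
    for k, cid in enumerate(chain_ids):
        names, coords = _strand_atoms(spec, k)
        if spec.positional_noise_sigma > 0:
            coords = coords + rng.normal(0.0, spec.positional_noise_sigma, coords.shape)
        res_iter = 0
        for (name, elem), xyz in zip(names, coords):
            if name == "N":
                res_iter += 1
            resno = spec.first_residue_index + res_iter - 1
            atoms.append(AtomRecord(
                atom_name=name, element=elem, chain_id=cid,
                residue_name=_ONE_TO_THREE[spec.sequence[res_iter - 1]],
                residue_index=resno, coordinates=xyz,
            ))
    return OligomerSnapshot(atoms, chain_ids)


# ---------------------------------------------------------------------------
# disordered builder
# ---------------------------------------------------------------------------

def _self_avoiding_walk(L: int, step: float, rng: np.random.Generator,
                        min_sep: float = 3.5, max_restart: int = 200) -> np.ndarray:
    """A freely-jointed self-avoiding Calpha walk; successive step
    directions are near-isotropic (backfolding below 45 degrees
    rejected), so orientational memory decays within ~2 residues."""
    for _ in range(max_restart):
        pts = [np.zeros(3)]
        d = _random_unit(rng)
        ok = True
        for _ in range(L - 1):
            placed = False
            for _ in range(80):
                cand_dir = _random_unit(rng)
                if float(cand_dir @ d) > math.cos(math.radians(45.0)):
                    continue  # too straight: keeps the coil compact and decorrelated
                cand = pts[-1] + step * cand_dir
                if all(np.linalg.norm(cand - p) >= min_sep for p in pts[:-1]):
                    pts.append(cand)
                    d = cand_dir
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise RuntimeError(f"self-avoiding walk of length {L} failed after {max_restart} restarts")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _backbone_from_ca(ca: np.ndarray) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Decorate a Calpha trace with idealized N, H, C, O placements in
    local frames, so coil chains share atom layout with sheet chains."""
    L = ca.shape[0]
    names, coords = [], []
    for i in range(L):
        lo = max(i - 1, 0)
        hi = min(i + 1, L - 1)
        t = ca[hi] - ca[lo]
        t = t / np.linalg.norm(t)
        p = np.cross(t, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(p) < 1e-6:
            p = np.cross(t, np.array([1.0, 0.0, 0.0]))
        p = p / np.linalg.norm(p)
        sigma = 1.0 if i % 2 == 0 else -1.0
        n = ca[i] - 0.6 * t + 0.4 * sigma * p
        h = n + sigma * p
        c = ca[i] + 0.6 * t + 0.4 * sigma * p
        o = c + 1.23 * sigma * p
        for name, elem, xyz in (("N", "N", n), ("H", "H", h), ("CA", "C", ca[i]),
                                ("C", "C", c), ("O", "O", o)):
            names.append((name, elem))
            coords.append(xyz)
    return names, np.array(coords)


def build_disordered_trimer(strand_length: int, box_side: float, seed: int,
                            sequence: Optional[str] = None,
                            first_residue_index: Optional[int] = None,
                            n_chains: int = 3,
                            min_interchain_distance: float = 4.0) -> OligomerSnapshot:
    """Three disordered coil chains placed at random in a cubic box.

    Each chain is a self-avoiding random Calpha walk with 3.8 Angstrom
    steps, randomly oriented and positioned; chain placement is rejected
    until every inter-chain Calpha distance is at least
    ``min_interchain_distance``.  Deterministic per seed.
    """
    if strand_length < 3:
        raise ValueError("strand_length must be >= 3")
    if sequence is None:
        sequence = SEGMENT_SEQUENCES[(14, 20)] if strand_length == 7 else "A" * strand_length
    if len(sequence) != strand_length:
        raise ValueError("sequence length does not match strand_length")
    if first_residue_index is None:
        first_residue_index = 14 if sequence == SEGMENT_SEQUENCES[(14, 20)] else 1

    rng = np.random.default_rng(seed)
    margin = 0.15 * box_side
    chain_ids = [chr(ord("A") + k) for k in range(n_chains)]
    placed_cas: list[np.ndarray] = []
    atoms: list[AtomRecord] = []
    for cid in chain_ids:
        for attempt in range(200):
            ca = _self_avoiding_walk(strand_length, 3.8, rng)
            ca = (ca - ca.mean(axis=0)) @ _random_rotation(rng).T
            center = rng.uniform(margin, box_side - margin, size=3)
            ca = ca + center
            if all(np.min(np.linalg.norm(ca[:, None, :] - other[None, :, :], axis=2)) >= min_interchain_distance
                   for other in placed_cas):
                break
        else:
            raise RuntimeError(f"could not place chain {cid} without clashes in a {box_side} A box")
        placed_cas.append(ca)
        names, coords = _backbone_from_ca(ca)
        res_iter = 0
        for (name, elem), xyz in zip(names, coords):
            if name == "N":
                res_iter += 1
            atoms.append(AtomRecord(
                atom_name=name, element=elem, chain_id=cid,
                residue_name=_ONE_TO_THREE[sequence[res_iter - 1]],
                residue_index=first_residue_index + res_iter - 1, coordinates=xyz,
            ))
    return OligomerSnapshot(atoms, chain_ids, box_side=box_side)


# ---------------------------------------------------------------------------
# mixtures
# ---------------------------------------------------------------------------

def build_mixture_trajectory(spec: MixtureSpec) -> tuple[EnsembleTrajectory, np.ndarray]:
    """A trajectory of exactly round(f * n_frames) ordered sheet frames
    and (n_frames - that) disordered frames, deterministically shuffled.

    Returns (trajectory, ground_truth_labels); labels[k] is True when
    frame k was generated by the sheet builder.  Analysis stages must
    never read the labels.
    """
    n_ord = round(spec.ordered_fraction * spec.n_frames)
    base_seed = spec.sheet.seed
    frames, labels = [], []
    topo: Optional[OligomerSnapshot] = None
    for k in range(n_ord):
        s = SheetSpec(**{**spec.sheet.__dict__, "seed": derive_seed(base_seed, f"sheet{k}")})
        snap = build_sheet_trimer(s)
        if topo is None:
            topo = snap
        frames.append(snap.coordinates())
        labels.append(True)
    for k in range(spec.n_frames - n_ord):
        snap = build_disordered_trimer(
            spec.sheet.strand_length, spec.box_side,
            derive_seed(spec.disordered_seed, f"coil{k}"),
            sequence=spec.sheet.sequence, first_residue_index=spec.sheet.first_residue_index)
        if topo is None:
            topo = snap
        frames.append(snap.coordinates())
        labels.append(False)
    order = np.random.default_rng(derive_seed(base_seed, "shuffle")).permutation(spec.n_frames)
    coords = np.stack(frames)[order]
    labels = np.array(labels)[order]
    assert topo is not None
    topo = OligomerSnapshot(topo.atoms, topo.peptide_chain_ids, topo.ligand_chain_id, spec.box_side)
    traj = EnsembleTrajectory(topo, coords, source_tag=f"mixture(f={spec.ordered_fraction})")
    log.info("mixture trajectory: %d frames, %d ordered by construction", spec.n_frames, n_ord)
    return traj, labels


# ---------------------------------------------------------------------------
# ligand template and pose trajectories
# ---------------------------------------------------------------------------

def _hexagon(center: np.ndarray, radius: float = 1.4, phase: float = 0.0) -> np.ndarray:
    ang = phase + np.arange(6) * math.pi / 3
    return center + radius * np.stack([np.cos(ang), np.sin(ang), np.zeros(6)], axis=1)


def build_ligand_template(chain_id: str = "L", residue_name: str = "NQT") -> list[AtomRecord]:
    """A synthetic rigid small-molecule template with the polar-group
    layout of a naphthoquinone-tryptophan hybrid: two quinone carbonyls
    (O1, O2), an anilinic N-H (N1/H1), an indole N-H (NE1/HE1) and a
    carboxylate pair (OX1, OX2, one symmetry class).

    The geometry is an idealized stand-in (fused hexagons plus a short
    linker), not the real compound conformation; analyses only require a
    rigid body with named polar atoms.
    """
    atoms: list[tuple[str, str, np.ndarray, str]] = []  # name, element, xyz, symmetry class
    ringA = _hexagon(np.array([0.0, 0.0, 0.0]))
    ringB = _hexagon(np.array([2.42, 1.4, 0.0]), phase=math.pi / 6)
    for i, xyz in enumerate(ringA):
        atoms.append((f"C{i + 1}", "C", xyz, ""))
    for i, xyz in enumerate(ringB[:4]):
        atoms.append((f"C{i + 7}", "C", xyz, ""))
    # quinone carbonyl oxygens off ring A
    atoms.append(("O1", "O", ringA[1] + np.array([0.0, 0.0, 1.22]), ""))
    atoms.append(("O2", "O", ringA[4] + np.array([0.0, 0.0, 1.22]), ""))
    # anilinic amine on ring A with its hydrogen
    n1 = ringA[0] + np.array([1.0, -1.0, 0.0])
    atoms.append(("N1", "N", n1, ""))
    atoms.append(("H1", "H", n1 + np.array([0.71, -0.71, 0.0]), ""))
    # short aliphatic linker to an indole-like ring and a carboxylate
    cb = n1 + np.array([0.0, -1.5, 0.4])
    cg = cb + np.array([1.2, -0.8, 0.4])
    atoms.append(("CB", "C", cb, ""))
    atoms.append(("CG", "C", cg, ""))
    ringI = _hexagon(cg + np.array([1.5, -1.5, 1.0]), radius=1.2)
    for i, xyz in enumerate(ringI[:4]):
        atoms.append((f"CI{i + 1}", "C", xyz, ""))
    ne1 = ringI[4]
    atoms.append(("NE1", "N", ne1, ""))
    atoms.append(("HE1", "H", ne1 + np.array([-0.8, 0.0, 0.6]), ""))
    cco = cb + np.array([-1.3, -0.6, -0.4])
    atoms.append(("CC", "C", cco, ""))
    atoms.append(("OX1", "O", cco + np.array([-1.05, 0.6, 0.0]), "lig_carboxylate"))
    atoms.append(("OX2", "O", cco + np.array([-0.3, -1.2, 0.0]), "lig_carboxylate"))
    return [
        AtomRecord(atom_name=name, element=elem, chain_id=chain_id, residue_name=residue_name,
                   residue_index=1, coordinates=xyz, symmetry_class=sym, is_ligand=True)
        for name, elem, xyz, sym in atoms
    ]


def default_ligand_polar_groups() -> LigandPolarGroups:
    """Polar-group labels of the template ligand: NH1 (anilinic N-H,
    donor), CO1/CO2 (quinone carbonyls, acceptors), CO3 (the symmetric
    carboxylate oxygen pair, acceptor), NE1 (indole N-H, donor)."""
    return LigandPolarGroups([
        PolarGroup("NH1", "donor", ["N1"]),
        PolarGroup("CO1", "acceptor", ["O1"]),
        PolarGroup("CO2", "acceptor", ["O2"]),
        PolarGroup("CO3", "acceptor", ["OX1", "OX2"]),
        PolarGroup("NE1", "donor", ["NE1"]),
    ])


def attach_ligand(snapshot: OligomerSnapshot, ligand_atoms: Optional[Sequence[AtomRecord]] = None,
                  position: Optional[np.ndarray] = None) -> OligomerSnapshot:
    """Add a ligand chain to a peptide snapshot, centred at ``position``
    (default: 8 Angstrom off the oligomer centroid along +y)."""
    if ligand_atoms is None:
        ligand_atoms = build_ligand_template()
    lig_coords = np.array([a.coordinates for a in ligand_atoms])
    centroid = lig_coords.mean(axis=0)
    if position is None:
        pep = np.array([a.coordinates for a in snapshot.atoms])
        position = pep.mean(axis=0) + np.array([0.0, 8.0, 0.0])
    shift = np.asarray(position, float) - centroid
    moved = [AtomRecord(atom_name=a.atom_name, element=a.element, chain_id=a.chain_id,
                        residue_name=a.residue_name, residue_index=a.residue_index,
                        coordinates=a.coordinates + shift, partial_charge=a.partial_charge,
                        lj_epsilon=a.lj_epsilon, lj_rmin_half=a.lj_rmin_half,
                        symmetry_class=a.symmetry_class)
             for a in ligand_atoms]
    lig_chain = moved[0].chain_id
    return OligomerSnapshot(list(snapshot.atoms) + moved, list(snapshot.peptide_chain_ids),
                            lig_chain, snapshot.box_side)


def build_ligand_pose_trajectory(template: OligomerSnapshot,
                                 poses: Sequence[tuple[np.ndarray, np.ndarray, float]],
                                 n_frames: int, jitter_sigma: float, seed: int,
                                 min_pose_separation: float = 3.0
                                 ) -> tuple[EnsembleTrajectory, np.ndarray]:
    """Frames that place the template's ligand at one of several planted
    rigid poses, chosen multinomially by weight, plus per-atom Gaussian
    jitter on the ligand.

    ``poses`` is a sequence of (rotation 3x3, translation 3-vector,
    weight); rotations act about the ligand centroid.  Weights must sum
    to 1 and planted poses must be separated by more than
    ``min_pose_separation`` (ligand-atom RMSD at fixed peptide frame,
    i.e. twice the default clustering cutoff) so clusters are
    identifiable.  Returns (trajectory, ground-truth pose labels).
    """
    if template.ligand_chain_id is None:
        raise ValueError("template has no ligand chain")
    weights = np.array([w for _, _, w in poses], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"pose weights must sum to 1, got {weights.sum()}")

    lig_mask = np.array([a.is_ligand for a in template.atoms])
    base = template.coordinates()
    lig0 = base[lig_mask]
    centroid = lig0.mean(axis=0)

    posed = []
    for rot, trans, _w in poses:
        rot = np.asarray(rot, float)
        posed.append((lig0 - centroid) @ rot.T + centroid + np.asarray(trans, float))
    for a in range(len(posed)):
        for b in range(a + 1, len(posed)):
            rmsd = math.sqrt(float(np.mean(np.sum((posed[a] - posed[b]) ** 2, axis=1))))
            if rmsd <= min_pose_separation:
                raise ValueError(
                    f"poses {a} and {b} are {rmsd:.2f} A apart (need > {min_pose_separation}); "
                    "clusters would not be identifiable")

    rng = np.random.default_rng(seed)
    labels = rng.choice(len(poses), size=n_frames, p=weights)
    frames = np.repeat(base[None, :, :], n_frames, axis=0)
    for k in range(n_frames):
        lig = posed[labels[k]]
        if jitter_sigma > 0:
            lig = lig + rng.normal(0.0, jitter_sigma, lig.shape)
        frames[k, lig_mask] = lig
    traj = EnsembleTrajectory(template, frames, source_tag=f"planted-poses(n={len(poses)})")
    return traj, labels


# ---------------------------------------------------------------------------
# correlated binary series
# ---------------------------------------------------------------------------

def sample_hbond_series(spec: HBondSeriesSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw two binary series from the bivariate Bernoulli with cells
    (p_ij, p_i - p_ij, p_j - p_ij, 1 - p_i - p_j + p_ij)."""
    cells = np.array([
        spec.p_ij,
        spec.p_i - spec.p_ij,
        spec.p_j - spec.p_ij,
        1.0 - spec.p_i - spec.p_j + spec.p_ij,
    ])
    cells = np.clip(cells, 0.0, None)
    cells = cells / cells.sum()
    rng = np.random.default_rng(spec.seed)
    draw = rng.choice(4, size=spec.T, p=cells)
    h_i = ((draw == 0) | (draw == 1)).astype(np.uint8)
    h_j = ((draw == 0) | (draw == 2)).astype(np.uint8)
    return h_i, h_j


# ---------------------------------------------------------------------------
# concentration bookkeeping
# ---------------------------------------------------------------------------

def concentration_to_box_side(sequences: Sequence[str] | str, n_peptides: Optional[int] = None,
                              concentration: float = 5.0,
                              mass_table: Optional[dict[str, float]] = None) -> float:
    """Cubic box side (Angstrom) for ``n_peptides`` chains at the stated
    mass concentration (mg/ml).

    ``sequences`` is one one-letter sequence applied to every chain, or
    one sequence per chain.  Chain mass is the sum of average residue
    masses plus one water (peptide-bond bookkeeping); the default mass
    table is overridable to match other mass conventions (termini
    protonation, united-atom masses).
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    mass_table = mass_table or AVERAGE_RESIDUE_MASSES
    if isinstance(sequences, str):
        if not sequences:
            raise ValueError("empty sequence")
        if n_peptides is None:
            raise ValueError("n_peptides required with a single sequence")
        sequences = [sequences] * n_peptides
    elif n_peptides is not None and n_peptides != len(sequences):
        raise ValueError("n_peptides does not match number of sequences")
    total_mass = 0.0
    for seq in sequences:
        for code in seq:
            if code not in mass_table:
                raise KeyError(f"unknown residue code {code!r}")
            total_mass += mass_table[code]
        total_mass += _WATER_MASS
    volume_cm3 = total_mass * _DALTON_G / (concentration * 1e-3)
    return (volume_cm3 * 1e24) ** (1.0 / 3.0)
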