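"""Geometric hydrogen-bond detection, occupancy matrices and pair
correlation.

A donor N-H donates to an acceptor O when the H...O distance is smaller
than 2.5 Angstrom and the N-H...O angle is larger than 130 degrees
(strict inequalities; ties are non-bonds).  Ligand polar groups carry
labels (e.g. NH1, CO1, CO3); symmetry-equivalent atoms within a group —
such as the two carboxylate oxygens — are collapsed into a single
labeled pair by logical OR.  Occupancy rows are tracked per frame,
giving binary time series h_i(t) whose pairwise co-occurrence frequency
c_ij = (1/T) sum_t h_i(t) h_j(t) measures how often two bonds are formed
simultaneously; the Pearson phi coefficient is reported alongside as a
normalized alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .model import AtomRecord, EnsembleTrajectory, LigandPolarGroups, OligomerSnapshot

log = logging.getLogger("oligorder.hbonds")

__all__ = [
    "HBondCriteria",
    "HBondOccupancy",
    "detect_hbonds",
    "occupancy_matrix",
    "hbond_correlation",
    "correlation_matrices",
    "simultaneous_probability",
]


@dataclass
class HBondCriteria:
    """Geometric criteria: H-acceptor distance below
    ``max_h_acceptor_distance`` and donor-H-acceptor angle above
    ``min_donor_h_acceptor_angle`` (both strict)."""

    max_h_acceptor_distance: float = 2.5
    min_donor_h_acceptor_angle: float = 130.0
    acceptor_elements: frozenset = frozenset({"O"})

    def __post_init__(self) -> None:
        if self.max_h_acceptor_distance <= 0:
            raise ValueError("distance criterion must be positive")
        if not (0.0 < self.min_donor_h_acceptor_angle <= 180.0):
            raise ValueError("angle criterion must lie in (0, 180]")


def _attach_hydrogens(atoms: Sequence[AtomRecord]) -> list[tuple[int, int]]:
    """(donor_heavy_index, hydrogen_index) pairs: each H is attached to
    the nitrogen of its own residue, by name (H -> N, H1 -> N1, HE1 ->
    NE1 ...) or failing that by proximity (< 1.3 Angstrom)."""
    by_res: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(atoms):
        by_res.setdefault((a.chain_id, a.residue_index), []).append(i)
    pairs: list[tuple[int, int]] = []
    for members in by_res.values():
        nitrogens = [i for i in members if atoms[i].element.upper() == "N"]
        for i in members:
            a = atoms[i]
            if a.element.upper() != "H":
                continue
            target = "N" + a.atom_name[1:].lstrip("N") if a.atom_name.startswith("H") else None
            match = [j for j in nitrogens if target and atoms[j].atom_name == target]
            if not match:
                match = [j for j in nitrogens
                         if np.linalg.norm(atoms[j].coordinates - a.coordinates) < 1.3]
            if match:
                pairs.append((match[0], i))
    return pairs


def detect_hbonds(snapshot: OligomerSnapshot, criteria: Optional[HBondCriteria] = None,
                  donors: Optional[Sequence[tuple[AtomRecord, AtomRecord]]] = None,
                  acceptors: Optional[Sequence[AtomRecord]] = None
                  ) -> list[tuple[AtomRecord, AtomRecord, AtomRecord]]:
    """All (donor N, H, acceptor) triples of a snapshot satisfying the
    geometric criteria.

    By default every residue nitrogen with an attached hydrogen donates
    and every atom whose element is in ``acceptor_elements`` accepts;
    pairs within one residue are never reported.  Nitrogens lacking a
    hydrogen are skipped with a warning.
    """
    criteria = criteria or HBondCriteria()
    atoms = snapshot.atoms
    if donors is None:
        idx_pairs = _attach_hydrogens(atoms)
        donors = [(atoms[i], atoms[j]) for i, j in idx_pairs]
        bonded_n = {id(atoms[i]) for i, _ in idx_pairs}
        for a in atoms:
            if a.element.upper() == "N" and id(a) not in bonded_n:
                log.warning("donor %s/%s%d %s has no attached hydrogen; skipped",
                            a.chain_id, a.residue_name, a.residue_index, a.atom_name)
    if acceptors is None:
        acceptors = [a for a in atoms if a.element.upper() in criteria.acceptor_elements]

    out = []
    cos_min = np.cos(np.radians(criteria.min_donor_h_acceptor_angle))
    for n_atom, h_atom in donors:
        for acc in acceptors:
            if acc.chain_id == n_atom.chain_id and acc.residue_index == n_atom.residue_index:
                continue
            ho = acc.coordinates - h_atom.coordinates
            d = float(np.linalg.norm(ho))
            if not (d < criteria.max_h_acceptor_distance):
                continue
            hn = n_atom.coordinates - h_atom.coordinates
            cosang = float(hn @ ho) / (np.linalg.norm(hn) * d)
            # angle > threshold <=> cos(angle) < cos(threshold)
            if cosang < cos_min:
                out.append((n_atom, h_atom, acc))
    return out


@dataclass
class HBondOccupancy:
    """Binary occupancy of labeled donor-acceptor pairs across frames.

    ``matrix[i, t]`` is 1 when labeled pair i is formed in frame t.
    ``intra_counts``/``inter_counts`` give per-frame numbers of
    backbone-backbone hydrogen bonds within and between peptide chains.
    """

    pair_labels: list[str]
    matrix: np.ndarray            # (n_pairs, T) uint8
    intra_counts: np.ndarray      # (T,)
    inter_counts: np.ndarray      # (T,)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise ValueError("occupancy matrix must be 2-D (pairs x frames)")
        if not np.all((self.matrix == 0) | (self.matrix == 1)):
            raise ValueError("occupancy entries must be binary")

    @property
    def T(self) -> int:
        return int(self.matrix.shape[1])

    def row(self, label: str) -> np.ndarray:
        return self.matrix[self.index(label)]

    def index(self, label: str) -> int:
        try:
            return self.pair_labels.index(label)
        except ValueError:
            raise KeyError(f"no occupancy row labeled {label!r}") from None


def _residue_tag(resname: str, resindex: int) -> str:
    return f"{resname.capitalize()}{resindex}"


def occupancy_matrix(traj: EnsembleTrajectory, criteria: Optional[HBondCriteria] = None,
                     polar_groups: Optional[LigandPolarGroups] = None,
                     resolution: str = "group") -> HBondOccupancy:
    """Per-frame hydrogen-bond occupancy.

    With ligand ``polar_groups`` declared, one row is emitted per labeled
    pair: donor groups pair with any peptide backbone carbonyl ("NH1-CO"
    at group resolution, "NH1-Phe20" at residue resolution, collapsed
    over the three identical chains), acceptor groups pair with peptide
    backbone amides ("CO1-NH" / "CO1-Phe20").  Symmetry-equivalent group
    atoms are OR-collapsed.  Backbone-backbone bond counts (intra- and
    inter-peptide) are always computed.
    """
    if resolution not in ("group", "residue"):
        raise ValueError(f"resolution must be 'group' or 'residue', got {resolution!r}")
    criteria = criteria or HBondCriteria()
    topo = traj.topology
    atoms = topo.atoms
    if polar_groups is not None:
        if topo.ligand_chain_id is None:
            raise ValueError("polar groups declared but trajectory has no ligand")
        polar_groups.validate_against(topo)

    donor_pairs = _attach_hydrogens(atoms)  # (N_idx, H_idx)
    pep_chains = set(topo.peptide_chain_ids)
    is_pep = np.array([a.chain_id in pep_chains for a in atoms])

    # peptide backbone donors/acceptors (atom names N/H and O)
    bb_donors = [(i, j) for i, j in donor_pairs
                 if is_pep[i] and atoms[i].atom_name == "N" and atoms[j].atom_name in ("H", "HN")]
    bb_acceptors = [i for i, a in enumerate(atoms) if is_pep[i] and a.atom_name == "O"]

    lig_donor_pairs = [(i, j) for i, j in donor_pairs if atoms[i].is_ligand]

    # labeled rows: (label, donor (N,H) index pairs, acceptor indices)
    rows: list[tuple[str, list[tuple[int, int]], list[int]]] = []
    pep_residues: list[tuple[int, str]] = []
    seen = set()
    for i, a in enumerate(atoms):
        if is_pep[i] and a.residue_index not in seen:
            seen.add(a.residue_index)
            pep_residues.append((a.residue_index, a.residue_name))
    pep_residues.sort()

    if polar_groups is not None:
        name_to_lig_idx = {}
        for i, a in enumerate(atoms):
            if a.is_ligand:
                name_to_lig_idx.setdefault(a.atom_name, i)
        for g in polar_groups:
            heavy = [name_to_lig_idx[n] for n in g.atom_names]
            if g.role == "donor":
                dpairs = [(i, j) for i, j in lig_donor_pairs if i in heavy]
                if not dpairs:
                    raise ValueError(f"donor group {g.label!r}: no attached hydrogen found")
                if resolution == "group":
                    rows.append((f"{g.label}-CO", dpairs, bb_acceptors))
                else:
                    for ridx, rname in pep_residues:
                        accs = [i for i in bb_acceptors if atoms[i].residue_index == ridx]
                        rows.append((f"{g.label}-{_residue_tag(rname, ridx)}", dpairs, accs))
            else:
                if resolution == "group":
                    rows.append((f"{g.label}-NH", bb_donors, heavy))
                else:
                    for ridx, rname in pep_residues:
                        dons = [(i, j) for i, j in bb_donors if atoms[i].residue_index == ridx]
                        rows.append((f"{g.label}-{_residue_tag(rname, ridx)}", dons, heavy))

    T = traj.n_frames
    matrix = np.zeros((len(rows), T), dtype=np.uint8)
    intra = np.zeros(T, dtype=int)
    inter = np.zeros(T, dtype=int)
    cos_min = np.cos(np.radians(criteria.min_donor_h_acceptor_angle))

    def bonds_mask(xyz, dpairs, accs):
        """Boolean (n_donors, n_acceptors) matrix of satisfied criteria."""
        if not dpairs or not accs:
            return np.zeros((len(dpairs), len(accs)), dtype=bool)
        nh = np.array([(i, j) for i, j in dpairs])
        hi = xyz[nh[:, 1]]
        ni = xyz[nh[:, 0]]
        ax = xyz[np.array(accs)]
        ho = ax[None, :, :] - hi[:, None, :]
        d = np.linalg.norm(ho, axis=2)
        hn = ni - hi
        cosang = np.einsum("dj,daj->da", hn, ho) / (np.linalg.norm(hn, axis=1)[:, None] * np.where(d > 0, d, 1.0))
        ok = (d < criteria.max_h_acceptor_distance) & (cosang < cos_min)
        # never count donor and acceptor of one residue
        same = np.array([[atoms[i].chain_id == atoms[a].chain_id
                          and atoms[i].residue_index == atoms[a].residue_index
                          for a in accs] for i, _ in dpairs])
        return ok & ~same

    for t in range(T):
        xyz = traj.frames[t]
        for r, (_label, dpairs, accs) in enumerate(rows):
            if bonds_mask(xyz, dpairs, accs).any():
                matrix[r, t] = 1
        bb = bonds_mask(xyz, bb_donors, bb_acceptors)
        if bb.any():
            di, ai = np.nonzero(bb)
            for d_idx, a_idx in zip(di, ai):
                same_chain = atoms[bb_donors[d_idx][0]].chain_id == atoms[bb_acceptors[a_idx]].chain_id
                if same_chain:
                    intra[t] += 1
                else:
                    inter[t] += 1

    log.info("occupancy: %d labeled pairs x %d frames; mean backbone H-bonds intra %.2f inter %.2f",
             len(rows), T, float(intra.mean()), float(inter.mean()))
    return HBondOccupancy(pair_labels=[r[0] for r in rows], matrix=matrix,
                          intra_counts=intra, inter_counts=inter)


def correlation_matrices(occupancy: HBondOccupancy) -> tuple[np.ndarray, np.ndarray]:
    """Co-occurrence frequency matrix c and Pearson phi matrix.

    c[i, j] = (1/T) sum_t h_i(t) h_j(t); the diagonal holds marginal
    occupancies.  phi is NaN where a series is constant.
    """
    if occupancy.T < 1 or occupancy.matrix.shape[0] == 0:
        raise ValueError("empty occupancy matrix")
    h = occupancy.matrix.astype(float)
    T = occupancy.T
    c = (h @ h.T) / T
    p = np.diag(c)
    var = p * (1.0 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (c - np.outer(p, p)) / np.sqrt(np.outer(var, var))
    phi[var == 0, :] = np.nan
    phi[:, var == 0] = np.nan
    return c, phi


def hbond_correlation(occupancy: HBondOccupancy, i: Union[int, str], j: Union[int, str]
                      ) -> tuple[float, float]:
    """Co-occurrence frequency c_ij and phi coefficient for one pair of
    labeled hydrogen bonds (indices or row labels)."""
    c, phi = correlation_matrices(occupancy)
    ii = occupancy.index(i) if isinstance(i, str) else i
    jj = occupancy.index(j) if isinstance(j, str) else j
    return float(c[ii, jj]), float(phi[ii, jj])


def simultaneous_probability(occupancy: HBondOccupancy, pair_set: Sequence[Union[int, str]]) -> float:
    """Fraction of frames in which every listed hydrogen bond is formed
    at the same time (monotone non-increasing in the size of the set)."""
    if not pair_set:
        raise ValueError("pair set is empty")
    idx = [occupancy.index(p) if isinstance(p, str) else int(p) for p in pair_set]
    return float(np.all(occupancy.matrix[idx] == 1, axis=0).mean())
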