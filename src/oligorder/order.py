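"""Nematic order analysis of peptide oligomers.

The degree of orientational (beta-sheet-like) order of a multi-peptide
system is measured by the nematic order parameter P2: build one unit
"molecular vector" per residue window by joining the Calpha of residue i
to the Calpha of residue i+2, form the second-rank order matrix

    Q = (1/N) sum_k ( 3/2 u_k u_k^T - 1/2 I ),

and take P2 as its largest eigenvalue.  P2 = 1 when all vectors are
parallel or antiparallel (an ordered in-register sheet), and approaches 0
for an isotropic, fully disordered arrangement.  Frames are classified
ordered/disordered against a crossover threshold P2* (default 0.665) and
summarized as an order:disorder event ratio r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import EnsembleTrajectory, OligomerSnapshot

log = logging.getLogger("oligorder.order")

__all__ = [
    "P2_STAR_DEFAULT",
    "MolecularVectorSet",
    "OrderProfile",
    "OrderRatioReport",
    "molecular_vectors",
    "nematic_p2",
    "order_matrix",
    "classify_order",
    "order_profile",
    "order_disorder_ratio",
    "p2_histogram",
    "decompose_segment",
]

#: crossover between ordered and disordered states
P2_STAR_DEFAULT = 0.665


@dataclass
class MolecularVectorSet:
    """Unit vectors Calpha(i) -> Calpha(i+2), one per (chain, residue i)
    with i <= L-2; a chain of length L contributes L-2 vectors."""

    unit_vectors: np.ndarray  # (N, 3), rows unit norm

    def __post_init__(self) -> None:
        self.unit_vectors = np.asarray(self.unit_vectors, dtype=float)
        if self.unit_vectors.ndim != 2 or self.unit_vectors.shape[1] != 3:
            raise ValueError("unit_vectors must have shape (N, 3)")
        norms = np.linalg.norm(self.unit_vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("molecular vectors must be unit norm")

    @property
    def N(self) -> int:
        return int(self.unit_vectors.shape[0])


@dataclass
class OrderProfile:
    """Per-frame P2 values, directors and order/disorder labels."""

    p2: np.ndarray            # (T,)
    directors: np.ndarray     # (T, 3)
    labels: np.ndarray        # (T,) bool, True = ordered
    p2_star: float = P2_STAR_DEFAULT

    @property
    def n_frames(self) -> int:
        return int(self.p2.shape[0])


@dataclass
class OrderRatioReport:
    n_ordered: int
    n_disordered: int

    @property
    def r(self) -> float:
        """Order:disorder event ratio; infinite when nothing is disordered."""
        if self.n_disordered == 0:
            return float("inf")
        return self.n_ordered / self.n_disordered

    @property
    def is_infinite(self) -> bool:
        return self.n_disordered == 0


def molecular_vectors(snapshot: OligomerSnapshot) -> MolecularVectorSet:
    """Build the normalized Calpha(i) -> Calpha(i+2) vectors of every
    peptide chain (the ligand never contributes)."""
    vecs = []
    for cid in snapshot.peptide_chain_ids:
        cas = snapshot.ca_atoms(cid)
        if len(cas) < 3:
            raise ValueError(f"chain {cid!r}: need >= 3 CA atoms for molecular vectors, have {len(cas)}")
        resids = [a.residue_index for a in cas]
        for k in range(len(cas) - 2):
            if resids[k + 2] - resids[k] != 2:
                raise ValueError(
                    f"chain {cid!r}: missing CA between residues {resids[k]} and {resids[k + 2]}"
                )
            v = cas[k + 2].coordinates - cas[k].coordinates
            n = np.linalg.norm(v)
            if n < 1e-9:
                raise ValueError(f"chain {cid!r} residue {resids[k]}: degenerate (zero-length) molecular vector")
            vecs.append(v / n)
    return MolecularVectorSet(np.array(vecs))


def order_matrix(vectors: MolecularVectorSet) -> np.ndarray:
    """The traceless symmetric order matrix Q (3x3)."""
    u = vectors.unit_vectors
    return 1.5 * (u[:, :, None] * u[:, None, :]).mean(axis=0) - 0.5 * np.eye(3)


def nematic_p2(vectors: MolecularVectorSet) -> tuple[float, np.ndarray]:
    """Largest eigenvalue of the order matrix and its eigenvector (the
    director).  The director's sign is fixed so its first nonzero
    component is positive; eigenvalue degeneracy is broken by
    lexicographic eigenvector order (eigh's deterministic output)."""
    if vectors.N < 2:
        raise ValueError("need at least 2 molecular vectors")
    q = order_matrix(vectors)
    evals, evecs = np.linalg.eigh(q)
    p2 = float(evals[-1])
    director = evecs[:, -1]
    for comp in director:
        if abs(comp) > 1e-12:
            if comp < 0:
                director = -director
            break
    # the largest eigenvalue of the traceless Q lies in [0, 1]; clip roundoff
    return float(np.clip(p2, 0.0, 1.0)), director


def _p2_frames(traj: EnsembleTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-frame P2 over a trajectory (single eigh batch)."""
    topo = traj.topology
    idx_pairs = []  # (i_atom_from, i_atom_to) into the flat atom list
    atom_pos = {id(a): i for i, a in enumerate(topo.atoms)}
    for cid in topo.peptide_chain_ids:
        cas = topo.ca_atoms(cid)
        if len(cas) < 3:
            raise ValueError(f"chain {cid!r}: need >= 3 CA atoms")
        for k in range(len(cas) - 2):
            idx_pairs.append((atom_pos[id(cas[k])], atom_pos[id(cas[k + 2])]))
    src = np.array([p[0] for p in idx_pairs])
    dst = np.array([p[1] for p in idx_pairs])
    v = traj.frames[:, dst, :] - traj.frames[:, src, :]           # (T, N, 3)
    v = v / np.linalg.norm(v, axis=2, keepdims=True)
    q = 1.5 * np.einsum("tni,tnj->tij", v, v) / v.shape[1] - 0.5 * np.eye(3)
    evals, evecs = np.linalg.eigh(q)
    p2 = evals[:, -1]
    directors = evecs[:, :, -1]
    # sign convention: first nonzero component positive
    first = np.where(np.abs(directors[:, 0]) > 1e-12, directors[:, 0],
                     np.where(np.abs(directors[:, 1]) > 1e-12, directors[:, 1], directors[:, 2]))
    directors = directors * np.where(first < 0, -1.0, 1.0)[:, None]
    return p2, directors


def classify_order(p2_values: Sequence[float], p2_star: float = P2_STAR_DEFAULT) -> np.ndarray:
    """ordered iff P2 > P2* (a tie counts as disordered)."""
    p2 = np.asarray(p2_values, dtype=float)
    if np.any((p2 < -1e-9) | (p2 > 1 + 1e-9)):
        raise ValueError("P2 values must lie in [0, 1]")
    return p2 > p2_star


def order_profile(traj: EnsembleTrajectory, p2_star: float = P2_STAR_DEFAULT) -> OrderProfile:
    """Per-frame P2, director and order/disorder label for a trajectory."""
    p2, directors = _p2_frames(traj)
    labels = classify_order(np.clip(p2, 0.0, 1.0), p2_star)
    log.info("order profile: %d frames, %d ordered (P2* = %.3f)", len(p2), int(labels.sum()), p2_star)
    return OrderProfile(p2=p2, directors=directors, labels=labels, p2_star=p2_star)


def order_disorder_ratio(profile: OrderProfile) -> OrderRatioReport:
    """Count ordered vs disordered frames; r = n_ordered / n_disordered."""
    if profile.n_frames == 0:
        raise ValueError("empty order profile")
    n_ord = int(profile.labels.sum())
    return OrderRatioReport(n_ordered=n_ord, n_disordered=profile.n_frames - n_ord)


def p2_histogram(profile: OrderProfile, bin_width: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Frequency histogram of per-frame P2 over [0, 1].

    Returns (bin_edges, frequencies); frequencies sum to 1.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts, _ = np.histogram(np.clip(profile.p2, 0.0, 1.0), bins=edges)
    return edges, counts / counts.sum()


def decompose_segment(start: int, end: int, window: int = 7, step: int = 2) -> list[tuple[int, int]]:
    """Overlapping inclusive residue windows covering [start, end].

    E.g. residues 14-24 with window 7 and step 2 decompose into the three
    heptapeptide windows (14, 20), (16, 22), (18, 24).  Warns when the
    final window stops short of ``end``.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    if end - start + 1 < window:
        raise ValueError(f"segment {start}-{end} shorter than window {window}")
    windows = []
    s = start
    while s + window - 1 <= end:
        windows.append((s, s + window - 1))
        s += step
    if windows[-1][1] != end:
        log.warning("segment decomposition of %d-%d leaves residues %d-%d uncovered by a final window",
                    start, end, windows[-1][1] + 1, end)
    return windows
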