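"""Domain types shared by every analysis stage.

The central objects are :class:`OligomerSnapshot` (one conformation of a
small peptide oligomer, optionally with a bound ligand) and
:class:`EnsembleTrajectory` (an ordered stack of snapshots sharing one
topology).  Coordinates are Cartesian and in Angstrom throughout; residue
numbering is 1-based and may start anywhere (e.g. an amyloid-beta fragment
whose first residue is numbered 14).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Optional, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "OligomerSnapshot",
    "EnsembleTrajectory",
    "PolarGroup",
    "LigandPolarGroups",
    "ShiftTable",
    "RestraintRecord",
    "RESTRAINT_CATEGORIES",
]

_HEAVY_EXCLUDED = {"H", "D"}


@dataclass
class AtomRecord:
    """One atom: identity, position and optional nonbond parameters.

    ``partial_charge`` is in elementary charge units, ``lj_epsilon`` in
    kcal/mol and ``lj_rmin_half`` in Angstrom (CHARMM-style Rmin/2).
    ``symmetry_class`` groups chemically indistinguishable atoms of one
    residue (e.g. the two carboxylate oxygens); empty string means none.
    """

    atom_name: str
    element: str
    chain_id: str
    residue_name: str
    residue_index: int
    coordinates: np.ndarray
    partial_charge: Optional[float] = None
    lj_epsilon: Optional[float] = None
    lj_rmin_half: Optional[float] = None
    is_ligand: bool = False
    symmetry_class: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (3,):
            raise ValueError(f"coordinates must be a 3-vector, got shape {self.coordinates.shape}")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")
        if self.residue_index < 0:
            raise ValueError(f"residue_index must be >= 0, got {self.residue_index}")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HEAVY_EXCLUDED


@dataclass
class OligomerSnapshot:
    """A single frame: atoms partitioned into peptide chains plus an
    optional ligand chain.

    The reference system is three copies of one heptapeptide with zero or
    one ligand molecule; other chain counts are accepted but flagged via
    :attr:`is_reference_system`.
    """

    atoms: list[AtomRecord]
    peptide_chain_ids: list[str]
    ligand_chain_id: Optional[str] = None
    box_side: Optional[float] = None

    def __post_init__(self) -> None:
        chain_ids = {a.chain_id for a in self.atoms}
        for cid in self.peptide_chain_ids:
            if cid not in chain_ids:
                raise ValueError(f"peptide chain {cid!r} has no atoms")
        if self.ligand_chain_id is not None and self.ligand_chain_id not in chain_ids:
            raise ValueError(f"ligand chain {self.ligand_chain_id!r} has no atoms")
        for a in self.atoms:
            a.is_ligand = a.chain_id == self.ligand_chain_id

    # -- selections ---------------------------------------------------
    def chain_atoms(self, chain_id: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.chain_id == chain_id]

    def ligand_atoms(self) -> list[AtomRecord]:
        if self.ligand_chain_id is None:
            return []
        return self.chain_atoms(self.ligand_chain_id)

    def peptide_atoms(self) -> list[AtomRecord]:
        keep = set(self.peptide_chain_ids)
        return [a for a in self.atoms if a.chain_id in keep]

    def coordinates(self) -> np.ndarray:
        """All coordinates as an (n_atoms, 3) array (copy)."""
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    def with_coordinates(self, coords: np.ndarray) -> "OligomerSnapshot":
        """A copy of this snapshot with every atom position replaced."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"expected coordinates of shape ({len(self.atoms)}, 3), got {coords.shape}")
        atoms = [replace(a, coordinates=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return OligomerSnapshot(atoms, list(self.peptide_chain_ids), self.ligand_chain_id, self.box_side)

    def ca_atoms(self, chain_id: str) -> list[AtomRecord]:
        """Calpha atoms of one chain, sorted by residue index."""
        cas = [a for a in self.chain_atoms(chain_id) if a.atom_name == "CA"]
        return sorted(cas, key=lambda a: a.residue_index)

    def residue_indices(self, chain_id: str) -> list[int]:
        return sorted({a.residue_index for a in self.chain_atoms(chain_id)})

    @property
    def is_reference_system(self) -> bool:
        """True for the canonical 3-peptide (+0/1 ligand) system."""
        return len(self.peptide_chain_ids) == 3

    def validate(self) -> None:
        """Check the molecular-vector precondition: every peptide chain
        needs Calpha atoms in >= 3 residues."""
        for cid in self.peptide_chain_ids:
            if len(self.ca_atoms(cid)) < 3:
                raise ValueError(f"peptide chain {cid!r} has fewer than 3 CA atoms")


@dataclass
class EnsembleTrajectory:
    """Ordered frames sharing one topology.

    ``topology`` is a template snapshot whose atom metadata (names,
    chains, charges ...) applies to every frame; ``frames`` is a
    (T, n_atoms, 3) coordinate array. Frame order is the file/generator
    order and is never permuted by analysis stages.
    """

    topology: OligomerSnapshot
    frames: np.ndarray
    frame_ids: Optional[list[int]] = None
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must have shape (T, n_atoms, 3), got {self.frames.shape}")
        if self.frames.shape[1] != len(self.topology.atoms):
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology atom count {len(self.topology.atoms)}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates in trajectory")
        if self.frame_ids is None:
            self.frame_ids = list(range(self.frames.shape[0]))
        elif len(self.frame_ids) != self.frames.shape[0]:
            raise ValueError("frame_ids length does not match frame count")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])

    def snapshot(self, k: int) -> OligomerSnapshot:
        """Materialize frame ``k`` as a full snapshot."""
        return self.topology.with_coordinates(self.frames[k])

    def __iter__(self) -> Iterator[OligomerSnapshot]:
        for k in range(self.n_frames):
            yield self.snapshot(k)

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class PolarGroup:
    """One labeled polar group of the ligand.

    ``atom_names`` with more than one entry marks symmetry-equivalent
    atoms (e.g. the two carboxylate oxygens) that are collapsed by
    logical OR in occupancy analysis.
    """

    label: str
    role: Literal["donor", "acceptor"]
    atom_names: list[str]

    def __post_init__(self) -> None:
        if self.role not in ("donor", "acceptor"):
            raise ValueError(f"role must be donor or acceptor, got {self.role!r}")
        if not self.atom_names:
            raise ValueError(f"polar group {self.label!r} has no atoms")


@dataclass
class LigandPolarGroups:
    """The ligand's labeled hydrogen-bonding groups (e.g. NH1, CO1..CO3, NE1)."""

    groups: list[PolarGroup]

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate polar-group labels")

    def __iter__(self) -> Iterator[PolarGroup]:
        return iter(self.groups)

    def get(self, label: str) -> PolarGroup:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(f"no polar group labeled {label!r}")

    def validate_against(self, snapshot: OligomerSnapshot) -> None:
        """Every named atom must exist in the ligand chain."""
        lig_names = {a.atom_name for a in snapshot.ligand_atoms()}
        for g in self.groups:
            missing = set(g.atom_names) - lig_names
            if missing:
                raise ValueError(f"polar group {g.label!r} names atoms absent from ligand: {sorted(missing)}")


@dataclass
class ShiftTable:
    """A proton chemical-shift assignment table.

    Rows are keyed by (residue_index, nucleus); shifts are in ppm and the
    spectrometer proton frequency in MHz converts ppm deviations to Hz.
    """

    rows: "object"  # pandas.DataFrame with columns residue_index, residue_name, nucleus, shift_ppm
    field_frequency_MHz: float

    def __post_init__(self) -> None:
        import pandas as pd

        df = pd.DataFrame(self.rows)
        required = {"residue_index", "residue_name", "nucleus", "shift_ppm"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"shift table missing columns: {sorted(missing)}")
        if df.duplicated(subset=["residue_index", "nucleus"]).any():
            raise ValueError("duplicate (residue_index, nucleus) keys in shift table")
        if not np.all(np.isfinite(df["shift_ppm"].to_numpy(dtype=float))):
            raise ValueError("non-finite chemical shifts")
        if self.field_frequency_MHz <= 0:
            raise ValueError("field frequency must be positive")
        self.rows = df.reset_index(drop=True)


RESTRAINT_CATEGORIES = ("intra", "i+1", "i+2", "i+3", "long_range")


@dataclass(frozen=True)
class RestraintRecord:
    """One NOE-derived residue-pair restraint; the category follows from
    the sequence separation |i - j| (0 intra, 1 sequential, 2/3 medium,
    >= 4 long range)."""

    residue_i: int
    residue_j: int

    def __post_init__(self) -> None:
        if self.residue_i < 0 or self.residue_j < 0:
            raise ValueError("residue indices must be non-negative")

    @property
    def separation(self) -> int:
        return abs(self.residue_i - self.residue_j)

    @property
    def category(self) -> str:
        s = self.separation
        if s >= 4:
            return "long_range"
        return RESTRAINT_CATEGORIES[s]
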