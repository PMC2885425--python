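"""File I/O: multi-model PDB and XYZ trajectories, topology sidecar
configs, and TSV tables for chemical shifts and NOE restraints.

A PDB file cannot carry partial charges, Lennard-Jones parameters, polar
group labels or symmetry classes, so those travel in a structured YAML
sidecar ("topology config").  For XYZ input the sidecar must also list
the atoms (name/element/chain/residue) in file order, since XYZ carries
elements only.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .model import (
    AtomRecord,
    EnsembleTrajectory,
    LigandPolarGroups,
    OligomerSnapshot,
    PolarGroup,
    RestraintRecord,
    ShiftTable,
)

log = logging.getLogger("oligorder.io")

__all__ = [
    "read_ensemble",
    "write_ensemble",
    "read_topology_config",
    "write_topology_config",
    "read_shift_table",
    "write_shift_table",
    "read_restraints",
    "write_restraints",
    "reconstruct_amide_hydrogens",
]

PathLike = Union[str, Path]

_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


# ---------------------------------------------------------------------------
# topology sidecar
# ---------------------------------------------------------------------------

def read_topology_config(path: PathLike) -> dict:
    """Load and minimally validate a topology sidecar.

    Recognized keys: ``peptide_chains`` (list), ``ligand_chain`` (str or
    null), ``box_side`` (float), ``polar_groups`` (list of
    {label, role, atoms}), ``atom_params`` (list of selector/value maps
    with keys chain, residue_index, atom_name, element, charge, epsilon,
    rmin_half), ``symmetry_classes`` (list of {class, chain,
    residue_name, residue_index, atoms}), ``atoms`` (full per-atom list,
    required for XYZ input), ``termini`` (free-form notes such as declared
    termini charges, passed through to atom_params by the user).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"topology config {path} must be a mapping")
    for key in ("peptide_chains",):
        if key in cfg and not isinstance(cfg[key], list):
            raise ValueError(f"topology config key {key!r} must be a list")
    return cfg


def write_topology_config(snapshot: OligomerSnapshot, path: PathLike,
                          polar_groups: Optional[LigandPolarGroups] = None,
                          include_atoms: bool = True) -> None:
    """Emit a sidecar describing ``snapshot`` (atom list in file order,
    chain partitioning, any charges/LJ parameters and symmetry classes),
    suitable for re-reading an XYZ encoding of the same system."""
    cfg: dict = {
        "peptide_chains": list(snapshot.peptide_chain_ids),
        "ligand_chain": snapshot.ligand_chain_id,
    }
    if snapshot.box_side is not None:
        cfg["box_side"] = float(snapshot.box_side)
    if polar_groups is not None:
        cfg["polar_groups"] = [
            {"label": g.label, "role": g.role, "atoms": list(g.atom_names)} for g in polar_groups
        ]
    if include_atoms:
        atoms = []
        for a in snapshot.atoms:
            rec = {
                "name": a.atom_name,
                "element": a.element,
                "chain": a.chain_id,
                "residue_name": a.residue_name,
                "residue_index": int(a.residue_index),
            }
            if a.partial_charge is not None:
                rec["charge"] = float(a.partial_charge)
            if a.lj_epsilon is not None:
                rec["epsilon"] = float(a.lj_epsilon)
            if a.lj_rmin_half is not None:
                rec["rmin_half"] = float(a.lj_rmin_half)
            if a.symmetry_class:
                rec["symmetry_class"] = a.symmetry_class
            atoms.append(rec)
        cfg["atoms"] = atoms
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def polar_groups_from_config(cfg: dict) -> Optional[LigandPolarGroups]:
    raw = cfg.get("polar_groups")
    if not raw:
        return None
    return LigandPolarGroups([
        PolarGroup(label=g["label"], role=g["role"], atom_names=list(g["atoms"])) for g in raw
    ])


def _apply_atom_params(atoms: list[AtomRecord], cfg: dict) -> None:
    """Apply charge/LJ/symmetry overrides from the sidecar, most specific
    selector last-wins in listed order."""
    for sel in cfg.get("atom_params", []) or []:
        for a in atoms:
            if "chain" in sel and a.chain_id != sel["chain"]:
                continue
            if "residue_index" in sel and a.residue_index != sel["residue_index"]:
                continue
            if "atom_name" in sel and a.atom_name != sel["atom_name"]:
                continue
            if "element" in sel and a.element.upper() != str(sel["element"]).upper():
                continue
            if "charge" in sel:
                a.partial_charge = float(sel["charge"])
            if "epsilon" in sel:
                a.lj_epsilon = float(sel["epsilon"])
            if "rmin_half" in sel:
                a.lj_rmin_half = float(sel["rmin_half"])
    for sc in cfg.get("symmetry_classes", []) or []:
        names = set(sc.get("atoms", []))
        for a in atoms:
            if a.atom_name not in names:
                continue
            if "chain" in sc and a.chain_id != sc["chain"]:
                continue
            if "residue_name" in sc and a.residue_name != sc["residue_name"]:
                continue
            if "residue_index" in sc and a.residue_index != sc["residue_index"]:
                continue
            a.symmetry_class = sc["class"]


# ---------------------------------------------------------------------------
# multi-model PDB
# ---------------------------------------------------------------------------

def _read_pdb(path: PathLike) -> tuple[list[AtomRecord], np.ndarray, Optional[float]]:
    """Parse a multi-model PDB via Biopython; returns (topology atoms of
    model 1, (T, n, 3) coordinates, box side from CRYST1 if cubic)."""
    from Bio.PDB import PDBParser

    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        structure = parser.get_structure("traj", str(path))
    except Exception as exc:  # Biopython raises assorted exceptions on bad input
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc

    box_side = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
                if abs(a - b) < 1e-6 and abs(b - c) < 1e-6:
                    box_side = a
                break

    models = list(structure)
    if not models:
        raise ValueError(f"no MODEL records found in {path}")

    def model_atoms(model):
        out = []
        for chain in model:
            for residue in chain:
                het, resseq, _ = residue.id
                for atom in residue:
                    out.append((chain.id, residue.resname.strip(), int(resseq),
                                atom.get_name(), (atom.element or "").strip() or atom.get_name()[0],
                                het.strip() != "", atom.coord))
        return out

    first = model_atoms(models[0])
    n = len(first)
    coords = np.empty((len(models), n, 3), dtype=float)
    for k, model in enumerate(models):
        rows = model_atoms(model) if k else first
        if len(rows) != n:
            raise ValueError(
                f"frame {k + 1} of {path} has {len(rows)} atoms, expected {n} (atom-count mismatch)"
            )
        for i, row in enumerate(rows):
            coords[k, i] = row[6]

    atoms = [
        AtomRecord(atom_name=name, element=elem, chain_id=cid, residue_name=resname,
                   residue_index=resseq, coordinates=np.array(xyz, dtype=float))
        for (cid, resname, resseq, name, elem, _het, xyz) in first
    ]
    return atoms, coords, box_side


def _infer_chains(atoms: Sequence[AtomRecord]) -> tuple[list[str], Optional[str]]:
    """Without a sidecar, chains made of standard amino acids are
    peptides and any remaining chain is taken as the ligand."""
    order: list[str] = []
    for a in atoms:
        if a.chain_id not in order:
            order.append(a.chain_id)
    peptides = [cid for cid in order
                if all(a.residue_name in _AA3 for a in atoms if a.chain_id == cid)]
    others = [cid for cid in order if cid not in peptides]
    if len(others) > 1:
        raise ValueError(f"cannot infer ligand chain among non-peptide chains {others}; provide a topology config")
    return peptides, (others[0] if others else None)


def read_ensemble(path: PathLike, format: str = "pdb_multimodel",
                  topology_config: Optional[PathLike] = None) -> EnsembleTrajectory:
    """Read a trajectory from a multi-model PDB or an XYZ file.

    Frame order in the file is frame order in the trajectory. For XYZ the
    sidecar must carry an ``atoms`` section (the format stores elements
    only).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cfg = read_topology_config(topology_config) if topology_config else {}

    if format == "pdb_multimodel":
        atoms, coords, box_side = _read_pdb(path)
    elif format == "xyz":
        atoms, coords, box_side = _read_xyz(path, cfg)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")

    if "peptide_chains" in cfg:
        peptide_ids = [str(c) for c in cfg["peptide_chains"]]
        ligand_id = cfg.get("ligand_chain")
    else:
        peptide_ids, ligand_id = _infer_chains(atoms)
    if cfg.get("box_side") is not None:
        box_side = float(cfg["box_side"])

    _apply_atom_params(atoms, cfg)
    topo = OligomerSnapshot(atoms, peptide_ids, ligand_id, box_side)
    if not topo.is_reference_system:
        log.warning("%s: %d peptide chains (reference system has 3)", path, len(peptide_ids))
    traj = EnsembleTrajectory(topo, coords, source_tag=str(path))
    log.info("read %d frames x %d atoms from %s", traj.n_frames, traj.n_atoms, path)
    return traj


def write_ensemble(traj: EnsembleTrajectory, path: PathLike, format: str = "pdb_multimodel") -> None:
    """Write a trajectory as multi-model PDB (fixed width, %.3f Angstrom)
    or XYZ (full precision)."""
    if traj.n_frames == 0:
        raise ValueError("refusing to write an empty trajectory")
    path = Path(path)
    if format == "pdb_multimodel":
        _write_pdb(traj, path)
    elif format == "xyz":
        _write_xyz(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    log.info("wrote %d frames to %s (%s)", traj.n_frames, path, format)


def _write_pdb(traj: EnsembleTrajectory, path: Path) -> None:
    topo = traj.topology
    with open(path, "w") as fh:
        if topo.box_side is not None:
            s = topo.box_side
            fh.write(f"CRYST1{s:9.3f}{s:9.3f}{s:9.3f}  90.00  90.00  90.00 P 1           1\n")
        for k in range(traj.n_frames):
            fh.write(f"MODEL     {k + 1:4d}\n")
            serial = 1
            prev_chain = None
            for a, xyz in zip(topo.atoms, traj.frames[k]):
                if prev_chain is not None and a.chain_id != prev_chain:
                    fh.write("TER\n")
                prev_chain = a.chain_id
                record = "HETATM" if a.is_ligand else "ATOM  "
                name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
                fh.write(
                    f"{record}{serial:5d} {name:<4s} {a.residue_name:<3s} {a.chain_id:1s}"
                    f"{a.residue_index:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"  1.00  0.00          {a.element:>2s}\n"
                )
                serial += 1
            fh.write("TER\nENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def _write_xyz(traj: EnsembleTrajectory, path: Path) -> None:
    topo = traj.topology
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame {k} {traj.source_tag}\n")
            for a, xyz in zip(topo.atoms, traj.frames[k]):
                fh.write(f"{a.element:<2s} {float(xyz[0])!r} {float(xyz[1])!r} {float(xyz[2])!r}\n")


def _read_xyz(path: PathLike, cfg: dict) -> tuple[list[AtomRecord], np.ndarray, Optional[float]]:
    atom_cfg = cfg.get("atoms")
    if not atom_cfg:
        raise ValueError("XYZ input requires a topology config with an 'atoms' section")
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"{path}:{i + 1}: expected atom count, got {lines[i]!r}") from exc
        block = lines[i + 2: i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}: truncated frame starting at line {i + 1}")
        coords = np.empty((n, 3), dtype=float)
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{i + 3 + j}: malformed XYZ record {line!r}")
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ValueError(f"no frames in {path}")
    n = frames[0].shape[0]
    if n != len(atom_cfg):
        raise ValueError(f"XYZ atom count {n} does not match topology config ({len(atom_cfg)} atoms)")
    for k, f in enumerate(frames):
        if f.shape[0] != n:
            raise ValueError(f"frame {k + 1} of {path} has {f.shape[0]} atoms, expected {n}")
    atoms = []
    for rec, xyz in zip(atom_cfg, frames[0]):
        atoms.append(AtomRecord(
            atom_name=rec["name"], element=rec["element"], chain_id=rec["chain"],
            residue_name=rec["residue_name"], residue_index=int(rec["residue_index"]),
            coordinates=xyz.copy(),
            partial_charge=rec.get("charge"), lj_epsilon=rec.get("epsilon"),
            lj_rmin_half=rec.get("rmin_half"), symmetry_class=rec.get("symmetry_class", ""),
        ))
    return atoms, np.stack(frames), cfg.get("box_side")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_shift_table(path: PathLike, field_frequency_MHz: Optional[float] = None) -> ShiftTable:
    """Read a TSV with columns residue_index, residue_name, nucleus,
    shift_ppm (and optionally field_frequency_MHz as a column or comment
    ``# field_frequency_MHz = ...``)."""
    field = field_frequency_MHz
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "field_frequency_MHz" in first and field is None:
        field = float(first.split("=")[1])
    df = pd.read_csv(path, sep="\t", comment="#")
    if field is None and "field_frequency_MHz" in df.columns:
        field = float(df["field_frequency_MHz"].iloc[0])
        df = df.drop(columns=["field_frequency_MHz"])
    if field is None:
        raise ValueError(f"{path}: spectrometer field frequency not given")
    return ShiftTable(rows=df, field_frequency_MHz=field)


def write_shift_table(table: ShiftTable, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# field_frequency_MHz = {table.field_frequency_MHz}\n")
        table.rows.to_csv(fh, sep="\t", index=False)


def read_restraints(path: PathLike) -> list[RestraintRecord]:
    """Read a TSV of residue-pair NOE restraints (columns residue_i,
    residue_j; extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [RestraintRecord(int(r.residue_i), int(r.residue_j)) for r in df.itertuples()]


def write_restraints(records: Sequence[RestraintRecord], path: PathLike) -> None:
    pd.DataFrame({
        "residue_i": [r.residue_i for r in records],
        "residue_j": [r.residue_j for r in records],
    }).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# amide hydrogen reconstruction
# ---------------------------------------------------------------------------

def reconstruct_amide_hydrogens(snapshot: OligomerSnapshot, nh_length: float = 1.0) -> OligomerSnapshot:
    """Place a backbone amide hydrogen on every peptide nitrogen lacking one.

    The hydrogen goes at ``nh_length`` (default 1.0 Angstrom) from N in
    the C(prev)-N-CA plane along the external bisector of the
    C(prev)-N-CA angle — the idealized trans-amide direction.  Existing
    hydrogens are left untouched and the first residue of each chain is
    skipped (no preceding carbonyl).  Residues missing a backbone atom
    are skipped with a warning.
    """
    new_atoms: list[AtomRecord] = [a for a in snapshot.atoms]
    insertions: list[tuple[int, AtomRecord]] = []

    for cid in snapshot.peptide_chain_ids:
        chain = snapshot.chain_atoms(cid)
        by_res: dict[int, dict[str, AtomRecord]] = {}
        for a in chain:
            by_res.setdefault(a.residue_index, {})[a.atom_name] = a
        resids = sorted(by_res)
        for prev_idx, idx in zip(resids, resids[1:]):
            res = by_res[idx]
            has_h = any(name in res for name in ("H", "HN")) or any(
                a.element.upper() == "H" and a.atom_name.startswith("H") and "N" in res
                and np.linalg.norm(a.coordinates - res["N"].coordinates) < 1.2
                for a in res.values()
            )
            if has_h:
                continue
            if "N" not in res or "CA" not in res or "C" not in by_res[prev_idx]:
                log.warning("chain %s residue %d: missing backbone atom, amide H not reconstructed", cid, idx)
                continue
            n = res["N"].coordinates
            u1 = by_res[prev_idx]["C"].coordinates - n
            u2 = res["CA"].coordinates - n
            u1 = u1 / np.linalg.norm(u1)
            u2 = u2 / np.linalg.norm(u2)
            d = -(u1 + u2)
            norm = np.linalg.norm(d)
            if norm < 1e-8:
                log.warning("chain %s residue %d: collinear backbone, amide H not reconstructed", cid, idx)
                continue
            h = AtomRecord(atom_name="H", element="H", chain_id=cid,
                           residue_name=res["N"].residue_name, residue_index=idx,
                           coordinates=n + nh_length * d / norm)
            insertions.append((new_atoms.index(res["N"]), h))

    for pos, h in sorted(insertions, key=lambda t: -t[0]):
        new_atoms.insert(pos + 1, h)
    return OligomerSnapshot(new_atoms, list(snapshot.peptide_chain_ids),
                            snapshot.ligand_chain_id, snapshot.box_side)
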