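"""Reproducible end-to-end runs: generate -> order/energy/hbonds -> modes.

A run is driven by one config mapping (usually a YAML file) with one
global seed; per-stage seeds are derived from it by stable hashing so
each stage has an independent stream and the whole run is deterministic.
Every run directory gets a ``manifest.json`` recording the config hash,
package version and per-stage output row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .energetics import NonbondParams, apply_toy_params, energy_histogram, inter_peptide_energies
from .hbonds import HBondCriteria, correlation_matrices, occupancy_matrix
from .io import write_ensemble
from .modes import ModeSelectionSpec, cluster_modes, select_mode_frames
from .order import order_disorder_ratio, order_profile, p2_histogram
from .synthetic import (MixtureSpec, SheetSpec, attach_ligand, build_ligand_pose_trajectory,
                        build_mixture_trajectory, build_sheet_trimer,
                        default_ligand_polar_groups, derive_seed)

log = logging.getLogger("oligorder.pipeline")

__all__ = ["validate_config", "run_pipeline"]

_KNOWN_TOP = {"seed", "output_dir", "log_level", "generate", "order", "energy", "hbonds", "modes"}


def validate_config(config: dict) -> None:
    """Schema check; raises ValueError listing every offending key."""
    problems = []
    unknown = set(config) - _KNOWN_TOP
    if unknown:
        problems.append(f"unknown keys: {sorted(unknown)}")
    if "seed" not in config:
        problems.append("missing required key: seed (every stochastic stage needs an explicit seed)")
    elif not isinstance(config["seed"], int):
        problems.append("seed must be an integer")
    if "output_dir" not in config:
        problems.append("missing required key: output_dir")
    gen = config.get("generate")
    if gen is None:
        problems.append("missing required section: generate")
    else:
        kind = gen.get("kind")
        if kind not in ("mixture", "ligand_poses"):
            problems.append(f"generate.kind must be 'mixture' or 'ligand_poses', got {kind!r}")
        if not isinstance(gen.get("n_frames"), int) or gen.get("n_frames", 0) < 1:
            problems.append("generate.n_frames must be a positive integer")
        if kind == "mixture" and "ordered_fraction" not in gen:
            problems.append("generate.ordered_fraction required for mixtures")
    if config.get("modes") is not None and not config["modes"].get("required_pairs"):
        problems.append("modes.required_pairs must be a non-empty list")
    if problems:
        raise ValueError("invalid run config: " + "; ".join(problems))


def _config_hash(config: dict) -> str:
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: dict, base_dir: Optional[Path] = None) -> Path:
    """Execute the configured stages; returns the run directory."""
    validate_config(config)
    level = getattr(logging, str(config.get("log_level", "INFO")).upper(), logging.INFO)
    logging.getLogger("oligorder").setLevel(level)

    out = Path(config["output_dir"])
    if base_dir is not None:
        out = Path(base_dir) / out
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    rows: dict[str, int] = {}

    # ---- generate ---------------------------------------------------
    gen = config["generate"]
    labels = None
    if gen["kind"] == "mixture":
        sheet = SheetSpec(positional_noise_sigma=float(gen.get("noise_sigma", 0.3)),
                          seed=derive_seed(seed, "sheet"))
        spec = MixtureSpec(n_frames=int(gen["n_frames"]),
                           ordered_fraction=float(gen["ordered_fraction"]),
                           sheet=sheet, disordered_seed=derive_seed(seed, "coil"),
                           box_side=float(gen.get("box_side", 98.0)))
        traj, labels = build_mixture_trajectory(spec)
    else:
        template = attach_ligand(build_sheet_trimer(SheetSpec(seed=derive_seed(seed, "sheet"))))
        poses = []
        for p in gen.get("poses", [{"translation": [0, 0, 0], "weight": 1.0}]):
            rot = np.array(p.get("rotation", np.eye(3)), dtype=float)
            poses.append((rot, np.array(p["translation"], dtype=float), float(p["weight"])))
        traj, labels = build_ligand_pose_trajectory(
            template, poses, int(gen["n_frames"]),
            float(gen.get("jitter_sigma", 0.2)), derive_seed(seed, "poses"))
    write_ensemble(traj, out / "trajectory.pdb")
    if labels is not None:
        pd.DataFrame({"frame": range(len(labels)), "ground_truth": labels}).to_csv(
            out / "ground_truth.csv", index=False)
    rows["frames"] = traj.n_frames

    # ---- order ------------------------------------------------------
    ocfg = config.get("order", {}) or {}
    prof = order_profile(traj, p2_star=float(ocfg.get("p2_star", 0.665)))
    pd.DataFrame({
        "frame": range(prof.n_frames), "p2": prof.p2,
        "director_x": prof.directors[:, 0], "director_y": prof.directors[:, 1],
        "director_z": prof.directors[:, 2],
        "label": np.where(prof.labels, "ordered", "disordered"),
    }).to_csv(out / "order.csv", index=False)
    ratio = order_disorder_ratio(prof)
    edges, freqs = p2_histogram(prof, bin_width=float(ocfg.get("bin_width", 0.05)))
    with open(out / "order_summary.json", "w") as fh:
        json.dump({
            "n_ordered": ratio.n_ordered, "n_disordered": ratio.n_disordered,
            "r_order_disorder": None if ratio.is_infinite else ratio.r,
            "r_infinite": ratio.is_infinite,
            "p2_star": prof.p2_star,
            "histogram": {"edges": edges.tolist(), "frequencies": freqs.tolist()},
        }, fh, indent=1)
    rows["order"] = prof.n_frames

    # ---- energy -----------------------------------------------------
    ecfg = config.get("energy", {}) or {}
    apply_toy_params(traj.topology.atoms)
    params = NonbondParams(cutoff=float(ecfg.get("cutoff", 7.5)),
                           truncation=str(ecfg.get("truncation", "hard")))
    eprof = inter_peptide_energies(traj, params)
    recs = []
    for t in range(traj.n_frames):
        for p, cid in enumerate(eprof.chain_ids):
            recs.append({"frame": t, "peptide": cid, "energy_kcal_mol": eprof.per_peptide[t, p]})
    pd.DataFrame(recs).to_csv(out / "energy.csv", index=False)
    eedges, efreqs = energy_histogram(eprof, bin_width=float(ecfg.get("bin_width", 5.0)))
    with open(out / "energy_hist.json", "w") as fh:
        json.dump({"edges": eedges.tolist(), "frequencies": efreqs.tolist()}, fh, indent=1)
    rows["energy"] = len(recs)

    # ---- hbonds -----------------------------------------------------
    hcfg = config.get("hbonds", {}) or {}
    criteria = HBondCriteria(
        max_h_acceptor_distance=float(hcfg.get("max_h_acceptor_distance", 2.5)),
        min_donor_h_acceptor_angle=float(hcfg.get("min_angle", 130.0)))
    groups = default_ligand_polar_groups() if traj.topology.ligand_chain_id else None
    occ = occupancy_matrix(traj, criteria, groups, resolution=str(hcfg.get("resolution", "group")))
    pd.DataFrame(occ.matrix, index=occ.pair_labels,
                 columns=[f"frame_{t}" for t in range(occ.T)]).to_csv(out / "hbond_occupancy.csv")
    pd.DataFrame({"frame": range(occ.T), "intra_backbone": occ.intra_counts,
                  "inter_backbone": occ.inter_counts}).to_csv(out / "hbond_counts.csv", index=False)
    if occ.pair_labels:
        c, phi = correlation_matrices(occ)
        pd.DataFrame(c, index=occ.pair_labels, columns=occ.pair_labels).to_csv(
            out / "hbond_correlation.csv")
        pd.DataFrame(phi, index=occ.pair_labels, columns=occ.pair_labels).to_csv(
            out / "hbond_phi.csv")
    rows["hbonds"] = occ.T

    # ---- modes ------------------------------------------------------
    mcfg = config.get("modes")
    if mcfg is not None:
        spec = ModeSelectionSpec(required_pairs=list(mcfg["required_pairs"]),
                                 atom_selection_radius=float(mcfg.get("atom_selection_radius", 4.5)),
                                 rmsd_cutoff=float(mcfg.get("rmsd_cutoff", 1.5)))
        frames = select_mode_frames(occ, spec)
        if frames.size:
            clusters = cluster_modes(traj, frames, spec)
            pd.DataFrame([{
                "cluster": k, "size": c.size, "frequency": c.frequency,
                "representative_frame": c.representative_frame,
                "mean_internal_rmsd": c.mean_internal_rmsd,
            } for k, c in enumerate(clusters)]).to_csv(out / "modes.csv", index=False)
            rows["modes"] = len(clusters)
        else:
            rows["modes"] = 0

    manifest = {
        "config_hash": _config_hash(config),
        "version": __version__,
        "seed": seed,
        "rows": rows,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    log.info("run complete: %s (%s)", out, rows)
    return out
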