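"""Shared fixtures: small synthetic systems built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from oligorder.model import AtomRecord, EnsembleTrajectory, OligomerSnapshot
from oligorder.synthetic import (SheetSpec, attach_ligand, build_sheet_trimer,
                                 default_ligand_polar_groups)


@pytest.fixture(scope="session")
def ideal_sheet():
    """Noise-free parallel in-register heptapeptide trimer."""
    return build_sheet_trimer(SheetSpec())


@pytest.fixture(scope="session")
def noisy_sheet():
    return build_sheet_trimer(SheetSpec(positional_noise_sigma=0.3, seed=17))


@pytest.fixture(scope="session")
def liganded_sheet(ideal_sheet):
    """Ideal sheet with the template ligand parked 8 A off the oligomer."""
    return attach_ligand(ideal_sheet)


@pytest.fixture(scope="session")
def polar_groups():
    return default_ligand_polar_groups()


@pytest.fixture()
def single_frame_traj(ideal_sheet):
    return EnsembleTrajectory(ideal_sheet, ideal_sheet.coordinates()[None])


def make_bead(name, chain, resi, xyz, q=0.0, eps=0.0, rmh=0.0, element="C", resname="ALA"):
    """A bare interaction-site atom for hand-built energy/H-bond cases."""
    return AtomRecord(atom_name=name, element=element, chain_id=chain, residue_name=resname,
                      residue_index=resi, coordinates=np.asarray(xyz, float),
                      partial_charge=q, lj_epsilon=eps, lj_rmin_half=rmh)
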