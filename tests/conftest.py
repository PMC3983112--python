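"""Shared fixtures: micro-systems with hand-set charges and the reference
synthetic binding scenario (session-scoped; it backs several test modules)."""

from __future__ import annotations

import numpy as np
import pytest

from peptscan.model import AtomRecord, MolecularSystem, Trajectory
from peptscan.synth import standard_scenario

_ELEMENT_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2}


def build_system(entries, roles=None, lj_epsilon=0.0, lj_rmin_half=1.0):
    """MolecularSystem from (chain, resseq, resname, atomname, element, xyz,
    charge) tuples.  LJ epsilon defaults to 0 so energies are purely
    Coulombic and hand-computable."""
    atoms = [
        AtomRecord(
            serial=i + 1, name=name, element=elem, chain_id=chain,
            residue_seq=seq, residue_name=resname, coords=tuple(map(float, xyz)),
            vdw_radius=_ELEMENT_RADII[elem], partial_charge=float(charge),
            lj_epsilon=lj_epsilon, lj_rmin_half=lj_rmin_half,
        )
        for i, (chain, seq, resname, name, elem, xyz, charge) in enumerate(entries)
    ]
    system = MolecularSystem(atoms)
    if roles:
        for label, idx in roles.items():
            system.set_role(label, idx)
    return system


def single_frame(system):
    """One-frame trajectory over the system's own coordinates."""
    return Trajectory(system, system.coords[None, :, :], np.array([0.0]))


@pytest.fixture(scope="session")
def scenario():
    """Reference three-event synthetic scenario (seed 1)."""
    traj, truth, patches = standard_scenario(seed=1)
    return traj, truth, patches


@pytest.fixture(scope="session")
def scenario_noise_free():
    """Single-event, noise-free scenario for exact ground-truth closure."""
    from peptscan.synth import (
        BindingEvent, EventSchedule, FragmentSpec, PatchSpec,
        make_binding_trajectory, make_toy_receptor,
    )

    patches = [PatchSpec(10, 4, "acidic")]
    receptor = make_toy_receptor(40, patches, seed=0)
    fragments = [FragmentSpec(30, 13, 4, "basic")]
    schedule = EventSchedule([BindingEvent(1, 0, 4, 10, 20, 26)], noise_sigma=0.0)
    traj, truth = make_binding_trajectory(
        receptor, fragments, schedule, 30, seed=0, patches=patches
    )
    return traj, truth, patches
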