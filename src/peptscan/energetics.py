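"""Pairwise nonbonded interaction energies and salt-bridge detection.

Energies follow the standard MD analysis convention: Coulomb electrostatics
``k q_i q_j / r`` with k = 332.0636 kcal·Å/(mol·e²) and a relative
dielectric of 1, plus a 12-6 Lennard-Jones term with Lorentz-Berthelot
combination (``ε_ij = sqrt(ε_i ε_j)``, ``rmin_ij = rmin_half_i +
rmin_half_j``).  Both terms are damped by the cubic-in-r² switching
function used by common MD engines: S = 1 below the switch-on distance
(default 10 Å), 0 beyond the cutoff (default 12 Å) and C¹-continuous in
between, so the energy has no jump discontinuities.

Salt bridges are close contacts (≤ 3.2 Å by default) between side-chain
carboxylate oxygens (Asp OD1/OD2, Glu OE1/OE2) and side-chain
amine/guanidinium nitrogens (Lys NZ, Arg NH1/NH2/NE; His ND1/NE2
optionally).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .model import MolecularSystem, ResidueKey, Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "switching_function",
    "pair_energy",
    "EnergySeries",
    "energy_series",
    "SaltBridgeEvent",
    "detect_salt_bridges",
    "ACIDIC_ATOMS",
    "BASIC_ATOMS",
]

#: Coulomb constant in kcal·Å/(mol·e²).
COULOMB_CONSTANT = 332.0636

ACIDIC_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
BASIC_ATOMS = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE")}
HIS_BASIC_ATOMS = {("HIS", "ND1"), ("HIS", "NE2")}


def switching_function(r: np.ndarray, switch_on: float, cutoff: float) -> np.ndarray:
    """Cubic switching factor S(r): 1 for r<=switch_on, 0 for r>=cutoff.

    Between the two distances S follows the standard form
    ``(c² − r²)² (c² + 2r² − 3s²) / (c² − s²)³`` which is C¹-continuous at
    both boundaries.
    """
    r = np.asarray(r, dtype=float)
    r2 = r * r
    c2 = cutoff * cutoff
    s2 = switch_on * switch_on
    with np.errstate(invalid="ignore"):
        mid = (c2 - r2) ** 2 * (c2 + 2.0 * r2 - 3.0 * s2) / (c2 - s2) ** 3
    return np.where(r <= switch_on, 1.0, np.where(r >= cutoff, 0.0, mid))


def pair_energy(
    coords: np.ndarray,
    system: MolecularSystem,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff: float = 12.0,
    switch_on: float = 10.0,
    dielectric: float = 1.0,
) -> tuple[float, float]:
    """(electrostatic, vdW) interaction energy between two atom groups.

    Groups must be disjoint and parameterized.  Pairs beyond *cutoff*
    contribute nothing; coincident atom pairs raise, naming the atoms.
    Returns energies in kcal/mol.
    """
    group_a = np.asarray(group_a, dtype=np.intp)
    group_b = np.asarray(group_b, dtype=np.intp)
    if np.intersect1d(group_a, group_b).size:
        shared = np.intersect1d(group_a, group_b)
        raise ValueError(f"groups overlap on atom indices {shared.tolist()}")
    for grp in (group_a, group_b):
        missing = np.intersect1d(grp, system.parameters_missing())
        if missing.size:
            raise ValueError(
                f"unparameterized atoms in energy group: indices {missing.tolist()}"
            )
    if group_a.size == 0 or group_b.size == 0:
        return 0.0, 0.0

    r = cdist(coords[group_a], coords[group_b])
    if np.any(r < 1e-9):
        ia, ib = np.argwhere(r < 1e-9)[0]
        a, b = system.atom(int(group_a[ia])), system.atom(int(group_b[ib]))
        raise ValueError(
            f"zero interatomic distance between {a.residue_name}{a.residue_seq}:"
            f"{a.name} and {b.residue_name}{b.residue_seq}:{b.name}"
        )
    within = r < cutoff
    if not np.any(within):
        return 0.0, 0.0
    ia, ib = np.nonzero(within)
    rij = r[ia, ib]
    s = switching_function(rij, switch_on, cutoff)

    qa = system.partial_charge[group_a][ia]
    qb = system.partial_charge[group_b][ib]
    elec = float(np.sum(COULOMB_CONSTANT * qa * qb / (dielectric * rij) * s))

    eps = np.sqrt(system.lj_epsilon[group_a][ia] * system.lj_epsilon[group_b][ib])
    rmin = system.lj_rmin_half[group_a][ia] + system.lj_rmin_half[group_b][ib]
    ratio6 = (rmin / rij) ** 6
    vdw = float(np.sum(eps * (ratio6 * ratio6 - 2.0 * ratio6) * s))
    return elec, vdw


@dataclass
class EnergySeries:
    """Per-frame nonbonded energies between a site and a fragment."""

    site_id: int
    fragment_id: int
    times: np.ndarray
    electrostatic: np.ndarray
    vdw: np.ndarray
    cutoff: float
    switch_on: float

    @property
    def total(self) -> np.ndarray:
        return self.electrostatic + self.vdw

    @property
    def mean(self) -> float:
        return float(np.mean(self.total))

    @property
    def sd(self) -> float:
        return float(np.std(self.total, ddof=1)) if len(self.times) > 1 else 0.0

    def to_rows(self) -> list[dict]:
        tot = self.total
        return [
            {
                "frame": k,
                "time_ns": float(self.times[k]),
                "elec": float(self.electrostatic[k]),
                "vdw": float(self.vdw[k]),
                "total": float(tot[k]),
            }
            for k in range(len(self.times))
        ]


def _resolve_residues(
    system: MolecularSystem, residues: Iterable[ResidueKey]
) -> np.ndarray:
    residues = list(residues)
    if not residues:
        raise ValueError("empty residue set")
    idx = [system.residue_atoms(chain, seq) for chain, seq in residues]
    return np.unique(np.concatenate(idx))


def energy_series(
    traj: Trajectory,
    site_residues: Iterable[ResidueKey],
    fragment_residues: Iterable[ResidueKey],
    cutoff: float = 12.0,
    switch_on: float = 10.0,
    site_id: int = 0,
    fragment_id: int = 0,
) -> EnergySeries:
    """Per-frame interaction energy between two residue sets.

    Residues are (chain_id, author residue number) pairs; all their atoms
    enter the pairwise sums.
    """
    system = traj.system
    group_a = _resolve_residues(system, site_residues)
    group_b = _resolve_residues(system, fragment_residues)
    n = traj.n_frames
    elec = np.empty(n)
    vdw = np.empty(n)
    for k in range(n):
        elec[k], vdw[k] = pair_energy(
            traj.frames[k], system, group_a, group_b, cutoff, switch_on
        )
    return EnergySeries(
        site_id=site_id,
        fragment_id=fragment_id,
        times=traj.times.copy(),
        electrostatic=elec,
        vdw=vdw,
        cutoff=cutoff,
        switch_on=switch_on,
    )


@dataclass
class SaltBridgeEvent:
    """A salt bridge between an acidic oxygen and a basic nitrogen."""

    acidic: tuple[str, int, str]  # (chain, residue_seq, atom name)
    basic: tuple[str, int, str]
    formed: np.ndarray  # per-frame bool

    @property
    def occupancy(self) -> float:
        return float(np.mean(self.formed))


def _charged_group_atoms(
    system: MolecularSystem, include_his: bool
) -> tuple[np.ndarray, np.ndarray]:
    acid_keys = ACIDIC_ATOMS
    base_keys = BASIC_ATOMS | (HIS_BASIC_ATOMS if include_his else set())
    res_atom = list(zip(system.residue_names.astype(str), system.names.astype(str)))
    acidic = np.array([i for i, ra in enumerate(res_atom) if ra in acid_keys], dtype=np.intp)
    basic = np.array([i for i, ra in enumerate(res_atom) if ra in base_keys], dtype=np.intp)
    return acidic, basic


def detect_salt_bridges(
    traj: Trajectory,
    cutoff: float = 3.2,
    min_occupancy: float = 0.0,
    include_his: bool = False,
    roles: tuple[str, str] | None = None,
) -> list[SaltBridgeEvent]:
    """Salt-bridge events over a trajectory.

    An event is recorded for every (acidic atom, basic atom) pair whose
    distance is ≤ *cutoff* (strictly: distances above the cutoff never
    count) in at least one frame; its per-frame formed flags give the
    occupancy.  *roles* optionally restricts pairs to span two role labels
    (in either orientation), e.g. ``("receptor", "ligand")``.
    """
    system = traj.system
    acidic, basic = _charged_group_atoms(system, include_his)
    if acidic.size == 0 or basic.size == 0:
        return []
    if roles is not None:
        ra = system.role_indices(roles[0])
        rb = system.role_indices(roles[1])
        pool = np.union1d(ra, rb)
        acidic = acidic[np.isin(acidic, pool)]
        basic = basic[np.isin(basic, pool)]
    if acidic.size == 0 or basic.size == 0:
        return []

    n = traj.n_frames
    formed = np.zeros((n, acidic.size, basic.size), dtype=bool)
    for k in range(n):
        d = cdist(traj.frames[k][acidic], traj.frames[k][basic])
        formed[k] = d <= cutoff
    events: list[SaltBridgeEvent] = []
    ever = formed.any(axis=0)
    if roles is not None:
        ra_set = set(system.role_indices(roles[0]).tolist())
        rb_set = set(system.role_indices(roles[1]).tolist())
    for ai, bi in np.argwhere(ever):
        i, j = int(acidic[ai]), int(basic[bi])
        if roles is not None:
            if not (
                (i in ra_set and j in rb_set) or (i in rb_set and j in ra_set)
            ):
                continue
        ev = SaltBridgeEvent(
            acidic=(str(system.chain_ids[i]), int(system.residue_seqs[i]), str(system.names[i])),
            basic=(str(system.chain_ids[j]), int(system.residue_seqs[j]), str(system.names[j])),
            formed=formed[:, ai, bi].copy(),
        )
        if ev.occupancy >= min_occupancy:
            events.append(ev)
    events.sort(key=lambda e: (e.acidic, e.basic))
    return events
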