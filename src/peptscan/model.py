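"""Shared data model: atoms, molecular systems, trajectories, site definitions.

A :class:`MolecularSystem` stores atoms column-wise in numpy arrays (fast
distance/energy math) while exposing row-wise :class:`AtomRecord` views for
inspection.  Residue numbering follows the *author* numbering of the source
file throughout: reports and site definitions always speak in author numbers
(e.g. K112, E1047); 0-based array indices never surface in output.

Nonbonded parameters (vdW radius, partial charge, Lennard-Jones well depth
and minimum-distance half) start out *missing* (NaN) and become defined only
through explicit assignment — never silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "MolecularSystem",
    "Trajectory",
    "SiteDefinition",
    "SiteResidue",
    "ResidueKey",
    "WATER_RESNAMES",
    "ION_RESNAMES",
    "BACKBONE_NAMES",
]

#: Residue names treated as water (never occluders, dropped by default on read).
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "TIP", "SOL", "H2O", "SPC"})

#: Common monatomic ion residue names (dropped with waters by default).
ION_RESNAMES = frozenset({"NA", "CL", "K", "MG", "CA2", "ZN", "SOD", "CLA", "POT"})

#: Backbone atom names excluded in side-chain-only SASA selections.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

ResidueKey = tuple[str, int]  # (chain_id, author residue_seq)


@dataclass(frozen=True)
class AtomRecord:
    """One atom with coordinates and (possibly missing) nonbonded parameters."""

    serial: int
    name: str
    element: str
    chain_id: str
    residue_seq: int
    residue_name: str
    coords: tuple[float, float, float]
    vdw_radius: float = float("nan")
    partial_charge: float = float("nan")
    lj_epsilon: float = float("nan")
    lj_rmin_half: float = float("nan")

    @property
    def has_parameters(self) -> bool:
        return not (
            np.isnan(self.vdw_radius)
            or np.isnan(self.partial_charge)
            or np.isnan(self.lj_epsilon)
            or np.isnan(self.lj_rmin_half)
        )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.name)


class MolecularSystem:
    """Ordered atom collection with role labels and a residue index.

    Parameters
    ----------
    atoms:
        Atom records in file order.  (chain_id, residue_seq, name) must be
        unique across the system.
    roles:
        Optional map role-label -> iterable of atom indices.  Role sets must
        be disjoint.  Conventional labels: ``receptor``, ``ligand``,
        ``cofactor``.
    """

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        roles: Mapping[str, Iterable[int]] | None = None,
    ):
        n = len(atoms)
        self.serials = np.array([a.serial for a in atoms], dtype=np.int64)
        self.names = np.array([a.name for a in atoms], dtype=object)
        self.elements = np.array([a.element for a in atoms], dtype=object)
        self.chain_ids = np.array([a.chain_id for a in atoms], dtype=object)
        self.residue_seqs = np.array([a.residue_seq for a in atoms], dtype=np.int64)
        self.residue_names = np.array([a.residue_name for a in atoms], dtype=object)
        self.coords = np.array([a.coords for a in atoms], dtype=float).reshape(n, 3)
        self.vdw_radius = np.array([a.vdw_radius for a in atoms], dtype=float)
        self.partial_charge = np.array([a.partial_charge for a in atoms], dtype=float)
        self.lj_epsilon = np.array([a.lj_epsilon for a in atoms], dtype=float)
        self.lj_rmin_half = np.array([a.lj_rmin_half for a in atoms], dtype=float)

        seen: dict[tuple[str, int, str], int] = {}
        for i, a in enumerate(atoms):
            k = a.key
            if k in seen:
                raise ValueError(
                    f"duplicate atom (chain {k[0]!r}, residue {k[1]}, name {k[2]!r}) "
                    f"at positions {seen[k]} and {i}"
                )
            seen[k] = i

        self._residue_index: dict[ResidueKey, np.ndarray] = {}
        order: dict[ResidueKey, list[int]] = {}
        for i in range(n):
            order.setdefault((str(self.chain_ids[i]), int(self.residue_seqs[i])), []).append(i)
        for k, idx in order.items():
            self._residue_index[k] = np.asarray(idx, dtype=np.intp)

        self.roles: dict[str, np.ndarray] = {}
        if roles:
            for label, idx in roles.items():
                self.set_role(label, idx)

    # ------------------------------------------------------------------ #
    @property
    def n_atoms(self) -> int:
        return len(self.serials)

    def __len__(self) -> int:
        return self.n_atoms

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serials[i]),
            name=str(self.names[i]),
            element=str(self.elements[i]),
            chain_id=str(self.chain_ids[i]),
            residue_seq=int(self.residue_seqs[i]),
            residue_name=str(self.residue_names[i]),
            coords=tuple(float(x) for x in self.coords[i]),
            vdw_radius=float(self.vdw_radius[i]),
            partial_charge=float(self.partial_charge[i]),
            lj_epsilon=float(self.lj_epsilon[i]),
            lj_rmin_half=float(self.lj_rmin_half[i]),
        )

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield self.atom(i)

    @property
    def residue_index(self) -> dict[ResidueKey, np.ndarray]:
        return self._residue_index

    def residue_atoms(self, chain_id: str, residue_seq: int) -> np.ndarray:
        key = (chain_id, int(residue_seq))
        if key not in self._residue_index:
            raise KeyError(f"no residue {residue_seq} in chain {chain_id!r}")
        return self._residue_index[key]

    def residue_keys(self) -> list[ResidueKey]:
        return list(self._residue_index)

    # ------------------------------------------------------------------ #
    def set_role(self, label: str, indices: Iterable[int]) -> None:
        """Assign atoms to a role; roles must stay pairwise disjoint."""
        idx = np.unique(np.asarray(list(indices), dtype=np.intp))
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_atoms):
            raise IndexError(f"role {label!r} has out-of-range atom indices")
        for other, oidx in self.roles.items():
            if other != label and np.intersect1d(idx, oidx).size:
                raise ValueError(f"roles {label!r} and {other!r} overlap")
        self.roles[label] = idx

    def role_indices(self, label: str) -> np.ndarray:
        return self.roles.get(label, np.empty(0, dtype=np.intp))

    def non_water_indices(self) -> np.ndarray:
        mask = ~np.isin(self.residue_names.astype(str), list(WATER_RESNAMES | ION_RESNAMES))
        return np.nonzero(mask)[0]

    def sidechain_mask(self) -> np.ndarray:
        """Boolean mask of side-chain atoms.

        Backbone atoms (N, CA, C, O, OXT) and hydrogens are excluded, except
        that glycine keeps CA as a pseudo-side-chain so a glycine-containing
        site always has a defined side-chain surface.
        """
        names = self.names.astype(str)
        is_h = np.array([n.startswith("H") or n[:1].isdigit() and "H" in n for n in names])
        is_h |= self.elements.astype(str) == "H"
        backbone = np.isin(names, list(BACKBONE_NAMES))
        mask = ~(backbone | is_h)
        gly_ca = (self.residue_names.astype(str) == "GLY") & (names == "CA")
        return mask | gly_ca

    def parameters_missing(self) -> np.ndarray:
        """Indices of atoms with any missing nonbonded parameter."""
        bad = (
            np.isnan(self.vdw_radius)
            | np.isnan(self.partial_charge)
            | np.isnan(self.lj_epsilon)
            | np.isnan(self.lj_rmin_half)
        )
        return np.nonzero(bad)[0]

    def copy(self) -> "MolecularSystem":
        new = MolecularSystem.__new__(MolecularSystem)
        for attr in (
            "serials", "names", "elements", "chain_ids", "residue_seqs",
            "residue_names", "coords", "vdw_radius", "partial_charge",
            "lj_epsilon", "lj_rmin_half",
        ):
            setattr(new, attr, getattr(self, attr).copy())
        new._residue_index = {k: v.copy() for k, v in self._residue_index.items()}
        new.roles = {k: v.copy() for k, v in self.roles.items()}
        return new


@dataclass
class Trajectory:
    """Fixed-topology sequence of coordinate frames.

    frames: (n_frames, n_atoms, 3) array in Å; times: ns, strictly increasing.
    """

    system: MolecularSystem
    frames: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.system.n_atoms:
            raise ValueError(
                f"frames carry {self.frames.shape[1]} atoms but system has "
                f"{self.system.n_atoms}"
            )
        if len(self.times) != len(self.frames):
            raise ValueError("one time per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def mean_structure(self) -> np.ndarray:
        """Trajectory-average coordinates, (n_atoms, 3)."""
        return self.frames.mean(axis=0)


@dataclass(frozen=True)
class SiteResidue:
    """One residue of a binding-site definition with its annotation flags."""

    residue_seq: int
    residue_name: str
    predicted_interfacial: bool = False
    salt_bridge: bool = False
    fully_conserved: bool = False
    snurportin: bool = False


@dataclass
class SiteDefinition:
    """A binding site: a chain, its residues, and per-residue annotations."""

    site_id: int
    chain_id: str
    residues: list[SiteResidue]
    position_note: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"site {self.site_id}: residue list must be non-empty")
        seqs = [r.residue_seq for r in self.residues]
        if len(set(seqs)) != len(seqs):
            raise ValueError(f"site {self.site_id}: duplicate residue numbers {seqs}")

    @property
    def residue_seqs(self) -> list[int]:
        return [r.residue_seq for r in self.residues]

    def atom_indices(self, system: MolecularSystem) -> np.ndarray:
        """All atom indices of this site's residues in *system*."""
        idx: list[np.ndarray] = []
        for r in self.residues:
            idx.append(system.residue_atoms(self.chain_id, r.residue_seq))
        return np.concatenate(idx) if idx else np.empty(0, dtype=np.intp)
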