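"""Synthetic receptor/fragment systems with ground-truth binding events.

The generator builds kinematic (scripted) trajectories, not physics: a
rigid coarse receptor chain with charged surface patches, and rigid peptide
fragments that approach a target patch along a straight path, dwell in
contact for a scheduled frame window, and retreat.  Because the motion is
scripted, the ground truth — which receptor residues are in contact in
which frames — is exact, which is what makes every analysis stage testable.

Geometry.  Each residue carries three backbone atoms (N, CA, C) laid out
along a gently curved chain with 4 Å CA spacing, plus side-chain atoms on
one face of the chain: neutral residues a single CB, basic residues a LYS
NZ carrying +1 e, acidic residues an ASP carboxylate pair OD1/OD2 carrying
−0.5 e each.  Charges and radii follow the package's bundled parameter
table, so a system written to PDB and re-parameterized from the table
reproduces the in-memory energetics.  All intra-molecule atom pairs keep at
least 2 Å separation.

Binding is electrostatic by construction — charged fragment blocks dock
onto oppositely charged receptor patches — mirroring the observation that
transient peptide binding sites are dominated by charged and polar
residues with negligible van der Waals contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AtomRecord, MolecularSystem, ResidueKey, Trajectory

__all__ = [
    "PatchSpec",
    "FragmentSpec",
    "BindingEvent",
    "EventSchedule",
    "make_toy_receptor",
    "make_binding_trajectory",
    "standard_scenario",
]

# coordinates of one residue's atoms relative to its CA (Å)
_BACKBONE_OFFSETS = {
    "N": np.array([-1.05, -1.80, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.05, 1.80, 0.0]),
}
_SIDE_Z = 2.1
_CA_SPACING = 4.0
_CURVE_AMPLITUDE = 1.2
_PARK_DISTANCE = 40.0

# element -> (vdw radius, LJ epsilon, LJ rmin_half); mirrors the bundled table
_ELEMENT_PARAMS = {
    "C": (1.70, 0.070, 2.00),
    "N": (1.55, 0.170, 1.85),
    "O": (1.52, 0.120, 1.70),
}


@dataclass(frozen=True)
class PatchSpec:
    """A charged surface patch: contiguous receptor residues of one kind."""

    start: int  # 0-based residue index on the chain
    length: int
    kind: str  # "acidic" (ASP, −1 e) or "basic" (LYS, +1 e)

    def __post_init__(self) -> None:
        if self.kind not in ("acidic", "basic"):
            raise ValueError(f"patch kind must be acidic or basic, got {self.kind!r}")
        if self.length < 1:
            raise ValueError("patch length must be >= 1")

    @property
    def residue_range(self) -> range:
        return range(self.start, self.start + self.length)


@dataclass(frozen=True)
class FragmentSpec:
    """A peptide fragment: length and one charged block.

    ``charged_start`` is the 0-based index of the first charged residue
    within the fragment; the block carries *kind* residues (complementary
    to the target patch).
    """

    n_residues: int
    charged_start: int
    charged_length: int
    kind: str  # "acidic" or "basic"

    def __post_init__(self) -> None:
        if not 30 <= self.n_residues <= 44:
            # the scan convention: fragments of 30-44 residues
            raise ValueError("fragment length must be within 30..44 residues")
        if self.charged_start < 0 or (
            self.charged_start + self.charged_length > self.n_residues
        ):
            raise ValueError("charged block outside fragment")
        if self.kind not in ("acidic", "basic"):
            raise ValueError(f"fragment kind must be acidic or basic, got {self.kind!r}")


@dataclass(frozen=True)
class BindingEvent:
    """One scripted approach / dwell / retreat of a fragment onto a patch."""

    fragment_id: int  # 1-based
    patch_index: int  # index into the receptor's patch list
    approach_frame: int
    dwell_start: int
    dwell_end: int  # inclusive
    retreat_frame: int
    dwell_gap: float = -0.1  # vdW surface-to-surface gap at dock (Å)

    def __post_init__(self) -> None:
        if not (
            self.approach_frame < self.dwell_start
            <= self.dwell_end < self.retreat_frame
        ):
            raise ValueError(
                "event frames must satisfy approach < dwell_start <= dwell_end < retreat"
            )


@dataclass
class EventSchedule:
    """All scripted events plus the noise model."""

    events: list[BindingEvent]
    noise_sigma: float = 0.2  # Å, isotropic Gaussian per fragment atom

    def __post_init__(self) -> None:
        by_frag: dict[int, list[BindingEvent]] = {}
        for ev in self.events:
            by_frag.setdefault(ev.fragment_id, []).append(ev)
        for frag_id, evs in by_frag.items():
            evs = sorted(evs, key=lambda e: e.approach_frame)
            for a, b in zip(evs, evs[1:]):
                if b.approach_frame < a.retreat_frame:
                    raise ValueError(
                        f"fragment {frag_id}: events overlap in time "
                        f"({a.retreat_frame} > {b.approach_frame})"
                    )


def _residue_atoms(
    kind: str, chain: str, resseq: int, ca: np.ndarray, side_sign: float, serial0: int
) -> list[AtomRecord]:
    """Atoms of one coarse residue; side chain on the ``side_sign`` z face."""
    if kind == "acidic":
        resname = "ASP"
        side = [("OD1", "O", np.array([0.0, -1.1, side_sign * _SIDE_Z]), -0.5),
                ("OD2", "O", np.array([0.0, 1.1, side_sign * _SIDE_Z]), -0.5)]
    elif kind == "basic":
        resname = "LYS"
        side = [("NZ", "N", np.array([0.0, 0.0, side_sign * _SIDE_Z]), 1.0)]
    else:
        resname = "ALA"
        side = [("CB", "C", np.array([0.0, 0.0, side_sign * _SIDE_Z]), 0.0)]
    atoms: list[AtomRecord] = []
    serial = serial0
    for name, elem in (("N", "N"), ("CA", "C"), ("C", "C")):
        radius, eps, rmin = _ELEMENT_PARAMS[elem]
        atoms.append(
            AtomRecord(
                serial=serial, name=name, element=elem, chain_id=chain,
                residue_seq=resseq, residue_name=resname,
                coords=tuple(ca + _BACKBONE_OFFSETS[name]),
                vdw_radius=radius, partial_charge=0.0,
                lj_epsilon=eps, lj_rmin_half=rmin,
            )
        )
        serial += 1
    for name, elem, off, charge in side:
        radius, eps, rmin = _ELEMENT_PARAMS[elem]
        atoms.append(
            AtomRecord(
                serial=serial, name=name, element=elem, chain_id=chain,
                residue_seq=resseq, residue_name=resname,
                coords=tuple(ca + off),
                vdw_radius=radius, partial_charge=charge,
                lj_epsilon=eps, lj_rmin_half=rmin,
            )
        )
        serial += 1
    return atoms


def _chain_atoms(
    n_residues: int,
    kinds: list[str],
    chain: str,
    side_sign: float,
    serial0: int,
    curve_amplitude: float,
    jitter: np.ndarray | None = None,
) -> list[AtomRecord]:
    atoms: list[AtomRecord] = []
    serial = serial0
    for i in range(n_residues):
        ca = np.array(
            [_CA_SPACING * i, curve_amplitude * np.sin(i / 8.0), 0.0]
        )
        res = _residue_atoms(kinds[i], chain, i + 1, ca, side_sign, serial)
        if jitter is not None:
            # jitter side-chain atoms only; backbone margins are tight
            res = [
                a if a.name in ("N", "CA", "C") else AtomRecord(
                    serial=a.serial, name=a.name, element=a.element,
                    chain_id=a.chain_id, residue_seq=a.residue_seq,
                    residue_name=a.residue_name,
                    coords=tuple(np.asarray(a.coords) + jitter[a.serial - serial0]),
                    vdw_radius=a.vdw_radius, partial_charge=a.partial_charge,
                    lj_epsilon=a.lj_epsilon, lj_rmin_half=a.lj_rmin_half,
                )
                for a in res
            ]
        atoms.extend(res)
        serial += len(res)
    return atoms


def make_toy_receptor(
    n_residues: int,
    charged_patch_specs: list[PatchSpec],
    seed: int = 0,
) -> MolecularSystem:
    """Build a rigid coarse receptor chain with charged surface patches.

    The chain (chain id A) runs along x on a gentle sine curve with side
    chains facing +z; patch residues become ASP (−1 e as an OD1/OD2 pair)
    or LYS (+1 e on NZ), all other residues neutral ALA.  Deterministic per
    seed (the seed drives a small side-chain jitter).  Patches must not
    overlap; all atom pairs keep ≥ 2 Å separation.
    """
    if n_residues < 10:
        raise ValueError("need at least 10 residues")
    kinds = ["neutral"] * n_residues
    claimed: set[int] = set()
    for spec in charged_patch_specs:
        for i in spec.residue_range:
            if i < 0 or i >= n_residues:
                raise ValueError(f"patch residue index {i} outside chain")
            if i in claimed:
                raise ValueError(f"overlapping patch specs at residue index {i}")
            claimed.add(i)
            kinds[i] = spec.kind
    rng = np.random.default_rng(seed)
    # one jitter row per atom; generous upper bound on atom count
    jitter = np.clip(rng.normal(0.0, 0.03, size=(6 * n_residues, 3)), -0.08, 0.08)
    atoms = _chain_atoms(
        n_residues, kinds, "A", +1.0, 1, _CURVE_AMPLITUDE, jitter
    )
    system = MolecularSystem(atoms)
    system.set_role("receptor", np.arange(system.n_atoms))
    return system


def _build_fragment(
    spec: FragmentSpec, chain: str, serial0: int
) -> list[AtomRecord]:
    kinds = ["neutral"] * spec.n_residues
    for j in range(spec.charged_start, spec.charged_start + spec.charged_length):
        kinds[j] = spec.kind
    # straight chain (no curve), side chains facing −z toward the receptor
    return _chain_atoms(spec.n_residues, kinds, chain, -1.0, serial0, 0.0)


def _min_surface_gap(
    coords_a: np.ndarray, radii_a: np.ndarray,
    coords_b: np.ndarray, radii_b: np.ndarray,
) -> float:
    from scipy.spatial.distance import cdist

    d = cdist(coords_a, coords_b)
    gaps = d - radii_a[:, None] - radii_b[None, :]
    return float(gaps.min())


def make_binding_trajectory(
    receptor: MolecularSystem,
    fragments: list[FragmentSpec],
    schedule: EventSchedule,
    n_frames: int,
    seed: int = 0,
    frame_interval_ns: float = 0.1,
    patches: list[PatchSpec] | None = None,
) -> tuple[Trajectory, list[dict]]:
    """Assemble receptor + fragments and script the scheduled events.

    Fragments are rigid; per event they interpolate linearly from a parking
    position (≥ 15 Å from the receptor) to a docked pose over the target
    patch — placed so the minimum vdW surface gap between fragment and
    receptor equals the event's ``dwell_gap`` — dwell there, and retreat.
    Gaussian positional noise (``schedule.noise_sigma``) is added to
    fragment atoms.  Returns the trajectory and a ground-truth event log:
    one entry per event with its fragment, dwell frames, and the receptor
    residues in contact.

    *patches* must be the patch list the receptor was built with (used to
    resolve each event's target residues).
    """
    if patches is None:
        raise ValueError("pass the receptor's patch list via patches=")
    for ev in schedule.events:
        if ev.fragment_id < 1 or ev.fragment_id > len(fragments):
            raise ValueError(f"event references unknown fragment {ev.fragment_id}")
        if ev.patch_index < 0 or ev.patch_index >= len(patches):
            raise ValueError(f"event references unknown patch {ev.patch_index}")
        if ev.retreat_frame >= n_frames:
            raise ValueError(
                f"event on fragment {ev.fragment_id} extends to frame "
                f"{ev.retreat_frame} but trajectory has {n_frames} frames"
            )

    rng = np.random.default_rng(seed)

    # assemble combined system: receptor chain A + fragment chains B, C, ...
    atoms = [receptor.atom(i) for i in range(receptor.n_atoms)]
    frag_slices: dict[int, slice] = {}
    chain_letters = "BCDEFGHIJKLM"
    serial = receptor.n_atoms + 1
    frag_local: dict[int, np.ndarray] = {}
    for f_idx, spec in enumerate(fragments, start=1):
        frag_atoms = _build_fragment(spec, chain_letters[f_idx - 1], serial)
        start = len(atoms)
        atoms.extend(frag_atoms)
        frag_slices[f_idx] = slice(start, len(atoms))
        frag_local[f_idx] = np.array([a.coords for a in frag_atoms])
        serial += len(frag_atoms)

    system = MolecularSystem(atoms)
    system.set_role("receptor", np.arange(receptor.n_atoms))
    lig_idx = np.arange(receptor.n_atoms, system.n_atoms)
    system.set_role("ligand", lig_idx)

    rec_coords = system.coords[: receptor.n_atoms]
    rec_radii = system.vdw_radius[: receptor.n_atoms]

    # parking and docking offsets per fragment
    park_offset: dict[int, np.ndarray] = {}
    for f_idx in frag_local:
        park_offset[f_idx] = np.array(
            [0.0, 0.0, _PARK_DISTANCE + 12.0 * (f_idx - 1)]
        )

    def docked_offset(ev: BindingEvent) -> np.ndarray:
        spec = fragments[ev.fragment_id - 1]
        patch = patches[ev.patch_index]
        local = frag_local[ev.fragment_id]
        sl = frag_slices[ev.fragment_id]
        radii_f = system.vdw_radius[sl.start:sl.stop]
        # align the charged block center over the patch center in x/y
        patch_atoms = np.concatenate(
            [receptor.residue_atoms("A", i + 1) for i in patch.residue_range]
        )
        sc_mask = receptor.sidechain_mask()
        patch_sc = patch_atoms[sc_mask[patch_atoms]]
        patch_center = rec_coords[patch_sc].mean(axis=0)
        block_res = range(
            spec.charged_start + 1, spec.charged_start + spec.charged_length + 1
        )
        block_atoms = np.concatenate(
            [
                np.nonzero(
                    (system.residue_seqs[sl] == r)
                    & (system.names[sl] != "N")
                    & (system.names[sl] != "CA")
                    & (system.names[sl] != "C")
                )[0]
                for r in block_res
            ]
        )
        block_center = local[block_atoms].mean(axis=0)
        offset_xy = patch_center - block_center
        offset_xy[2] = 0.0
        # find the z shift giving the requested minimum surface gap
        lo, hi = 0.0, 60.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            shifted = local + offset_xy + np.array([0.0, 0.0, mid])
            gap = _min_surface_gap(shifted, radii_f, rec_coords, rec_radii)
            if gap > ev.dwell_gap:
                hi = mid
            else:
                lo = mid
        return offset_xy + np.array([0.0, 0.0, 0.5 * (lo + hi)])

    dock_cache = {id(ev): docked_offset(ev) for ev in schedule.events}
    events_by_frag: dict[int, list[BindingEvent]] = {}
    for ev in schedule.events:
        events_by_frag.setdefault(ev.fragment_id, []).append(ev)
    for evs in events_by_frag.values():
        evs.sort(key=lambda e: e.approach_frame)

    frames = np.empty((n_frames, system.n_atoms, 3))
    frames[:, : receptor.n_atoms] = rec_coords
    for f_idx, local in frag_local.items():
        park = park_offset[f_idx]
        for k in range(n_frames):
            offset = park
            for ev in events_by_frag.get(f_idx, ()):
                dock = dock_cache[id(ev)]
                if ev.approach_frame <= k < ev.dwell_start:
                    t = (k - ev.approach_frame) / (ev.dwell_start - ev.approach_frame)
                    offset = park + t * (dock - park)
                elif ev.dwell_start <= k <= ev.dwell_end:
                    offset = dock
                elif ev.dwell_end < k <= ev.retreat_frame:
                    t = (k - ev.dwell_end) / (ev.retreat_frame - ev.dwell_end)
                    offset = dock + t * (park - dock)
            pos = local + offset
            if schedule.noise_sigma > 0:
                pos = pos + rng.normal(0.0, schedule.noise_sigma, size=pos.shape)
            frames[k, frag_slices[f_idx]] = pos

    traj = Trajectory(
        system=system,
        frames=frames,
        times=frame_interval_ns * np.arange(n_frames),
    )
    fragments_map = {
        f_idx: np.arange(sl.start, sl.stop) for f_idx, sl in frag_slices.items()
    }
    truth = [
        {
            "fragment_id": ev.fragment_id,
            "site_residues": [
                ("A", i + 1) for i in patches[ev.patch_index].residue_range
            ],
            "dwell_start": ev.dwell_start,
            "dwell_end": ev.dwell_end,
            "dwell_gap": ev.dwell_gap,
        }
        for ev in schedule.events
    ]
    traj.fragments = fragments_map  # type: ignore[attr-defined]
    return traj, truth


def standard_scenario(
    seed: int = 0,
    n_frames: int = 60,
    noise_sigma: float = 0.2,
) -> tuple[Trajectory, list[dict], list[PatchSpec]]:
    """The reference synthetic scenario: three well-separated binding events.

    A 100-residue receptor carries three 4-residue charged patches spaced
    ~150 Å apart — far enough that a 30-residue fragment lying over one
    patch cannot reach another — and three 30-residue fragments with
    complementary charged blocks each dock onto their patch for a ≥ 40 %
    dwell window.  Returns (trajectory, ground-truth event log, patches).
    """
    patches = [
        PatchSpec(10, 4, "acidic"),
        PatchSpec(48, 4, "basic"),
        PatchSpec(86, 4, "acidic"),
    ]
    receptor = make_toy_receptor(100, patches, seed=seed)
    fragments = [
        FragmentSpec(30, 13, 4, "basic"),
        FragmentSpec(30, 13, 4, "acidic"),
        FragmentSpec(30, 13, 4, "basic"),
    ]
    events = [
        BindingEvent(1, 0, 5, 10, 35, 40),
        BindingEvent(2, 1, 8, 14, 40, 46),
        BindingEvent(3, 2, 10, 16, 45, 50),
    ]
    schedule = EventSchedule(events, noise_sigma=noise_sigma)
    traj, truth = make_binding_trajectory(
        receptor, fragments, schedule, n_frames, seed=seed, patches=patches
    )
    return traj, truth, patches
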