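"""Multi-criterion binding-site calling from peptide-fragment trajectories.

The pipeline codifies a screening procedure for transient binding of
unstructured peptide fragments to a rigid receptor surface:

1. **Contact pairing** — a receptor residue is paired with a fragment in a
   frame when its centroid lies within a conservative distance cutoff
   (default 7 Å) of any residue centroid of that fragment.
2. **Energy screen** — a paired region survives when its mean total
   nonbonded interaction energy with the fragment drops by at least a
   per-residue threshold (default 3 kcal/mol per paired receptor residue).
3. **Fragment splitting** — one fragment touching the receptor in two
   sequence-separated stretches is split into independent interactions
   wherever a long enough run of fragment residues (default 5) stays
   unattached in most contact frames.
4. **Spatial merging** — candidate residue groups whose heavy atoms come
   within an adjacency cutoff (default 5 Å) in the trajectory-average
   structure are transitively merged into one site, possibly pooling
   several fragments.
5. **Re-scoring and pruning** — per merged site the energy is recomputed
   against the pooled fragments; residues contributing almost nothing
   (mean above −0.5 kcal/mol) or with essentially no solvent-accessible
   side-chain surface are pruned, and sites failing the energy screen
   after recomputation are dropped.  Each retained call reports mean ± sd
   energy, mean ± sd RASAS and any salt bridges.

A per-frame least-squares superposition RMSD utility is included for
assessing receptor and site stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .energetics import SaltBridgeEvent, detect_salt_bridges, pair_energy
from .model import MolecularSystem, ResidueKey, SiteDefinition, SiteResidue, Trajectory
from .sasa import rasas_series, sasa

__all__ = [
    "CallParams",
    "ContactPairing",
    "Candidate",
    "BindingSiteCall",
    "fragments_by_chain",
    "pair_contacts",
    "screen_by_energy",
    "split_fragment_interactions",
    "merge_adjacent_sites",
    "call_sites",
    "superposed_rmsd",
]


@dataclass(frozen=True)
class CallParams:
    """Thresholds of the site-calling pipeline (defaults are the standard
    analysis values: 7 Å contact, 3 kcal/mol per residue, 3.2 Å salt
    bridge, 1.4 Å probe, 12/10 Å nonbonded cutoff/switch)."""

    contact_cutoff: float = 7.0
    energy_per_residue: float = 3.0
    min_gap: int = 5
    persistence: float = 0.5
    adjacency_cutoff: float = 5.0
    prune_floor: float = 0.5
    sasa_floor: float = 5.0
    probe_radius: float = 1.4
    sidechain_only: bool = True
    n_points: int = 960
    cutoff: float = 12.0
    switch_on: float = 10.0
    salt_bridge_cutoff: float = 3.2


@dataclass
class ContactPairing:
    """Per-frame contact map of one fragment against receptor residues."""

    fragment_id: int
    fragment_residues: list[ResidueKey]  # in sequence order
    cutoff: float
    #: one dict per frame: fragment residue -> set of receptor residues
    contacts: list[dict[ResidueKey, set[ResidueKey]]]

    @property
    def receptor_residues(self) -> frozenset[ResidueKey]:
        out: set[ResidueKey] = set()
        for frame in self.contacts:
            for recs in frame.values():
                out |= recs
        return frozenset(out)

    @property
    def contact_frames(self) -> list[int]:
        return [k for k, frame in enumerate(self.contacts) if frame]


@dataclass(frozen=True)
class Candidate:
    """A candidate site: receptor residues plus contributing fragments."""

    receptor_residues: frozenset[ResidueKey]
    fragment_ids: frozenset[int]


@dataclass
class BindingSiteCall:
    """A called binding site with its summary statistics."""

    call_id: int
    receptor_residues: list[ResidueKey]  # sorted by (chain, residue number)
    fragment_ids: list[int]
    mean_energy: float
    sd_energy: float
    mean_rasas: float
    sd_rasas: float
    salt_bridges: list[SaltBridgeEvent]
    per_residue_energy: dict[ResidueKey, float]

    def to_dict(self) -> dict:
        return {
            "call_id": self.call_id,
            "residues": [
                {"chain": c, "residue_seq": s} for c, s in self.receptor_residues
            ],
            "fragments": self.fragment_ids,
            "mean_energy_kcal_mol": self.mean_energy,
            "sd_energy_kcal_mol": self.sd_energy,
            "mean_rasas": self.mean_rasas,
            "sd_rasas": self.sd_rasas,
            "salt_bridges": [
                {
                    "acidic": list(ev.acidic),
                    "basic": list(ev.basic),
                    "occupancy": ev.occupancy,
                }
                for ev in self.salt_bridges
            ],
            "per_residue_energy_kcal_mol": {
                f"{c}:{s}": e for (c, s), e in self.per_residue_energy.items()
            },
        }


# ------------------------------------------------------------------------- #
def fragments_by_chain(
    system: MolecularSystem, ligand_role: str = "ligand"
) -> dict[int, np.ndarray]:
    """Partition the ligand role into fragments, one per chain.

    Fragment ids are 1-based in order of chain appearance — the convention
    used by the synthetic generator and the CLI.
    """
    ligand = system.role_indices(ligand_role)
    order: dict[str, list[int]] = {}
    for i in ligand:
        order.setdefault(str(system.chain_ids[i]), []).append(int(i))
    return {
        f_idx: np.asarray(idx, dtype=np.intp)
        for f_idx, (_, idx) in enumerate(order.items(), start=1)
    }


def _residues_of_atoms(system: MolecularSystem, atoms: np.ndarray) -> list[ResidueKey]:
    """Residue keys touched by *atoms*, in first-appearance order."""
    seen: dict[ResidueKey, None] = {}
    for i in atoms:
        seen.setdefault((str(system.chain_ids[i]), int(system.residue_seqs[i])), None)
    return list(seen)


def _residue_centroids(
    system: MolecularSystem, frame: np.ndarray, residues: list[ResidueKey]
) -> np.ndarray:
    cents = np.empty((len(residues), 3))
    for r, (chain, seq) in enumerate(residues):
        cents[r] = frame[system.residue_atoms(chain, seq)].mean(axis=0)
    return cents


def pair_contacts(
    traj: Trajectory,
    fragments: dict[int, np.ndarray],
    cutoff: float = 7.0,
    receptor_role: str = "receptor",
) -> list[ContactPairing]:
    """Pair receptor residues with fragments by residue-centroid distance.

    A receptor residue is paired with a fragment in a frame iff its
    centroid is within *cutoff* of the centroid of ANY residue of that
    fragment.  Centroids are unweighted means of residue atom coordinates.
    """
    system = traj.system
    rec_residues = _residues_of_atoms(system, system.role_indices(receptor_role))
    pairings: list[ContactPairing] = []
    for frag_id in sorted(fragments):
        frag_res = _residues_of_atoms(system, np.asarray(fragments[frag_id]))
        contacts: list[dict[ResidueKey, set[ResidueKey]]] = []
        for k in range(traj.n_frames):
            frame = traj.frames[k]
            rc = _residue_centroids(system, frame, rec_residues)
            fc = _residue_centroids(system, frame, frag_res)
            d = cdist(fc, rc)
            frame_map: dict[ResidueKey, set[ResidueKey]] = {}
            fi, ri = np.nonzero(d <= cutoff)
            for f, r in zip(fi, ri):
                frame_map.setdefault(frag_res[f], set()).add(rec_residues[r])
            contacts.append(frame_map)
        pairings.append(
            ContactPairing(
                fragment_id=frag_id,
                fragment_residues=frag_res,
                cutoff=cutoff,
                contacts=contacts,
            )
        )
    return pairings


def _fragment_atoms(
    system: MolecularSystem, fragments: dict[int, np.ndarray], frag_ids
) -> np.ndarray:
    idx = [np.asarray(fragments[f], dtype=np.intp) for f in frag_ids]
    return np.unique(np.concatenate(idx))


def _residue_set_atoms(system: MolecularSystem, residues) -> np.ndarray:
    idx = [system.residue_atoms(c, s) for c, s in residues]
    return np.unique(np.concatenate(idx)) if idx else np.empty(0, dtype=np.intp)


def _mean_energy(
    traj: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
    params: CallParams,
) -> tuple[float, float]:
    """Mean and sd of per-frame total nonbonded energy between two groups."""
    totals = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        e, v = pair_energy(
            traj.frames[k], traj.system, group_a, group_b,
            params.cutoff, params.switch_on,
        )
        totals[k] = e + v
    sd = float(np.std(totals, ddof=1)) if traj.n_frames > 1 else 0.0
    return float(np.mean(totals)), sd


def screen_by_energy(
    pairings: list[ContactPairing],
    traj: Trajectory,
    fragments: dict[int, np.ndarray],
    threshold: float = 3.0,
    params: CallParams | None = None,
) -> list[tuple[ContactPairing, float]]:
    """Keep pairings whose mean interaction energy drops enough.

    A pairing is retained iff the mean total energy between its paired
    receptor residues and the whole fragment is ≤ −threshold × (number of
    paired receptor residues).  Returns the surviving pairings with their
    mean energies.
    """
    params = params or CallParams(energy_per_residue=threshold)
    system = traj.system
    survivors: list[tuple[ContactPairing, float]] = []
    for pairing in pairings:
        rec = sorted(pairing.receptor_residues)
        if not rec:
            continue
        group_a = _residue_set_atoms(system, rec)
        group_b = np.asarray(fragments[pairing.fragment_id], dtype=np.intp)
        mean, _ = _mean_energy(traj, group_a, group_b, params)
        if mean <= -threshold * len(rec):
            survivors.append((pairing, mean))
    return survivors


def split_fragment_interactions(
    pairing: ContactPairing,
    min_gap: int = 5,
    persistence: float = 0.5,
) -> list[ContactPairing]:
    """Split a pairing into independent interactions along the fragment.

    Fragment residues are taken in sequence order; a residue is *attached*
    when it has a paired receptor residue in at least *persistence* of the
    pairing's contact frames.  A split is placed wherever a run of at least
    *min_gap* consecutive unattached fragment residues separates two
    attached stretches.  Each sub-pairing keeps only the contacts of its
    own fragment residues (and hence its own receptor residues).
    """
    frames = pairing.contact_frames
    if not frames:
        return []
    n_contact = len(frames)
    order = pairing.fragment_residues
    counts = {res: 0 for res in order}
    for k in frames:
        for res, recs in pairing.contacts[k].items():
            if recs:
                counts[res] += 1
    attached = [j for j, res in enumerate(order) if counts[res] >= persistence * n_contact]
    if not attached:
        return []
    blocks: list[list[int]] = [[attached[0]]]
    for j in attached[1:]:
        if j - blocks[-1][-1] - 1 >= min_gap:
            blocks.append([j])
        else:
            blocks[-1].append(j)
    if len(blocks) == 1:
        return [pairing]
    subs: list[ContactPairing] = []
    for block in blocks:
        lo, hi = block[0], block[-1]
        members = set(order[lo:hi + 1])
        sub_contacts = [
            {res: set(recs) for res, recs in frame.items() if res in members}
            for frame in pairing.contacts
        ]
        subs.append(
            ContactPairing(
                fragment_id=pairing.fragment_id,
                fragment_residues=order[lo:hi + 1],
                cutoff=pairing.cutoff,
                contacts=sub_contacts,
            )
        )
    return subs


def merge_adjacent_sites(
    candidates: list[Candidate],
    system: MolecularSystem,
    avg_coords: np.ndarray,
    adjacency_cutoff: float = 5.0,
) -> list[Candidate]:
    """Transitively merge candidates whose heavy atoms sit close together.

    Two candidates merge iff any heavy-atom pair between their receptor
    residue sets is within *adjacency_cutoff* in the trajectory-average
    structure; merging proceeds over connected components (union-find), so
    chained candidates collapse into one.  Output is ordered by minimum
    receptor residue (chain, number).
    """
    n = len(candidates)
    heavy = system.elements.astype(str) != "H"
    atom_sets = []
    for cand in candidates:
        atoms = _residue_set_atoms(system, sorted(cand.receptor_residues))
        atom_sets.append(atoms[heavy[atoms]])

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            if candidates[i].receptor_residues & candidates[j].receptor_residues:
                union(i, j)
                continue
            if atom_sets[i].size and atom_sets[j].size:
                d = cdist(avg_coords[atom_sets[i]], avg_coords[atom_sets[j]])
                if d.min() <= adjacency_cutoff:
                    union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged = [
        Candidate(
            receptor_residues=frozenset().union(
                *(candidates[i].receptor_residues for i in members)
            ),
            fragment_ids=frozenset().union(
                *(candidates[i].fragment_ids for i in members)
            ),
        )
        for members in groups.values()
    ]
    merged.sort(key=lambda c: min(c.receptor_residues))
    return merged


def _per_residue_sasa_mean(
    traj: Trajectory,
    residues: list[ResidueKey],
    params: CallParams,
) -> dict[ResidueKey, float]:
    """Mean ligand-ignored side-chain SASA per residue (accessibility)."""
    system = traj.system
    ligand = system.role_indices("ligand")
    non_water = system.non_water_indices()
    context_all = np.setdiff1d(non_water, ligand)
    sc_mask = system.sidechain_mask()
    out: dict[ResidueKey, float] = {}
    for chain, seq in residues:
        atoms = system.residue_atoms(chain, seq)
        target = atoms[sc_mask[atoms]]
        if target.size == 0:
            target = atoms  # fall back to all atoms rather than undefined
        ctx = np.setdiff1d(context_all, target)
        vals = [
            sasa(
                traj.frames[k], system.vdw_radius, target, ctx,
                params.probe_radius, params.n_points,
            ).sum()
            for k in range(traj.n_frames)
        ]
        out[(chain, seq)] = float(np.mean(vals))
    return out


def call_sites(
    traj: Trajectory,
    fragments: dict[int, np.ndarray],
    params: CallParams | None = None,
) -> list[BindingSiteCall]:
    """Run the full site-calling pipeline.

    *fragments* partitions the ligand role: fragment id -> atom indices.
    Returns retained :class:`BindingSiteCall` objects ordered along the
    receptor sequence; every retained call satisfies the per-residue energy
    threshold after final re-scoring.
    """
    params = params or CallParams()
    system = traj.system

    pairings = pair_contacts(traj, fragments, params.contact_cutoff)
    survivors = screen_by_energy(
        pairings, traj, fragments, params.energy_per_residue, params
    )

    candidates: list[Candidate] = []
    for pairing, _ in survivors:
        for sub in split_fragment_interactions(pairing, params.min_gap, params.persistence):
            rec = sub.receptor_residues
            if not rec:
                continue
            group_a = _residue_set_atoms(system, sorted(rec))
            group_b = np.asarray(fragments[sub.fragment_id], dtype=np.intp)
            mean, _ = _mean_energy(traj, group_a, group_b, params)
            if mean <= -params.energy_per_residue * len(rec):
                candidates.append(
                    Candidate(
                        receptor_residues=rec,
                        fragment_ids=frozenset({sub.fragment_id}),
                    )
                )

    merged = merge_adjacent_sites(
        candidates, system, traj.mean_structure(), params.adjacency_cutoff
    )

    all_bridges = detect_salt_bridges(
        traj, params.salt_bridge_cutoff, roles=("receptor", "ligand")
    )

    calls: list[BindingSiteCall] = []
    for cand in merged:
        residues = sorted(cand.receptor_residues)
        frag_ids = sorted(cand.fragment_ids)
        frag_atoms = _fragment_atoms(system, fragments, frag_ids)

        # per-residue energy pruning
        per_res: dict[ResidueKey, float] = {}
        for key in residues:
            atoms = system.residue_atoms(*key)
            mean, _ = _mean_energy(traj, atoms, frag_atoms, params)
            per_res[key] = mean
        kept = [key for key in residues if per_res[key] <= -params.prune_floor]

        # accessibility pruning: buried side chains cannot bind
        if kept:
            sasa_means = _per_residue_sasa_mean(traj, kept, params)
            kept = [key for key in kept if sasa_means[key] >= params.sasa_floor]
        if not kept:
            continue

        group_a = _residue_set_atoms(system, kept)
        mean_e, sd_e = _mean_energy(traj, group_a, frag_atoms, params)
        if mean_e > -params.energy_per_residue * len(kept):
            continue

        site = SiteDefinition(
            site_id=len(calls) + 1,
            chain_id=kept[0][0],
            residues=[
                SiteResidue(
                    residue_seq=seq,
                    residue_name=str(
                        system.residue_names[system.residue_atoms(chain, seq)[0]]
                    ),
                )
                for chain, seq in kept
            ],
        )
        rseries = rasas_series(
            traj, site, "ligand", params.probe_radius,
            params.sidechain_only, params.n_points,
        )

        site_res_set = set(kept)
        frag_res_set = set(_residues_of_atoms(system, frag_atoms))
        bridges = [
            ev for ev in all_bridges
            if (
                ((ev.acidic[0], ev.acidic[1]) in site_res_set
                 and (ev.basic[0], ev.basic[1]) in frag_res_set)
                or ((ev.basic[0], ev.basic[1]) in site_res_set
                    and (ev.acidic[0], ev.acidic[1]) in frag_res_set)
            )
        ]

        calls.append(
            BindingSiteCall(
                call_id=len(calls) + 1,
                receptor_residues=kept,
                fragment_ids=frag_ids,
                mean_energy=mean_e,
                sd_energy=sd_e,
                mean_rasas=rseries.mean,
                sd_rasas=rseries.sd,
                salt_bridges=bridges,
                per_residue_energy={k: per_res[k] for k in kept},
            )
        )
    return calls


def superposed_rmsd(
    traj: Trajectory,
    selection: np.ndarray,
    reference: np.ndarray,
) -> np.ndarray:
    """Per-frame RMSD of *selection* after optimal rigid superposition.

    Each frame's selected coordinates are least-squares superposed
    (rotation + translation, Kabsch) onto *reference* before the RMSD is
    taken.  Requires at least 3 non-collinear atoms.
    """
    selection = np.asarray(selection, dtype=np.intp)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (selection.size, 3):
        raise ValueError(
            f"reference has shape {reference.shape}, expected ({selection.size}, 3)"
        )
    if selection.size < 3:
        raise ValueError("superposition needs at least 3 atoms")
    ref_c = reference - reference.mean(axis=0)
    out = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        mob = traj.frames[k][selection]
        mob_c = mob - mob.mean(axis=0)
        _, rssd = Rotation.align_vectors(ref_c, mob_c)
        out[k] = rssd / np.sqrt(selection.size)
    return out
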