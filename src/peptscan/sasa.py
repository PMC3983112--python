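"""Sphere-point solvent-accessible surface areas and the RASAS occupancy ratio.

SASA is computed by deterministic sphere-point sampling: each atom's solvent
sphere (radius ``r + probe``) is covered by a generalized-spiral (Fibonacci)
point set, a point is occluded when it falls inside any neighbour's solvent
sphere, and the accessible fraction times the sphere area gives the per-atom
SASA.  The point set is fixed, so results are exactly reproducible without a
random seed; the discretization error of an isolated sphere is bounded by
about ``3/sqrt(n_points)`` relative.

RASAS (ratio of available solvent-accessible surface) for a binding site is
the site's SASA with the ligand present divided by its SASA with the ligand
atoms ignored, frame by frame.  Both SASAs see the identical receptor and
cofactor context, so conformational self-occlusion cancels and the ratio
isolates occlusion by the ligand: 1 means unoccupied, lower means covered.
With a 1.4 Å probe, a ligand atom starts to depress RASAS exactly when its
van der Waals surface comes within twice the probe radius — 2.8 Å — of a
site atom's surface.

Surface coverage is ``1 − RASAS`` of the whole receptor surface, by
convention at a 2.5 Å probe (≈ 5 Å proximity).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from .model import MolecularSystem, SiteDefinition, Trajectory

__all__ = [
    "fibonacci_sphere",
    "sasa",
    "RASASSeries",
    "CoverageSeries",
    "rasas_series",
    "surface_coverage",
]

DEFAULT_N_POINTS = 960
MIN_N_POINTS = 100


@lru_cache(maxsize=8)
def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic generalized-spiral unit vectors, shape (n_points, 3)."""
    k = np.arange(n_points, dtype=float)
    # golden-angle longitude, uniform-area latitude
    phi = k * (np.pi * (3.0 - np.sqrt(5.0)))
    z = 1.0 - (2.0 * k + 1.0) / n_points
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack((rho * np.cos(phi), rho * np.sin(phi), z))
    pts.setflags(write=False)
    return pts


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    target: np.ndarray,
    context: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible areas of *target* atoms, in Ų.

    Parameters
    ----------
    coords, radii:
        Full coordinate array (n, 3) and vdW radii (n,) in Å.
    target, context:
        Atom index arrays.  Occluders of a target atom are all other atoms
        of ``target ∪ context``.
    probe_radius:
        Solvent probe radius in Å (1.4 for water).
    n_points:
        Sphere points per atom; at least 100 (accuracy floor).

    Notes
    -----
    A point on atom *i*'s solvent sphere is occluded by atom *j* when its
    distance to *j*'s center is below ``r_j + probe``.  Exactly coincident
    atoms are resolved deterministically: the larger-radius atom occludes
    the smaller; at equal radius the lower-index atom wins, so a duplicated
    atom contributes zero area rather than raising.
    """
    if n_points < MIN_N_POINTS:
        raise ValueError(f"n_points must be >= {MIN_N_POINTS}, got {n_points}")
    target = np.asarray(target, dtype=np.intp)
    context = np.asarray(context, dtype=np.intp)
    occluders = np.union1d(target, context)
    if np.any(~np.isfinite(radii[occluders])) or np.any(radii[occluders] <= 0):
        bad = occluders[~np.isfinite(radii[occluders]) | (radii[occluders] <= 0)]
        raise ValueError(f"unparameterized vdW radius for atom indices {bad.tolist()}")

    unit = fibonacci_sphere(n_points)
    occ_xyz = coords[occluders]
    occ_r = radii[occluders] + probe_radius
    max_occ = float(occ_r.max()) if occluders.size else 0.0
    tree = cKDTree(occ_xyz) if occluders.size else None

    areas = np.empty(target.size, dtype=float)
    for t_pos, i in enumerate(target):
        ri = radii[i] + probe_radius
        center = coords[i]
        sphere_area = 4.0 * np.pi * ri * ri
        if tree is None:
            areas[t_pos] = sphere_area
            continue
        cand = tree.query_ball_point(center, ri + max_occ)
        cand = np.asarray(cand, dtype=np.intp)
        cand = cand[occluders[cand] != i]
        if cand.size == 0:
            areas[t_pos] = sphere_area
            continue
        cxyz = occ_xyz[cand]
        cr = occ_r[cand]
        d_center = np.linalg.norm(cxyz - center, axis=1)
        coincident = d_center < 1e-12
        if np.any(coincident):
            cj = cand[coincident]
            # larger radius swallows smaller; equal radius: lower index wins
            swallowed = (occ_r[cj] > ri + 1e-12) | (
                (np.abs(occ_r[cj] - ri) <= 1e-12) & (occluders[cj] < i)
            )
            if np.any(swallowed):
                areas[t_pos] = 0.0
                continue
            cxyz = cxyz[~coincident]
            cr = cr[~coincident]
            if cr.size == 0:
                areas[t_pos] = sphere_area
                continue
        points = center + ri * unit  # (m, 3)
        # (m, k) squared distances to candidate occluder centers
        d2 = (
            (points[:, None, :] - cxyz[None, :, :]) ** 2
        ).sum(axis=2)
        occluded = (d2 < (cr * cr)[None, :]).any(axis=1)
        areas[t_pos] = sphere_area * (1.0 - occluded.mean())
    return areas


@dataclass
class RASASSeries:
    """Per-frame RASAS of one site against one ligand role.

    ``sasa_with_ligand`` is the site SASA in the presence of the ligand
    (numerator); ``sasa_ligand_ignored`` the same SASA with ligand atoms
    removed from the context (denominator); ``ratio`` their frame-wise
    quotient.
    """

    site_id: int
    probe_radius: float
    times: np.ndarray
    sasa_with_ligand: np.ndarray
    sasa_ligand_ignored: np.ndarray
    ratio: np.ndarray
    sidechain_only: bool = True

    @property
    def mean(self) -> float:
        return float(np.mean(self.ratio))

    @property
    def sd(self) -> float:
        return float(np.std(self.ratio, ddof=1)) if len(self.ratio) > 1 else 0.0

    def to_rows(self) -> list[dict]:
        return [
            {
                "frame": k,
                "time_ns": float(self.times[k]),
                "numerator_A2": float(self.sasa_with_ligand[k]),
                "denominator_A2": float(self.sasa_ligand_ignored[k]),
                "rasas": float(self.ratio[k]),
            }
            for k in range(len(self.ratio))
        ]


@dataclass
class CoverageSeries:
    """Per-frame fraction of receptor surface occluded by the ligand role."""

    probe_radius: float
    times: np.ndarray
    coverage: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.coverage))


def _site_target_atoms(
    system: MolecularSystem, site: SiteDefinition, sidechain_only: bool
) -> np.ndarray:
    idx = site.atom_indices(system)
    if sidechain_only:
        mask = system.sidechain_mask()
        kept = idx[mask[idx]]
        if kept.size == 0:
            residues = ", ".join(
                f"{r.residue_name}{r.residue_seq}" for r in site.residues
            )
            raise ValueError(
                f"site {site.site_id}: no side-chain atoms in side-chain-only "
                f"mode (residues {residues})"
            )
        return kept
    return idx


def rasas_series(
    traj: Trajectory,
    site: SiteDefinition,
    ligand_role: str = "ligand",
    probe_radius: float = 1.4,
    sidechain_only: bool = True,
    n_points: int = DEFAULT_N_POINTS,
) -> RASASSeries:
    """RASAS of *site* over the trajectory.

    Numerator context: all non-water atoms including the ligand role.
    Denominator context: the same minus ligand atoms, so receptor/cofactor
    self-occlusion is identical in both and only ligand occlusion moves the
    ratio.  An empty ligand role yields a ratio of exactly 1 in every frame.
    """
    system = traj.system
    target = _site_target_atoms(system, site, sidechain_only)
    ligand = system.role_indices(ligand_role)
    non_water = system.non_water_indices()
    ctx_with = np.setdiff1d(non_water, target)
    ctx_without = np.setdiff1d(ctx_with, ligand)

    n = traj.n_frames
    num = np.empty(n)
    den = np.empty(n)
    if ligand.size == 0:
        # no ligand: numerator and denominator are the same computation
        for k in range(n):
            den[k] = sasa(
                traj.frames[k], system.vdw_radius, target, ctx_without,
                probe_radius, n_points,
            ).sum()
        num[:] = den
    else:
        for k in range(n):
            frame = traj.frames[k]
            num[k] = sasa(
                frame, system.vdw_radius, target, ctx_with, probe_radius, n_points
            ).sum()
            den[k] = sasa(
                frame, system.vdw_radius, target, ctx_without, probe_radius, n_points
            ).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return RASASSeries(
        site_id=site.site_id,
        probe_radius=probe_radius,
        times=traj.times.copy(),
        sasa_with_ligand=num,
        sasa_ligand_ignored=den,
        ratio=ratio,
        sidechain_only=sidechain_only,
    )


def surface_coverage(
    traj: Trajectory,
    probe_radius: float = 2.5,
    receptor_role: str = "receptor",
    ligand_role: str = "ligand",
    n_points: int = DEFAULT_N_POINTS,
) -> CoverageSeries:
    """Fraction of the whole receptor surface occluded by ligand fragments.

    Per frame: ``1 − SASA(receptor | ligand present) / SASA(receptor |
    ligand ignored)`` with the entire receptor role as target and a 2.5 Å
    probe by default (≈ 5 Å proximity distance).
    """
    system = traj.system
    target = system.role_indices(receptor_role)
    if target.size == 0:
        raise ValueError(f"receptor role {receptor_role!r} is empty")
    ligand = system.role_indices(ligand_role)
    non_water = system.non_water_indices()
    ctx_with = np.setdiff1d(non_water, target)
    ctx_without = np.setdiff1d(ctx_with, ligand)

    n = traj.n_frames
    cov = np.empty(n)
    for k in range(n):
        frame = traj.frames[k]
        with_lig = sasa(
            frame, system.vdw_radius, target, ctx_with, probe_radius, n_points
        ).sum()
        without = sasa(
            frame, system.vdw_radius, target, ctx_without, probe_radius, n_points
        ).sum()
        cov[k] = 1.0 - (with_lig / without if without > 0 else 1.0)
    return CoverageSeries(probe_radius=probe_radius, times=traj.times.copy(), coverage=cov)
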