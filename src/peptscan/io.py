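"""Structure, trajectory, alignment and parameter-table I/O.

PDB handling is deliberately strict: records are parsed by fixed columns,
malformed records raise :class:`PdbParseError` naming the offending line,
and the writer emits exactly the fields the reader parses, so a
read-write-read cycle is lossless.  Multi-model PDB files serve as the
plain-text trajectory format.

Alignments (aligned FASTA or Clustal) are loaded through Biopython's
``AlignIO``; the parameter table is a TSV mapping (residue, atom) — with an
element-level fallback — to vdW radius, partial charge and Lennard-Jones
parameters.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

from .model import (
    AtomRecord,
    ION_RESNAMES,
    MolecularSystem,
    SiteDefinition,
    SiteResidue,
    Trajectory,
    WATER_RESNAMES,
)

__all__ = [
    "PdbParseError",
    "read_pdb",
    "write_pdb",
    "read_multimodel_trajectory",
    "write_multimodel_trajectory",
    "ParameterTable",
    "read_parameter_table",
    "bundled_parameter_table",
    "assign_parameters",
    "read_alignment",
    "write_alignment",
    "read_sites_json",
    "table1_fixture",
    "select_atoms",
]

log = logging.getLogger(__name__)


class PdbParseError(ValueError):
    """Raised for malformed fixed-width PDB records; names the line number."""


_GUESS_ELEMENT = re.compile(r"[A-Z]")


def _guess_element(name: str) -> str:
    """Element from an atom-name token when columns 77-78 are blank."""
    stripped = name.strip()
    if stripped[:1].isdigit():
        stripped = stripped.lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[0] == "H" or (len(stripped) > 1 and stripped[:2] in ("1H", "2H", "3H")):
        return "H"
    return stripped[0]


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    if len(line.rstrip("\n")) < 54:
        raise PdbParseError(f"line {lineno}: record too short for coordinates")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PdbParseError(f"line {lineno}: malformed fixed-width field ({exc})") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name)
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        chain_id=chain,
        residue_seq=resseq,
        residue_name=resname,
        coords=(x, y, z),
    )


def read_pdb(path: str | Path, keep_waters: bool = False) -> MolecularSystem:
    """Read ATOM/HETATM records from a (single-model) PDB file.

    HETATM residues that are not waters/ions are kept and assigned to the
    ``cofactor`` role; waters and monatomic ions are dropped unless
    *keep_waters* is set.  For multi-model files only the first model is
    read (use :func:`read_multimodel_trajectory` for the frames).
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    het_flags: list[bool] = []
    in_model = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                in_model += 1
                if in_model > 1:
                    break
            elif rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(line, lineno)
                if not keep_waters and rec == "HETATM" and (
                    atom.residue_name in WATER_RESNAMES or atom.residue_name in ION_RESNAMES
                ):
                    continue
                # altloc: keep only the blank or 'A' conformer
                altloc = line[16].strip()
                if altloc and altloc != "A":
                    continue
                atoms.append(atom)
                het_flags.append(rec == "HETATM")
    if not atoms:
        raise PdbParseError(f"{path}: no atoms")
    system = MolecularSystem(atoms)
    het_idx = [i for i, h in enumerate(het_flags) if h]
    if het_idx:
        system.set_role("cofactor", het_idx)
    return system


def _format_atom_line(a: AtomRecord, het: bool) -> str:
    name = a.name
    # standard PDB alignment: names of <4 chars start in column 14
    if len(name) < 4 and not name[:1].isdigit():
        name = " " + name
    rec = "HETATM" if het else "ATOM  "
    return (
        f"{rec}{a.serial:5d} {name:<4s}{'':1s}{a.residue_name:>3s} "
        f"{a.chain_id:1s}{a.residue_seq:4d}    "
        f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
    )


def write_pdb(system: MolecularSystem, path: str | Path) -> None:
    """Write the system as a single-model PDB (fields the reader parses)."""
    het = np.zeros(system.n_atoms, dtype=bool)
    cof = system.role_indices("cofactor")
    het[cof] = True
    with open(path, "w") as fh:
        for i in range(system.n_atoms):
            fh.write(_format_atom_line(system.atom(i), bool(het[i])))
        fh.write("END\n")


def read_multimodel_trajectory(
    path: str | Path,
    system: MolecularSystem,
    frame_interval_ns: float = 0.1,
    t0_ns: float = 0.0,
) -> Trajectory:
    """Read a MODEL/ENDMDL multi-model PDB as a trajectory over *system*.

    Every model must contain exactly the system's atoms in the same order;
    a mismatch raises an error naming the model index.  Times are assigned
    as ``t0 + k * frame_interval``.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    current: list[tuple[float, float, float]] | None = None
    model_no = 0
    n = system.n_atoms
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                model_no += 1
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(line, lineno)
                if current is None:  # MODEL-free file: single implicit model
                    model_no = 1
                    current = []
                if atom.residue_name in WATER_RESNAMES or atom.residue_name in ION_RESNAMES:
                    continue
                current.append(atom.coords)
            elif rec.startswith("ENDMDL"):
                if current is None:
                    raise PdbParseError(f"line {lineno}: ENDMDL without MODEL")
                if len(current) != n:
                    raise PdbParseError(
                        f"model {model_no}: {len(current)} atoms, expected {n}"
                    )
                frames.append(np.asarray(current, dtype=float))
                current = None
    if current is not None:  # trailing model without ENDMDL
        if len(current) != n:
            raise PdbParseError(f"model {model_no}: {len(current)} atoms, expected {n}")
        frames.append(np.asarray(current, dtype=float))
    if not frames:
        raise PdbParseError(f"{path}: no models")
    times = t0_ns + frame_interval_ns * np.arange(len(frames))
    return Trajectory(system=system, frames=np.stack(frames), times=times)


def write_multimodel_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB."""
    system = traj.system
    het = np.zeros(system.n_atoms, dtype=bool)
    het[system.role_indices("cofactor")] = True
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"MODEL {k + 1:8d}\n")
            for i in range(system.n_atoms):
                a = system.atom(i)
                a = AtomRecord(
                    serial=a.serial, name=a.name, element=a.element,
                    chain_id=a.chain_id, residue_seq=a.residue_seq,
                    residue_name=a.residue_name,
                    coords=tuple(float(x) for x in traj.frames[k, i]),
                )
                fh.write(_format_atom_line(a, bool(het[i])))
            fh.write("ENDMDL\n")
        fh.write("END\n")


# --------------------------------------------------------------------------- #
# parameter table


@dataclass
class ParameterTable:
    """Maps (residue_name, atom_name) or element to nonbonded parameters.

    Specific (residue, atom) rows take precedence; rows with residue ``*``
    keyed by element symbol act as the fallback class.
    """

    specific: dict[tuple[str, str], tuple[float, float, float, float]]
    element_fallback: dict[str, tuple[float, float, float, float]]

    def lookup(
        self, residue_name: str, atom_name: str, element: str
    ) -> tuple[tuple[float, float, float, float] | None, bool]:
        """Return ((radius, charge, epsilon, rmin_half), used_fallback)."""
        key = (residue_name, atom_name)
        if key in self.specific:
            return self.specific[key], False
        if element in self.element_fallback:
            return self.element_fallback[element], True
        return None, False


_TABLE_HEADER = ["residue", "atom", "radius", "charge", "epsilon", "rmin_half"]


def read_parameter_table(path: str | Path) -> ParameterTable:
    """Read a TSV parameter table (header: residue atom radius charge epsilon rmin_half)."""
    specific: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    fallback: dict[str, tuple[float, float, float, float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip() for h in header] != _TABLE_HEADER:
            raise ValueError(
                f"{path}: parameter table header must be {_TABLE_HEADER}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path} line {lineno}: expected 6 columns")
            res, atom = parts[0].strip(), parts[1].strip()
            try:
                vals = tuple(float(p) for p in parts[2:])
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
            if vals[0] <= 0:
                raise ValueError(f"{path} line {lineno}: radius must be positive")
            if res == "*":
                fallback[atom] = vals  # type: ignore[assignment]
            else:
                specific[(res, atom)] = vals  # type: ignore[assignment]
    return ParameterTable(specific=specific, element_fallback=fallback)


def bundled_parameter_table() -> ParameterTable:
    """The packaged reduced parameter set.

    Per-element vdW radii (C 1.7, N 1.55, O 1.52, S 1.8, H 1.2 Å), side-chain
    formal charges localized on the terminal polar atoms of charged residues,
    and generic per-element Lennard-Jones parameters.  Intended as a usable
    default that users can replace with real force-field values via
    :func:`read_parameter_table`.
    """
    with resources.as_file(
        resources.files("peptscan.data").joinpath("nonbonded.tsv")
    ) as p:
        return read_parameter_table(p)


def assign_parameters(
    system: MolecularSystem,
    table: ParameterTable,
    element_fallback: bool = True,
) -> MolecularSystem:
    """Return a copy of *system* with every atom parameterized from *table*.

    Atoms without a specific (residue, atom) row use the element-level
    fallback (logged).  Any atom matching neither raises, listing the
    unmatched atoms.
    """
    new = system.copy()
    unmatched: list[str] = []
    n_fallback = 0
    for i in range(new.n_atoms):
        res = str(new.residue_names[i])
        atom = str(new.names[i])
        elem = str(new.elements[i])
        entry, used_fb = table.lookup(res, atom, elem if element_fallback else "\0")
        if entry is None:
            unmatched.append(f"{res} {atom} (chain {new.chain_ids[i]} {new.residue_seqs[i]})")
            continue
        if used_fb:
            n_fallback += 1
            log.debug("element fallback for %s %s -> %s", res, atom, elem)
        radius, charge, eps, rmin_half = entry
        new.vdw_radius[i] = radius
        new.partial_charge[i] = charge
        new.lj_epsilon[i] = eps
        new.lj_rmin_half[i] = rmin_half
    if unmatched:
        preview = "; ".join(unmatched[:10])
        raise ValueError(
            f"{len(unmatched)} atoms without parameter-table entry or fallback: {preview}"
        )
    if n_fallback:
        log.info("parameter assignment used element fallback for %d atoms", n_fallback)
    return new


# --------------------------------------------------------------------------- #
# alignments


def read_alignment(path: str | Path) -> MultipleSeqAlignment:
    """Read an aligned FASTA or Clustal file; rows must have equal length."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    fmt = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise ValueError(f"{path}: not a valid {fmt} alignment ({exc})") from exc
    lengths = {len(rec.seq) for rec in aln}
    if len(lengths) > 1:
        raise ValueError(f"{path}: ragged alignment rows, lengths {sorted(lengths)}")
    return aln


def write_alignment(aln: MultipleSeqAlignment, path: str | Path, fmt: str = "fasta") -> None:
    AlignIO.write(aln, str(path), fmt)


# --------------------------------------------------------------------------- #
# packaged site fixture


def _sites_from_mapping(raw: dict) -> list[SiteDefinition]:
    sites: list[SiteDefinition] = []
    for s in raw["sites"]:
        residues = [
            SiteResidue(
                residue_seq=r["seq"],
                residue_name=r.get("name", "UNK"),
                predicted_interfacial=r.get("predicted_interfacial", False),
                salt_bridge=r.get("salt_bridge", False),
                fully_conserved=r.get("fully_conserved", False),
                snurportin=r.get("snurportin", False),
            )
            for r in s["residues"]
        ]
        sites.append(
            SiteDefinition(
                site_id=s["site_id"],
                chain_id=s["chain_id"],
                residues=residues,
                position_note=s.get("position_note", ""),
            )
        )
    return sites


def read_sites_json(path: str | Path) -> list[SiteDefinition]:
    """Read a JSON site list ({"sites": [{site_id, chain_id, residues}]})."""
    with open(path) as fh:
        return _sites_from_mapping(json.load(fh))


def table1_fixture() -> list[SiteDefinition]:
    """The packaged list of 11 transient C-Tpr binding sites.

    Sites 1-9 lie on the CRM1 receptor chain, sites 10-11 on Snurportin.
    Per-residue flags mark residues predicted as interfacial by an external
    predictor and residues that form salt bridges (3.2 Å cutoff).
    Fully-conserved annotations are not encoded in this fixture (flags are
    False); use :mod:`peptscan.conservation` with an alignment to derive
    conservation classes.
    """
    with resources.files("peptscan.data").joinpath("binding_sites.json").open() as fh:
        raw = json.load(fh)
    return _sites_from_mapping(raw)


# --------------------------------------------------------------------------- #
# atom selection mini-language


def select_atoms(system: MolecularSystem, expr: str) -> np.ndarray:
    """Resolve a selection expression to atom indices.

    Grammar: comma-separated union of terms ``chain:<id>`` and
    ``resid:<a>-<b>`` (inclusive author numbers) or ``resid:<a>``.  A term
    combining both, e.g. ``chain:A/resid:5-8``, intersects its parts.
    """
    chosen = np.zeros(system.n_atoms, dtype=bool)
    for term in expr.split(","):
        term = term.strip()
        if not term:
            continue
        mask = np.ones(system.n_atoms, dtype=bool)
        for part in term.split("/"):
            part = part.strip()
            if part.startswith("chain:"):
                mask &= system.chain_ids.astype(str) == part[6:].strip()
            elif part.startswith("resid:"):
                rng = part[6:].strip()
                m = re.fullmatch(r"(-?\d+)(?:-(\d+))?", rng)
                if m is None:
                    raise ValueError(f"bad residue range {rng!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                mask &= (system.residue_seqs >= lo) & (system.residue_seqs <= hi)
            else:
                raise ValueError(f"unknown selection term {part!r}")
        chosen |= mask
    return np.nonzero(chosen)[0]
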