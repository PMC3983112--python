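"""Alignment-column conservation classes mapped onto binding-site residues.

A residue position is *fully conserved* when every aligned sequence shows
the identical amino acid, and *group conserved* when all sequences stay
within one physicochemical group — acidic, basic, polar uncharged or
nonpolar — so that evolutionary substitutions preserve charge and polarity.
Columns that are mostly gaps are reported as such rather than classified.

The default group partition:

=================  ==========================
acidic             D E
basic              K R H
polar uncharged    S T N Q C Y G
nonpolar           A V L I M F W P
=================  ==========================
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

from Bio.Align import MultipleSeqAlignment

from .model import SiteDefinition

__all__ = [
    "DEFAULT_GROUPS",
    "ConservationProfile",
    "classify_columns",
    "site_conservation",
]

DEFAULT_GROUPS: dict[str, frozenset[str]] = {
    "acidic": frozenset("DE"),
    "basic": frozenset("KRH"),
    "polar_uncharged": frozenset("STNQCYG"),
    "nonpolar": frozenset("AVLIMFWP"),
}

GAP_CHARS = frozenset("-.")

CLASSES = ("fully_conserved", "group_conserved", "not_conserved", "gap_majority")


@dataclass
class ConservationProfile:
    """Per-residue conservation classes of one reference sequence."""

    reference_id: str
    classes: dict[int, str]  # reference residue number -> class
    groups: Mapping[str, frozenset[str]] = field(default_factory=lambda: DEFAULT_GROUPS)

    def __getitem__(self, residue_seq: int) -> str:
        if residue_seq not in self.classes:
            raise KeyError(
                f"residue {residue_seq} outside the conservation profile of "
                f"{self.reference_id!r}"
            )
        return self.classes[residue_seq]


def _group_of(symbol: str, groups: Mapping[str, frozenset[str]]) -> str | None:
    for name, members in groups.items():
        if symbol in members:
            return name
    return None


def classify_columns(
    alignment: MultipleSeqAlignment,
    reference_id: str,
    groups: Mapping[str, frozenset[str]] | None = None,
    start_number: int = 1,
) -> ConservationProfile:
    """Classify every alignment column holding a reference residue.

    Per column: ``gap_majority`` when more than half the rows are gaps;
    otherwise ``fully_conserved`` when all non-gap symbols are identical;
    ``group_conserved`` when they all fall in a single group; else
    ``not_conserved``.  The profile is indexed by reference residue number
    (author numbering starting at *start_number*).
    """
    groups = dict(groups) if groups is not None else DEFAULT_GROUPS
    ref_row = None
    for rec in alignment:
        if rec.id == reference_id:
            ref_row = str(rec.seq).upper()
            break
    if ref_row is None:
        ids = [rec.id for rec in alignment]
        raise ValueError(f"reference {reference_id!r} not in alignment (rows: {ids})")

    columns = [str(rec.seq).upper() for rec in alignment]
    n_rows = len(columns)
    classes: dict[int, str] = {}
    resnum = start_number - 1
    for col in range(alignment.get_alignment_length()):
        if ref_row[col] in GAP_CHARS:
            continue
        resnum += 1
        symbols = [row[col] for row in columns]
        gaps = sum(1 for s in symbols if s in GAP_CHARS)
        non_gap = [s for s in symbols if s not in GAP_CHARS]
        if gaps > n_rows / 2:
            classes[resnum] = "gap_majority"
        elif len(set(non_gap)) == 1:
            classes[resnum] = "fully_conserved"
        else:
            col_groups = {_group_of(s, groups) for s in non_gap}
            if None not in col_groups and len(col_groups) == 1:
                classes[resnum] = "group_conserved"
            else:
                classes[resnum] = "not_conserved"
    return ConservationProfile(reference_id=reference_id, classes=classes, groups=groups)


def site_conservation(
    profile: ConservationProfile, site: SiteDefinition
) -> tuple[dict[int, str], Counter]:
    """Look up the class of each site residue and summarize counts.

    Returns (per-residue classes keyed by residue number, Counter over
    classes).  A site residue outside the profile raises, naming it.
    """
    per_residue: dict[int, str] = {}
    for r in site.residues:
        try:
            per_residue[r.residue_seq] = profile[r.residue_seq]
        except KeyError as exc:
            raise KeyError(
                f"site {site.site_id}: residue {r.residue_name}{r.residue_seq} "
                f"outside conservation profile"
            ) from exc
    return per_residue, Counter(per_residue.values())
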