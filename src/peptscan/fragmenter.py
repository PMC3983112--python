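"""Segment an unstructured protein tail into overlapping peptide fragments.

A fragment scan tiles the chain with nominally 30-residue windows that
overlap by 10 residues, so no candidate binding region can be split across
a fragment boundary.  Proline is structurally constrained; a fragment end
falling near a proline would bias the fragment's local geometry, so windows
are extended (up to a maximum length, default 44) until neither the
fragment's trailing residues nor the next fragment's leading residues
contain the avoided residue.  The final fragment is anchored to the chain
end and back-extended to at least the nominal length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

__all__ = ["Fragment", "segment_chain"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Fragment:
    """An overlapping subsequence of the scanned chain.

    ``start``/``end`` are inclusive author residue numbers; ``index`` is
    1-based in scan order.
    """

    index: int
    start: int
    end: int
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start + 1


def _window_clean(seq: str, end: int, overlap: int, avoid: str, window: int) -> bool:
    """True when neither the fragment-end window nor the next-start window
    contains the avoided residue.  *end* is the exclusive 0-based fragment end."""
    tail = seq[max(0, end - window):end]
    next_start = end - overlap
    head = seq[max(0, next_start):next_start + window] if next_start < len(seq) else ""
    return avoid not in tail and avoid not in head


def segment_chain(
    sequence: str,
    start_number: int = 1,
    nominal_len: int = 30,
    max_len: int = 44,
    overlap: int = 10,
    avoid_residue: str = "P",
    end_window: int = 3,
) -> list[Fragment]:
    """Tile *sequence* into overlapping fragments.

    Parameters
    ----------
    sequence:
        1-letter amino-acid string.
    start_number:
        Author number of the first residue (fragment coordinates are
        reported in author numbering).
    nominal_len, max_len:
        Nominal and maximum fragment lengths; windows grow beyond nominal
        only to push the avoided residue away from fragment ends.
    overlap:
        Minimum residues shared by consecutive fragments.
    avoid_residue, end_window:
        Residue to keep out of the first/last *end_window* positions of
        every internal fragment boundary.

    Returns fragments that cover every residue, overlap by at least
    *overlap*, and respect the length bounds (except when avoidance is
    impossible within *max_len*, which is logged and the nominal end kept).
    """
    sequence = sequence.strip().upper()
    n = len(sequence)
    if not 0 < overlap < nominal_len <= max_len:
        raise ValueError("require 0 < overlap < nominal_len <= max_len")
    if n < nominal_len:
        log.warning(
            "sequence of %d residues shorter than nominal fragment length %d; "
            "emitting a single fragment", n, nominal_len,
        )
        return [Fragment(1, start_number, start_number + n - 1, sequence)]

    fragments: list[Fragment] = []
    start = 0
    while True:
        end = start + nominal_len  # exclusive
        if end >= n:
            # final fragment: anchor to the chain end, back-extend to nominal
            final_start = min(start, n - nominal_len)
            fragments.append(
                Fragment(
                    index=len(fragments) + 1,
                    start=start_number + final_start,
                    end=start_number + n - 1,
                    sequence=sequence[final_start:],
                )
            )
            break
        if avoid_residue:
            while (
                not _window_clean(sequence, end, overlap, avoid_residue, end_window)
                and end - start < max_len
                and end < n
            ):
                end += 1
            if end >= n:
                final_start = min(start, n - nominal_len)
                fragments.append(
                    Fragment(
                        index=len(fragments) + 1,
                        start=start_number + final_start,
                        end=start_number + n - 1,
                        sequence=sequence[final_start:],
                    )
                )
                break
            if not _window_clean(sequence, end, overlap, avoid_residue, end_window):
                end = start + nominal_len
                log.warning(
                    "fragment %d: cannot avoid %r near the boundary within "
                    "max_len=%d; keeping nominal end",
                    len(fragments) + 1, avoid_residue, max_len,
                )
        fragments.append(
            Fragment(
                index=len(fragments) + 1,
                start=start_number + start,
                end=start_number + end - 1,
                sequence=sequence[start:end],
            )
        )
        start = end - overlap
    return fragments
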