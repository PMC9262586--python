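"""Junction coordinate arithmetic: left-alignment and microhomology.

A deletion of ``[left, right)`` from a sequence is ambiguous whenever the
flanks share sequence at the junction: the placements ``[left+k, right+k)``
reconstruct the same product for every ``k`` within the shared run.  The
canonical placement reported throughout the package is the leftmost one, and
the microhomology length is the size of that shared run (equivalently, the
number of equivalent placements minus one).
"""

from __future__ import annotations

__all__ = ["left_align", "microhomology_length", "equivalent_placements"]


def left_align(seq: str, left: int, right: int) -> tuple[int, int]:
    """Shift a deletion ``[left, right)`` to its leftmost equivalent placement."""
    if not (0 < right <= len(seq)) or not (0 <= left < right):
        raise ValueError("breakpoints must satisfy 0 <= left < right <= len(seq)")
    while left > 0 and seq[left - 1] == seq[right - 1]:
        left -= 1
        right -= 1
    return left, right


def microhomology_length(seq: str, left: int, right: int) -> int:
    """Microhomology of the deletion ``[left, right)`` (any placement).

    Counts backward-shiftable plus forward-shiftable positions, so the result
    is placement-invariant: it equals the maximal exact repeat shared by the
    two junction flanks.
    """
    if not (0 < right <= len(seq)) or not (0 <= left < right):
        raise ValueError("breakpoints must satisfy 0 <= left < right <= len(seq)")
    back = 0
    while left - back > 0 and seq[left - back - 1] == seq[right - back - 1]:
        back += 1
    fwd = 0
    while right + fwd < len(seq) and seq[left + fwd] == seq[right + fwd]:
        fwd += 1
    return back + fwd


def equivalent_placements(seq: str, left: int, right: int) -> list[tuple[int, int]]:
    """All placements reconstructing the same deletion product, leftmost first."""
    l0, r0 = left_align(seq, left, right)
    out = [(l0, r0)]
    while r0 < len(seq) and seq[l0] == seq[r0]:
        l0 += 1
        r0 += 1
        out.append((l0, r0))
    return out
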