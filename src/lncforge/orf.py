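"""Longest-ORF search on the sense strand of a spliced transcript sequence."""

from __future__ import annotations

__all__ = ["find_max_orf"]

_STOPS = frozenset({"TAA", "TAG", "TGA"})


def find_max_orf(seq: str) -> tuple[int, int | None, int | None]:
    """Longest ATG..stop ORF over the three forward frames.

    Returns ``(aa_length, start_offset, frame)`` where ``aa_length`` excludes
    the stop codon.  Only stop-terminated ORFs count: an ATG that never meets
    an in-frame stop before the sequence end is ignored.  Ties are broken by
    the leftmost start offset.  ``(0, None, None)`` when no complete ORF
    exists.  Transcripts are assumed oriented, so the reverse strand is never
    scanned.
    """
    seq = seq.upper()
    best_aa, best_start = 0, None
    for frame in range(3):
        open_start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in _STOPS:
                if open_start is not None:
                    aa = (i - open_start) // 3
                    if aa > best_aa or (aa == best_aa and best_start is not None
                                        and open_start < best_start):
                        best_aa, best_start = aa, open_start
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = i
    if best_start is None:
        return 0, None, None
    return best_aa, best_start, best_start % 3
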