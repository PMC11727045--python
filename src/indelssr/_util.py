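"""Small shared helpers: sequence utilities and coordinate conventions.

All internal coordinates are 0-based half-open; anything read from or
written to VCF/GFF3/TSV is 1-based inclusive.  The two helpers below are
the only place the conversion happens.
"""

from __future__ import annotations

import logging

logger = logging.getLogger("indelssr")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_motif_class(motif: str) -> str:
    """Pool a motif with its reverse complement (not its rotations).

    Returns a label like ``"AG/CT"`` (lexicographically smaller member
    first) or ``"AT/AT"`` collapsed to ``"AT"`` when self-complementary.
    """
    rc = revcomp(motif)
    a, b = sorted((motif, rc))
    return a if a == b else f"{a}/{b}"


def to_external(pos0: int) -> int:
    """0-based internal position -> 1-based external."""
    return pos0 + 1


def to_internal(pos1: int) -> int:
    """1-based external position -> 0-based internal."""
    return pos1 - 1


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def at_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("A") + seq.count("T")) / len(seq)
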