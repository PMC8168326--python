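"""Small shared helpers."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero-free: .5 always rounds up."""
    import math

    return int(math.floor(x + 0.5))
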