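"""Small shared helpers: rounding conventions and sequence primitives."""

from __future__ import annotations

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTRYSWKMN-.", "TGCAYRSWMKN-.")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved as upper)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (so 16.5 -> 17, not banker's 16).

    All printed percentages in the reports use this convention; it is what
    reproduces 7/42 -> 17 and 13/42 -> 31.
    """
    from decimal import Decimal, ROUND_HALF_UP

    q = Decimal(10) ** -ndigits
    v = float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
    return int(v) if ndigits <= 0 else v
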