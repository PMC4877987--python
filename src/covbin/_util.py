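"""Small shared helpers."""

from __future__ import annotations

import math

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (report convention).

    Python's built-in round() uses banker's rounding, which would turn
    e.g. 0.25 into 0.2 at one decimal; percentages in reports follow the
    half-away-from-zero convention instead.
    """
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
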