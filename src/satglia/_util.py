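"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero.

    Python's built-in ``round`` uses banker's rounding; reported distances
    and percentages use the conventional half-away-from-zero rule instead.
    """
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))
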