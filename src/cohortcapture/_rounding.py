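"""Deterministic decimal rounding helpers.

Counts and similarity indices in reports are rounded half away from zero
(the convention of most clinical tables), not banker's rounding as Python's
built-in ``round`` does.
"""

from __future__ import annotations

import math

__all__ = ["round_half_away", "round_half_up_places"]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def round_half_up_places(x: float, places: int) -> float:
    """Round to ``places`` decimals, halves away from zero."""
    scale = 10**places
    return round_half_away(x * scale) / scale
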