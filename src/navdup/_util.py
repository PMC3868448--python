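"""Small shared numeric helpers."""

from __future__ import annotations

import math
from typing import List, Sequence


def largest_remainder(values: Sequence[float], total: int) -> List[int]:
    """Allocate ``total`` integer units proportionally to ``values``.

    Floors each value, then hands out the remaining units by descending
    fractional remainder; ties go to the earlier index (stable sort).
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    floors = [math.floor(v) for v in values]
    leftover = total - sum(floors)
    if leftover < 0:
        raise ValueError("values already exceed total")
    remainders = sorted(
        range(len(values)), key=lambda i: (-(values[i] - floors[i]), i)
    )
    for i in remainders[:leftover]:
        floors[i] += 1
    return floors


def round_half_away(x: float) -> int:
    """Round to nearest integer with ties away from zero (not banker's)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))
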