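"""Small shared numeric helpers."""

from __future__ import annotations

import math

__all__ = ["round_half_away"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (printed-table convention),
    unlike banker's rounding of the builtin ``round``."""
    factor = 10.0 ** ndigits
    scaled = x * factor
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / factor
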