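"""Small shared numeric helpers."""

from __future__ import annotations

import math

__all__ = ["round_half_away"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (school rounding).

    Python's built-in ``round`` uses banker's rounding; the report tables in
    this package round halves away from zero instead.
    """
    if math.isnan(x) or math.isinf(x):
        return x
    factor = 10.0 ** ndigits
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5)
    out = math.copysign(rounded, x) / factor
    return out if ndigits > 0 else float(int(out))
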