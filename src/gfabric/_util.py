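"""Small shared helpers."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, matching printed-report style.

    Python's built-in ``round`` uses banker's rounding; reports here use
    conventional half-up (5.565 -> 5.57, not 5.56).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """100 * numerator / denominator, half-up rounded to ``ndigits``."""
    return round_half_up(100.0 * numerator / denominator, ndigits)
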