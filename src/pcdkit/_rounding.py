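"""Half-up rounding helpers shared across modules.

Python's built-in ``round`` is banker's rounding; the printed style this
package reproduces (e.g. percentages such as 51.56%, ratios such as 1:17,641)
uses conventional half-up rounding, so all user-facing rounding goes through
these helpers.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def nearest_int_half_up(x: float) -> int:
    """Nearest integer with .5 rounding up (for positive ``x``)."""
    if x < 0:
        raise ValueError("nearest_int_half_up expects a non-negative value")
    return int(math.floor(x + 0.5))


def percent(count: int, total: int, ndigits: int = 2) -> float:
    """Exact-rational percentage ``100*count/total`` rounded half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    frac = Fraction(100 * count, total)
    q = Decimal(1).scaleb(-ndigits)
    return float(
        (Decimal(frac.numerator) / Decimal(frac.denominator)).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )
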