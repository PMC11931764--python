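"""Display-rounding helpers: half-away-from-zero at fixed decimals.

Published diagnostic tables round percentages half-away-from-zero; banker's
rounding (Python's built-in ``round``) would disagree on exact halves, so all
display rounding in the package funnels through these two functions.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Operates on the shortest decimal representation of the float, so values
    such as ``97.0251`` round on their printed digits rather than on binary
    representation artifacts.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_to_int(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(Decimal(repr(float(x))).quantize(Decimal(1), rounding=ROUND_HALF_UP))
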