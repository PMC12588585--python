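"""Decimal half-up rounding used for all presentation output.

Python's built-in ``round`` is banker's rounding; the published preference
tables round halves away from zero, so presentation values go through
:func:`round_half_up` instead.  Internal computation always stays at full
float precision — rounding happens once, at the edge.
"""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals, halves away from zero.

    Uses ``repr`` of the float so that values that are decimal literals
    (e.g. ``3.357``) round the way they read, not the way their binary
    expansion happens to fall.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
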