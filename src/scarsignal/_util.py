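"""Shared numeric helpers (rounding conventions used in all printed tables)."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

__all__ = ["round_half_away", "percent"]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (decimal ROUND_HALF_UP semantics)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, denominator: int, ndigits: int = 1) -> float:
    """100*count/denominator rounded half away from zero at ``ndigits``.

    Computed in exact decimal arithmetic so ties (e.g. 6.25%) round the same
    way regardless of binary floating-point representation.  A zero
    denominator yields 0.0 by convention.
    """
    if denominator == 0:
        return 0.0
    q = Decimal(1).scaleb(-ndigits)
    value = (Decimal(count) * 100 / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)
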