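"""Summary formatting helpers shared by the reporting surfaces."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def fraction_percent(numerator: float, denominator: float, digits: int = 2) -> float:
    """Numerator/denominator as a percentage rounded half-up.

    Half-up rounding matches how genome summary tables print fractions
    (e.g. 34/64 -> 53.13, not banker's 53.12).
    """
    if denominator == 0:
        raise ZeroDivisionError("zero denominator")
    pct = Decimal(str(numerator)) / Decimal(str(denominator)) * 100
    q = Decimal(1).scaleb(-digits)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def format_percent(numerator: float, denominator: float, digits: int = 2) -> str:
    return f"{fraction_percent(numerator, denominator, digits):.{digits}f}%"
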