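"""Small shared helpers."""

from __future__ import annotations

import decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with the half-up convention used for reported values.

    Python's builtin round() is banker's rounding; reported community
    proportions and fold changes follow the half-up convention instead
    (0.125 -> 0.13 at 2 digits).
    """
    quant = decimal.Decimal(1).scaleb(-ndigits)
    return float(
        decimal.Decimal(repr(value)).quantize(quant, rounding=decimal.ROUND_HALF_UP)
    )
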