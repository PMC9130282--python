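"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (report-table convention).

    Python's built-in round() uses banker's rounding, which disagrees with
    how agronomic report tables round .005 boundaries (e.g. 3.275 -> 3.28).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
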