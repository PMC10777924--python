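"""Report arithmetic: percentage formatting shared by every summary table."""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, Decimal


def ratio(numerator: int, denominator: int) -> float:
    """Percentage ``100 * numerator / denominator`` rounded half-even to 2
    decimals — the precision used by every printed summary figure."""
    if denominator == 0:
        raise ValueError("denominator must be > 0")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))
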