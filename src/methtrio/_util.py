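"""Small shared numeric/reporting helpers."""

from __future__ import annotations

import math


def percent(count: float, total: float, decimals: int = 2) -> float:
    """100 * count / total, rounded to ``decimals`` places.

    This is the single reporting path for every percentage the pipeline
    prints, so count tables and summaries round consistently.
    """
    if total <= 0:
        raise ValueError("percent() requires a positive denominator")
    return round(100.0 * count / total, decimals)


def round_sig(x: float, sig: int = 4) -> float:
    """Round ``x`` to ``sig`` significant digits."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))
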