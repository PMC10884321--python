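"""Half-up decimal rounding used for reported index values.

Python's built-in ``round`` is banker's rounding; published anatomy index
tables round half away from zero (0.0845 -> 0.085), so reported values go
through :func:`round_half_up`.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, decimals: int = 3) -> float:
    """Round ``x`` half-up to ``decimals`` places."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_value(x: float, decimals: int = 3, min_sig: int = 2) -> str:
    """Format a value at ``decimals`` places, extending for tiny values.

    Keeps at least ``min_sig`` significant digits for small non-zero values,
    so 0.027778 renders as "0.0278" rather than "0.028" losing precision
    relative to the convention of its source table.
    """
    if x == 0:
        return f"{0:.{decimals}f}"
    d = decimals
    s = f"{round_half_up(x, d):.{d}f}"
    while d < 12:
        s = f"{round_half_up(x, d):.{d}f}"
        sig = len(s.replace("-", "").replace(".", "").lstrip("0"))
        if sig >= min_sig:
            break
        d += 1
    return s
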