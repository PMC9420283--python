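"""Display rounding and formatting helpers.

All analysis code keeps full floating-point precision; rounding happens
once, at report time. Published burden tables round half-up (2.575 -> 2.58),
which differs from Python's built-in banker's rounding, and several table
cells sit exactly on a decimal midpoint (e.g. 0.0135 x 4,275,100 =
57,713.85) where the nearest binary double lies a hair below the midpoint.
``round_half_up`` therefore quantizes through :class:`decimal.Decimal` with
a guard stage so that values intended to be exact decimals round the way a
human with a pencil would.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "format_percent", "format_dalys"]

#: extra decimal digits absorbed before the final quantization, so that
#: binary representation error (~1e-16 relative) cannot flip a midpoint
_GUARD_DIGITS = 6


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round ``value`` to ``ndigits`` decimals, ties away from zero.

    A two-stage quantization: first to ``ndigits + 6`` decimals (recovering
    intended exact decimals from their float representation), then to
    ``ndigits``.
    """
    d = Decimal(repr(float(value)))
    guard = Decimal(1).scaleb(-(ndigits + _GUARD_DIGITS))
    final = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(guard, ROUND_HALF_UP).quantize(final, ROUND_HALF_UP))


def format_percent(fraction: float) -> str:
    """Render a proportion as a 2-decimal percent string, e.g. ``'2.58%'``."""
    return f"{round_half_up(fraction * 100.0, 2):.2f}%"


def format_dalys(dalys: float) -> str:
    """Render person-years to 1 decimal with thousands separators."""
    return f"{round_half_up(dalys, 1):,.1f}"
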