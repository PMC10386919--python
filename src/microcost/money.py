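"""Exact money arithmetic.

Monetary amounts are held internally as exact rationals
(:class:`fractions.Fraction`).  Ledger sums, effort-weighted splits and
currency conversion are therefore free of binary floating-point error;
half-up rounding to cents happens exactly once, at presentation.  This
order of operations is what makes per-participant tables reproducible to
the cent: dividing a full-precision arm total by the recipient count and
*then* rounding gives the printed value, whereas summing pre-rounded
cells does not.
"""

from __future__ import annotations

from decimal import Decimal
from fractions import Fraction
from typing import Union

#: Public alias: monetary amounts are exact rationals.
Money = Fraction

#: Anything :func:`as_money` can coerce.
MoneyLike = Union[int, float, str, Decimal, Fraction]

__all__ = ["Money", "MoneyLike", "as_money", "parse_money", "round_half_up", "format_money"]


def as_money(value: MoneyLike) -> Money:
    """Coerce *value* to an exact rational amount.

    Floats are interpreted through their shortest decimal repr (so
    ``as_money(0.1) == Fraction(1, 10)``), which matches what a user who
    typed ``0.1`` meant.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, bool):  # bool is an int subclass; reject explicitly
        raise TypeError("cannot interpret bool as a money amount")
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, Decimal):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(Decimal(repr(value)))
    if isinstance(value, str):
        return parse_money(value)
    raise TypeError(f"cannot interpret {type(value).__name__} as a money amount")


def parse_money(text: str) -> Money:
    """Parse a money string into an exact rational.

    Accepts plain decimals, thousands separators and a leading currency
    sign (``"4,042.27"``, ``"$1,763.38"``), and the exact-rational form
    ``"p/q"`` used to round-trip non-terminating amounts produced by
    effort-weighted splits.
    """
    cleaned = text.strip().replace(",", "").replace("$", "").replace(" ", "")
    if not cleaned:
        raise ValueError("empty money value")
    try:
        return Fraction(cleaned)
    except (ValueError, ZeroDivisionError) as exc:
        raise ValueError(f"unparseable money value: {text!r}") from exc


def round_half_up(value: MoneyLike, places: int = 2) -> Decimal:
    """Round to *places* decimals, ties away from zero, exactly.

    Operates on the exact rational, so ``round_half_up(Fraction(2675, 1000))``
    is ``Decimal('2.68')`` — no binary representation artefacts.
    """
    frac = as_money(value) * 10**places
    n, d = frac.numerator, frac.denominator
    if n >= 0:
        q = (2 * n + d) // (2 * d)
    else:
        q = -((2 * -n + d) // (2 * d))
    return Decimal(q).scaleb(-places)


def format_money(value: MoneyLike, places: int = 2) -> str:
    """Presentation string with thousands separators, e.g. ``'23,082.92'``."""
    return f"{round_half_up(value, places):,.{places}f}"
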