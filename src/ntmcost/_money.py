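"""Exact currency arithmetic.

All catalogue prices and billing lines are held as :class:`decimal.Decimal`
euro amounts and rounded half-up at defined boundaries (per-day rates,
per-course totals, invoice lines).  Binary floating point only appears
downstream, in the Monte-Carlo sampler, where amounts are consumed as
read-only draws and never accumulated back into the books.
"""

from __future__ import annotations

from decimal import Decimal, InvalidOperation, ROUND_HALF_UP

CENT = Decimal("0.01")

__all__ = ["CENT", "cents", "parse_eur", "fmt_eur"]


def cents(amount: Decimal | int | str) -> Decimal:
    """Quantize an amount to whole cents, rounding half-up.

    Half-up (commercial rounding) is the convention used throughout German
    fee-schedule and retail-price arithmetic; 1.955 rounds to 1.96.
    """
    return Decimal(amount).quantize(CENT, rounding=ROUND_HALF_UP)


def parse_eur(text: str | Decimal | int) -> Decimal:
    """Parse a euro amount from catalogue text.

    Strips a leading/trailing euro sign, surrounding whitespace and
    thousands separators, so ``"€10,551.6"`` parses as ``Decimal('10551.6')``.
    The decimal separator is always ``"."``.
    """
    if isinstance(text, Decimal):
        return text
    if isinstance(text, int):
        return Decimal(text)
    cleaned = text.strip().replace("€", "").replace(",", "").strip()
    try:
        return Decimal(cleaned)
    except InvalidOperation as exc:
        raise ValueError(f"not a euro amount: {text!r}") from exc


def fmt_eur(amount: Decimal) -> str:
    """Render an amount with two decimals, no thousands separators."""
    return f"{cents(amount):.2f}"
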