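"""Drug-course costing.

Per-day drug rates are derived from retail pack prices as
``pack_price / pack_quantity * daily_intake``, rounded half-up to the cent
(the only reading that reproduces the published per-day column).  Course
costs use 30-day months — 14 months = 420 days, 18 months = 540 days — and
add a separately priced IV amikacin block (daily IV rate x course days)
where the regimen carries one.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal

from ._money import cents
from .catalog import DrugProduct, IVComponent, Regimen

__all__ = [
    "DAYS_PER_MONTH",
    "CourseCost",
    "daily_cost",
    "regimen_daily_cost",
    "iv_addon_cost",
    "course_cost",
]

#: Month length used to convert treatment months to dosing days.
DAYS_PER_MONTH = 30

#: How a regimen's per-day rate aggregates its components: sum the
#: per-drug rates already rounded to the cent ("rounded_components",
#: default), or round the exact sum once ("round_sum").
CONVENTIONS = ("rounded_components", "round_sum")


@dataclass(frozen=True)
class CourseCost:
    """Drug cost of one regimen over one treatment duration."""

    regimen_label: str
    duration_months: int
    oral_cost: Decimal
    iv_cost: Decimal

    @property
    def total_drug_cost(self) -> Decimal:
        return self.oral_cost + self.iv_cost


def daily_cost(product: DrugProduct) -> Decimal:
    """Per-day cost of one drug, rounded half-up to the cent."""
    if product.pack_quantity <= 0:
        raise ValueError(f"{product.abbreviation}: pack_quantity must be positive")
    return cents(product.pack_price / product.pack_quantity * product.daily_intake)


def regimen_daily_cost(regimen: Regimen, convention: str = "rounded_components") -> Decimal:
    """Per-day cost of a regimen's oral drugs (IV component excluded)."""
    if not regimen.oral_drugs:
        raise ValueError(f"{regimen.label}: regimen has no oral drugs")
    if convention == "rounded_components":
        return sum((daily_cost(d) for d in regimen.oral_drugs), Decimal("0.00"))
    if convention == "round_sum":
        exact = sum(
            (d.pack_price / d.pack_quantity * d.daily_intake for d in regimen.oral_drugs),
            Decimal(0),
        )
        return cents(exact)
    raise ValueError(f"unknown summation convention {convention!r}")


def iv_addon_cost(iv: IVComponent) -> Decimal:
    """Cost of the IV block: per-day rate x course days (0 if no days)."""
    return cents(daily_cost(iv.drug) * iv.course_days)


def course_cost(
    regimen: Regimen,
    duration_months: int,
    convention: str = "rounded_components",
    days_per_month: int = DAYS_PER_MONTH,
) -> CourseCost:
    """Total drug cost of a regimen over a treatment duration.

    Oral cost is the per-day regimen rate times ``duration_months`` 30-day
    months; the IV block is priced for its own fixed course length and does
    not scale with treatment duration.
    """
    if duration_months < 0:
        raise ValueError("duration_months must be >= 0")
    oral = cents(regimen_daily_cost(regimen, convention) * duration_months * days_per_month)
    iv = iv_addon_cost(regimen.iv) if regimen.iv is not None else Decimal("0.00")
    return CourseCost(regimen.label, duration_months, oral, iv)
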