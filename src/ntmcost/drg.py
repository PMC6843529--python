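"""Hospital-side reimbursement under the G-DRG system.

The NTM hospital group (E76C: TB/NTM without severe complications, stay up
to 14 days) is paid a flat case rate — national base rate times the group's
cost weight — regardless of the actual length of stay up to the cap and of
any coded secondary diagnoses.  The grouper itself is out of scope; its
published parameters are plain configuration.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

from ._money import cents
from .catalog import DRGParameters

__all__ = ["drg_case_payment", "per_bed_day_rate", "per_bed_day_rate_display"]


def drg_case_payment(params: DRGParameters, length_of_stay_days: int | None = None) -> Decimal:
    """Flat case payment: base rate x cost weight, to the cent.

    ``length_of_stay_days`` is accepted only to document the flat-rate
    property: any stay from admission to the cap pays the same amount.
    """
    if length_of_stay_days is not None and length_of_stay_days > params.cap_days:
        raise ValueError(
            f"stay of {length_of_stay_days} days exceeds the {params.cap_days}-day group cap")
    return cents(params.base_rate * params.cost_weight)


def per_bed_day_rate(params: DRGParameters) -> Decimal:
    """Average reimbursement per occupied bed day, to the cent.

    The unrounded case payment divided by the group's mean length of stay.
    """
    return cents(params.base_rate * params.cost_weight / params.mean_length_of_stay)


def per_bed_day_rate_display(params: DRGParameters) -> Decimal:
    """Per-bed-day rate at the published one-decimal display precision."""
    exact = params.base_rate * params.cost_weight / params.mean_length_of_stay
    return exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
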