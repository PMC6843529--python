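"""Intersectoral comparison report.

Assembles the headline figures of the analysis: mean outpatient cost and
its drug component from the two Monte-Carlo stages, quarterly physician
revenues over the 26- and 30-month pathways, the hospital flat case
payment, and the percentage shares relating them.  Shares are computed
from unrounded cent-level values and rounded once, to one decimal, for
display.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from typing import Mapping, Sequence

from .catalog import DRGParameters, FeeItem, default_fee_schedule
from .drg import drg_case_payment
from .monitoring import monthly_physician_revenue, physician_revenue
from .simulate import SimulationResult

__all__ = ["IntersectoralReport", "percentage_share", "pathway_revenues", "build_report"]

#: The two care pathways: (total months, quarters billed).
PATHWAYS = ((26, 9), (30, 10))


def percentage_share(numerator: float | Decimal, denominator: float | Decimal) -> float:
    """100 x numerator/denominator, rounded to one decimal."""
    denominator = float(denominator)
    if denominator == 0:
        raise ValueError("zero denominator in share computation")
    return round(100.0 * float(numerator) / denominator, 1)


def pathway_revenues(fees: Sequence[FeeItem] | None = None) -> dict[int, tuple[Decimal, Decimal]]:
    """(GP, pneumologist) course revenue per pathway, keyed by total months."""
    fees = list(fees) if fees is not None else default_fee_schedule()
    return {months: physician_revenue(quarters, fees) for months, quarters in PATHWAYS}


@dataclass(frozen=True)
class IntersectoralReport:
    outpatient_mean_total: float
    outpatient_mean_drug: float
    doctor_revenue_26: Decimal
    doctor_revenue_30: Decimal
    doctor_share_26: float
    doctor_share_30: float
    drug_share: float
    drg_payment: Decimal
    drg_vs_outpatient_share: float
    monthly_doctor_revenue_26: Decimal
    monthly_doctor_revenue_30: Decimal
    seed: int
    n_runs: int
    mode: str

    def is_self_consistent(self) -> bool:
        """Each stored share matches its own numerator/denominator to 0.1."""
        return (
            self.doctor_share_26 == percentage_share(self.doctor_revenue_26, self.outpatient_mean_total)
            and self.doctor_share_30 == percentage_share(self.doctor_revenue_30, self.outpatient_mean_total)
            and self.drug_share == percentage_share(self.outpatient_mean_drug, self.outpatient_mean_total)
            and self.drg_vs_outpatient_share == percentage_share(self.drg_payment, self.outpatient_mean_total)
        )


def build_report(
    total_result: SimulationResult,
    drug_result: SimulationResult,
    revenues: Mapping[int, tuple[Decimal, Decimal]] | None = None,
    drg_payment: Decimal | None = None,
) -> IntersectoralReport:
    """Combine the simulation stages with billing and DRG arithmetic.

    ``revenues`` maps pathway months to (GP, pneumologist) course revenue;
    defaults to the bundled fee schedule over 9 and 10 quarters.  The drug
    share is the ratio of the two Monte-Carlo means from the same run.
    """
    revenues = dict(revenues) if revenues is not None else pathway_revenues()
    drg_payment = drg_payment if drg_payment is not None else drg_case_payment(DRGParameters())
    gp26, pn26 = revenues[26]
    gp30, pn30 = revenues[30]
    doc26, doc30 = gp26 + pn26, gp30 + pn30
    total_mean = total_result.mean
    return IntersectoralReport(
        outpatient_mean_total=total_mean,
        outpatient_mean_drug=drug_result.mean,
        doctor_revenue_26=doc26,
        doctor_revenue_30=doc30,
        doctor_share_26=percentage_share(doc26, total_mean),
        doctor_share_30=percentage_share(doc30, total_mean),
        drug_share=percentage_share(drug_result.mean, total_mean),
        drg_payment=drg_payment,
        drg_vs_outpatient_share=percentage_share(drg_payment, total_mean),
        monthly_doctor_revenue_26=monthly_physician_revenue(gp26, pn26, 26),
        monthly_doctor_revenue_30=monthly_physician_revenue(gp30, pn30, 30),
        seed=total_result.seed,
        n_runs=total_result.n,
        mode=total_result.mode,
    )
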