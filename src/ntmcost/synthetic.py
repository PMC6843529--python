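"""Synthetic catalogues and option spaces for property testing.

The published catalogues are single fixed tables, so structural claims
(billing linearity, simulation/oracle agreement, weight normalization)
need inputs with controlled variation.  This module perturbs pack prices
with multiplicative log-normal noise — prices stay strictly positive
without truncation — and generates random weighted option spaces whose
cells are built by the real costing and billing engines, so every
structural invariant of a real option set holds by construction.

Generator seeds are independent of simulation seeds: data randomness and
sampling randomness never share a stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal

import numpy as np

from ._money import cents
from .catalog import (
    DrugProduct,
    IVComponent,
    Regimen,
    TreatmentOption,
    ValidationError,
    IV_COURSE_DAYS,
)
from .drugs import course_cost, regimen_daily_cost
from .monitoring import ScheduleParameters, recomputed_monitoring_total
from .catalog import default_drug_catalog, default_fee_schedule
from .options import OptionSet

__all__ = ["PerturbationSpec", "perturb_catalog", "random_option_space"]


@dataclass(frozen=True)
class PerturbationSpec:
    """Controls for the synthetic generators.

    ``price_noise_sd`` is the SD of the log-scale multiplicative price
    noise; ``weight_concentration`` the symmetric Dirichlet concentration
    over option weights (``math.inf`` means exactly uniform).
    """

    price_noise_sd: float = 0.1
    weight_concentration: float = 1.0
    n_regimens: int = 10
    durations: tuple[int, ...] = (14, 18)
    seed: int = 0

    def __post_init__(self):
        if self.price_noise_sd < 0:
            raise ValidationError("price_noise_sd must be >= 0")
        if self.weight_concentration <= 0:
            raise ValidationError("weight_concentration must be > 0")
        if self.n_regimens < 1:
            raise ValidationError("n_regimens must be >= 1")
        if not self.durations:
            raise ValidationError("durations must be non-empty")
        if any(d < 2 for d in self.durations):
            raise ValidationError("durations below 2 months cannot host a conversion")


def perturb_catalog(base: list[DrugProduct], spec: PerturbationSpec) -> list[DrugProduct]:
    """Multiply each pack price by exp(N(0, sd)); quantities unchanged."""
    rng = np.random.default_rng(spec.seed)
    factors = np.exp(rng.normal(0.0, spec.price_noise_sd, size=len(base)))
    return [
        DrugProduct(
            name=d.name,
            abbreviation=d.abbreviation,
            pack_price=cents(d.pack_price * Decimal(repr(float(f)))),
            pack_quantity=d.pack_quantity,
            daily_intake=d.daily_intake,
        )
        for d, f in zip(base, factors)
    ]


def random_option_space(spec: PerturbationSpec,
                        drugs: list[DrugProduct] | None = None) -> OptionSet:
    """Generate a weighted option space with random regimens.

    Each synthetic regimen takes a random subset of oral drugs from the
    catalogue (amikacin reserved for the IV role) and is randomly flagged
    as needing the IV block; costs run through the regular drug-costing
    and fee-line billing, weights come from a symmetric Dirichlet with the
    configured concentration, renormalized to sum to 1.
    """
    rng = np.random.default_rng(spec.seed)
    drugs = list(drugs) if drugs is not None else default_drug_catalog()
    orals = [d for d in drugs if d.abbreviation != "AMK"] or drugs
    amk = next((d for d in drugs if d.abbreviation == "AMK"), None)
    fees = default_fee_schedule()

    n_cells = spec.n_regimens * len(spec.durations)
    if math.isinf(spec.weight_concentration):
        weights = np.full(n_cells, 1.0 / n_cells)
    else:
        weights = rng.dirichlet([spec.weight_concentration] * n_cells)
        # a very small concentration can underflow a component to 0.0,
        # which a valid option weight must not be
        weights = np.clip(weights, 1e-15, None)
    weights = weights / weights.sum()

    cells: list[TreatmentOption] = []
    for i in range(spec.n_regimens):
        k = int(rng.integers(1, min(4, len(orals)) + 1))
        chosen = tuple(orals[j] for j in sorted(rng.choice(len(orals), size=k, replace=False)))
        with_iv = amk is not None and bool(rng.integers(0, 2))
        regimen = Regimen(
            label=f"SYN-{i}-" + "-".join(d.abbreviation for d in chosen),
            oral_drugs=chosen,
            category="severe" if with_iv else "macrolide_susceptible",
            iv=IVComponent(amk, IV_COURSE_DAYS) if with_iv else None,
        )
        for j, duration in enumerate(spec.durations):
            cc = course_cost(regimen, duration)
            mon = recomputed_monitoring_total(
                ScheduleParameters(treatment_months=duration, conversion_months=2,
                                   amk_given=with_iv),
                fees,
            )
            drug_cost = cents(cc.total_drug_cost)
            cells.append(
                TreatmentOption(
                    regimen_label=regimen.label,
                    category=regimen.category,
                    duration_months=duration,
                    drug_cost=drug_cost,
                    monitoring_cost=mon,
                    total_cost=cents(drug_cost + mon),
                    weight=float(weights[i * len(spec.durations) + j]),
                    daily_drug_cost=regimen_daily_cost(regimen),
                )
            )
    return OptionSet(tuple(cells), mode="recomputed")
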