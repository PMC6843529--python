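"""The weighted space of treatment options.

Ten regimens (four macrolide-susceptible, two macrolide-resistant, four
severe) crossed with two treatment durations give 20 options.  84% of the
probability mass is spread uniformly over the 8 macrolide-susceptible
cells (0.105 each), 16% over the 12 IV-amikacin cells (0.16/12 each);
durations are equiprobable within each regimen.

Two construction modes exist on purpose:

* ``as_published`` loads the bundled option table verbatim — the printed
  per-option costs, internal inconsistencies included.  This is the input
  that reproduces the published simulation summary.
* ``recomputed`` rebuilds every cell from first principles: drug-course
  costing from the price catalogue plus a monitoring total, which is the
  published course constant by default or the fee-line sum on request.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from ._money import cents
from . import drugs as drug_costing
from . import monitoring
from .catalog import (
    ConfigurationError,
    DrugProduct,
    FeeItem,
    TreatmentOption,
    ValidationError,
    WeightConfig,
    DURATIONS_MONTHS,
    build_regimens,
    default_drug_catalog,
    default_fee_schedule,
    load_published_options,
)

__all__ = ["OptionSet", "Moments", "enumerate_options", "analytic_moments"]

MODES = ("as_published", "recomputed")

#: Conversion month assumed for each duration: the 14-month course follows
#: a fast (2-month) conversion, the 18-month course a slow (6-month) one.
CONVERSION_BY_DURATION = {14: 2, 18: 6}


@dataclass(frozen=True)
class OptionSet:
    """A validated, weighted option space."""

    options: tuple[TreatmentOption, ...]
    mode: str
    weight_config: WeightConfig | None = None

    def __post_init__(self):
        if not self.options:
            raise ValidationError("option set is empty")
        total = math.fsum(o.weight for o in self.options)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"option weights sum to {total!r}, expected 1")
        if self.mode == "recomputed":
            broken = [o.regimen_label for o in self.options if not o.is_additive()]
            if broken:
                raise ValidationError(f"non-additive recomputed option(s): {broken}")
        if self.weight_config is not None:
            expected = (self.weight_config.n_susceptible_options
                        + self.weight_config.n_amk_options)
            if len(self.options) != expected:
                raise ValidationError(
                    f"expected {expected} options, got {len(self.options)}")

    def __len__(self) -> int:
        return len(self.options)

    def __iter__(self):
        return iter(self.options)

    def values(self, field: str = "total_cost") -> list[float]:
        return [float(getattr(o, field)) for o in self.options]

    def weights(self) -> list[float]:
        return [o.weight for o in self.options]


@dataclass(frozen=True)
class Moments:
    """Exact moments of the discrete cost distribution (the simulation oracle)."""

    mean: float
    variance: float
    minimum: float
    maximum: float

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


def enumerate_options(
    drugs: Sequence[DrugProduct] | None = None,
    fees: Sequence[FeeItem] | None = None,
    weights: WeightConfig | None = None,
    mode: str = "as_published",
    monitoring_totals: str | None = None,
    convention: str = "rounded_components",
    durations: Sequence[int] = DURATIONS_MONTHS,
) -> OptionSet:
    """Build the 20-option space.

    ``monitoring_totals`` selects where recomputed cells take their
    monitoring component: ``"published"`` (course constants, the default)
    or ``"recomputed"`` (fee-line sums).  Ignored in as-published mode.
    """
    if mode not in MODES:
        raise ConfigurationError(f"unknown option mode {mode!r}")
    weights = weights or WeightConfig()
    if mode == "as_published":
        return OptionSet(tuple(load_published_options(weights=weights)), mode, weights)

    monitoring_totals = monitoring_totals or "published"
    if monitoring_totals not in ("published", "recomputed"):
        raise ConfigurationError(f"unknown monitoring_totals {monitoring_totals!r}")
    drugs = list(drugs) if drugs is not None else default_drug_catalog()
    fees = list(fees) if fees is not None else default_fee_schedule()

    cells: list[TreatmentOption] = []
    for regimen in build_regimens(drugs):
        amk = regimen.iv is not None
        w = weights.amk_weight if amk else weights.susceptible_weight
        for duration in durations:
            cc = drug_costing.course_cost(regimen, duration, convention=convention)
            if monitoring_totals == "published":
                mon = monitoring.published_monitoring_total(duration, amk)
            else:
                params = monitoring.ScheduleParameters(
                    treatment_months=duration,
                    conversion_months=CONVERSION_BY_DURATION.get(duration, 2),
                    amk_given=amk,
                )
                mon = monitoring.recomputed_monitoring_total(params, fees)
            drug_cost = cents(cc.total_drug_cost)
            cells.append(
                TreatmentOption(
                    regimen_label=regimen.label,
                    category=regimen.category,
                    duration_months=duration,
                    drug_cost=drug_cost,
                    monitoring_cost=mon,
                    total_cost=cents(drug_cost + mon),
                    weight=w,
                    daily_drug_cost=drug_costing.regimen_daily_cost(regimen, convention),
                )
            )
    return OptionSet(tuple(cells), mode, weights)


def analytic_moments(options: OptionSet, field: str = "total_cost") -> Moments:
    """Exact weighted moments of an option set.

    The Monte-Carlo sampler must converge to these; they serve as the
    closed-form oracle for every simulation result.
    """
    if len(options) == 0:
        raise ValueError("empty option set")
    values = options.values(field)
    weights = options.weights()
    mean = math.fsum(w * v for w, v in zip(weights, values))
    second = math.fsum(w * v * v for w, v in zip(weights, values))
    return Moments(mean=mean, variance=max(second - mean * mean, 0.0),
                   minimum=min(values), maximum=max(values))
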