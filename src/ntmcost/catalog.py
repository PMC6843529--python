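"""Domain data model and catalogue I/O.

The whole analysis runs off four small published catalogues: a drug price
list (pack price, pack quantity, daily intake), the statutory outpatient
fee schedule (EBM/GOP items with unit prices and frequency rules), the
20-cell table of weighted treatment options, and the G-DRG parameters for
the NTM hospital group (E76C).  This module defines the record types,
reads/writes the delimited catalogue files, and exposes the bundled
as-published fixtures.

File dialect: comma-delimited with a header row, UTF-8, ``"."`` decimal
separator.  Euro signs and thousands separators are stripped on read, so
published figures like ``"€10,551.6"`` parse unambiguously.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass, field
from decimal import Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._money import cents, parse_eur

__all__ = [
    "CatalogError",
    "SchemaError",
    "CatalogParseError",
    "ValidationError",
    "ConfigurationError",
    "DrugProduct",
    "IVComponent",
    "Regimen",
    "FeeItem",
    "DRGParameters",
    "WeightConfig",
    "TreatmentOption",
    "FREQUENCY_ROLES",
    "PAYER_GROUPS",
    "CATEGORIES",
    "REGIMEN_DEFS",
    "PUBLISHED_MONITORING_TOTALS",
    "IV_COURSE_DAYS",
    "DURATIONS_MONTHS",
    "load_drug_catalog",
    "load_fee_schedule",
    "load_published_options",
    "build_regimens",
    "default_drug_catalog",
    "default_fee_schedule",
    "published_options_path",
    "write_report",
    "read_report",
    "write_option_set_csv",
]


class CatalogError(Exception):
    """Base class for catalogue and configuration problems."""


class SchemaError(CatalogError):
    """A file is missing a column, or a record violates a structural rule."""


class CatalogParseError(CatalogError):
    """A field could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message} (line {line})" if line else message)


class ValidationError(CatalogError):
    """A loaded catalogue violates a numeric invariant (e.g. weight sum)."""


class ConfigurationError(CatalogError):
    """Inconsistent run configuration (unknown mode, unmatched counter...)."""


# ---------------------------------------------------------------------------
# record types

@dataclass(frozen=True)
class DrugProduct:
    """One purchasable pack from the retail price catalogue.

    ``daily_intake`` is the number of pack units taken per day under the
    dosing instructions (e.g. 2 x 1 tablets -> 2).
    """

    name: str
    abbreviation: str
    pack_price: Decimal
    pack_quantity: int
    daily_intake: int

    def __post_init__(self):
        if self.pack_price < 0:
            raise ValidationError(f"{self.abbreviation}: negative pack price")
        if self.pack_quantity <= 0:
            raise ValidationError(f"{self.abbreviation}: pack_quantity must be > 0")
        if self.daily_intake <= 0:
            raise ValidationError(f"{self.abbreviation}: daily_intake must be > 0")


@dataclass(frozen=True)
class IVComponent:
    """An intravenous add-on (amikacin), given for a fixed number of days."""

    drug: DrugProduct
    course_days: int = 60

    def __post_init__(self):
        if self.course_days < 0:
            raise ValidationError("IV course_days must be >= 0")


CATEGORIES = ("macrolide_susceptible", "macrolide_resistant", "severe")


@dataclass(frozen=True)
class Regimen:
    """A drug combination: daily oral drugs plus an optional IV component."""

    label: str
    oral_drugs: tuple[DrugProduct, ...]
    category: str
    iv: IVComponent | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown regimen category {self.category!r}")
        if self.category == "macrolide_susceptible" and self.iv is not None:
            raise ValidationError(f"{self.label}: macrolide-susceptible regimens carry no IV")
        if self.category != "macrolide_susceptible" and self.iv is None:
            raise ValidationError(f"{self.label}: {self.category} regimens require an IV component")


FREQUENCY_ROLES = (
    "per_quarter_gp",
    "per_quarter_pneumo",
    "once",
    "per_sputum_sample",
    "per_xray",
    "per_ophtha_visit",
    "per_ct",
    "per_lab_visit",
    "per_audiometry",
    "per_amk_level",
    "zero_billable",
)

PAYER_GROUPS = (
    "general_practitioner",
    "pneumologist",
    "methods",
    "microbiology",
    "laboratory",
)


@dataclass(frozen=True)
class FeeItem:
    """One outpatient fee-schedule line (GOP/EBM code).

    ``frequency_role`` ties the line to exactly one event counter of the
    monitoring schedule; ``zero_billable`` lines (ECG) are performed but
    cannot be charged separately and always bill 0.00.
    """

    service_name: str
    code: str
    unit_price: Decimal
    frequency_role: str
    payer_group: str
    points: int | None = None

    def __post_init__(self):
        if self.unit_price < 0:
            raise ValidationError(f"{self.code}: negative unit price")
        if self.frequency_role not in FREQUENCY_ROLES:
            raise SchemaError(f"{self.code}: unknown frequency_role {self.frequency_role!r}")
        if self.payer_group not in PAYER_GROUPS:
            raise SchemaError(f"{self.code}: unknown payer_group {self.payer_group!r}")


@dataclass(frozen=True)
class DRGParameters:
    """Parameters of the hospital payment group (defaults: G-DRG E76C, 2019)."""

    base_rate: Decimal = Decimal("3544.97")
    cost_weight: Decimal = Decimal("0.937")
    mean_length_of_stay: Decimal = Decimal("6.4")
    cap_days: int = 14

    def __post_init__(self):
        for name in ("base_rate", "cost_weight", "mean_length_of_stay", "cap_days"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"DRG parameter {name} must be strictly positive")


@dataclass(frozen=True)
class WeightConfig:
    """Probability mass split between the no-amikacin and amikacin blocks.

    84% of patients are assumed treatable without IV amikacin (macrolide
    susceptibility rate from the literature); that mass is spread uniformly
    over the 8 macrolide-susceptible regimen x duration cells, the
    remaining 16% over the 12 amikacin cells.
    """

    p_no_amk: float = 0.84
    p_amk: float = 0.16
    n_susceptible_options: int = 8
    n_amk_options: int = 12

    def __post_init__(self):
        if abs(self.p_no_amk + self.p_amk - 1.0) > 1e-12:
            raise ValidationError("block probabilities must sum to 1")
        if min(self.p_no_amk, self.p_amk) <= 0:
            raise ValidationError("block probabilities must be positive")
        if self.n_susceptible_options < 1 or self.n_amk_options < 1:
            raise ValidationError("option counts must be >= 1")

    @property
    def susceptible_weight(self) -> float:
        return self.p_no_amk / self.n_susceptible_options

    @property
    def amk_weight(self) -> float:
        return self.p_amk / self.n_amk_options


@dataclass(frozen=True)
class TreatmentOption:
    """One regimen x duration cell of the option table with its weight."""

    regimen_label: str
    category: str
    duration_months: int
    drug_cost: Decimal
    monitoring_cost: Decimal
    total_cost: Decimal
    weight: float
    daily_drug_cost: Decimal | None = None

    def __post_init__(self):
        if not 0 < self.weight <= 1:
            raise ValidationError(f"{self.regimen_label}/{self.duration_months}: weight out of (0, 1]")
        for name in ("drug_cost", "monitoring_cost", "total_cost"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.regimen_label}: negative {name}")

    @property
    def uses_amk(self) -> bool:
        return self.category != "macrolide_susceptible"

    def is_additive(self) -> bool:
        """Whether total = drug + monitoring to the cent.

        True for every recomputed option.  The as-published table contains
        two non-additive cells (digit transpositions in the printed
        figures), which the fixture preserves verbatim.
        """
        return cents(self.drug_cost + self.monitoring_cost) == cents(self.total_cost)


# ---------------------------------------------------------------------------
# published constants

#: Published diagnostics/monitoring course totals, keyed (duration_months,
#: amk_given).  These are the constants the option table adds to drug costs;
#: summing the individual fee lines instead gives slightly different figures
#: (see monitoring.recompute note in docs).
PUBLISHED_MONITORING_TOTALS: Mapping[tuple[int, bool], Decimal] = {
    (14, False): Decimal("2162.47"),
    (18, False): Decimal("2895.75"),
    (14, True): Decimal("2263.30"),
    (18, True): Decimal("2996.58"),
}

#: IV amikacin course length in the base case ("at least eight weeks",
#: modelled as 60 days as in the option table).
IV_COURSE_DAYS = 60

#: The two modelled treatment durations (12 months past culture conversion
#: at 2 or 6 months), equiprobable.
DURATIONS_MONTHS = (14, 18)

#: The ten modelled regimens: label as printed in the option table, oral
#: drug abbreviations, category.  Labels are kept verbatim, including the
#: table's spelling variants (AMX for the IV amikacin suffix, ATZ/ATM for
#: azithromycin); the oral components are resolved to catalogue drugs.
REGIMEN_DEFS: tuple[tuple[str, tuple[str, ...], str], ...] = (
    ("R-E-CLAM", ("R", "E", "CLAM"), "macrolide_susceptible"),
    ("RBT-E-CLAM", ("RBT", "E", "CLAM"), "macrolide_susceptible"),
    ("R-E-AZM", ("R", "E", "AZM"), "macrolide_susceptible"),
    ("RBT-E-AZM", ("RBT", "E", "AZM"), "macrolide_susceptible"),
    ("R-E-CLO-AMK", ("R", "E", "CLO"), "macrolide_resistant"),
    ("R-E-MOX-AMK", ("R", "E", "MOX"), "macrolide_resistant"),
    ("R-E-CLAM-AMX", ("R", "E", "CLAM"), "severe"),
    ("RBT-E-CLAM-AMX", ("RBT", "E", "CLAM"), "severe"),
    ("R-E-ATZ-AMX", ("R", "E", "AZM"), "severe"),
    ("RBT-E-ATM-AMX", ("RBT", "E", "AZM"), "severe"),
)


# ---------------------------------------------------------------------------
# loaders

def _data_path(name: str) -> Path:
    return Path(str(resources.files("ntmcost").joinpath("data", name)))


def published_options_path() -> Path:
    """Path of the bundled as-published option table fixture."""
    return _data_path("options_published.csv")


def _reader(path: str | Path, required: Sequence[str]) -> Iterable[tuple[int, dict]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise SchemaError(f"{path.name}: missing column(s) {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            yield lineno, row


def _parse_price(raw: str, *, path_name: str, lineno: int, column: str) -> Decimal:
    try:
        return parse_eur(raw)
    except ValueError as exc:
        raise CatalogParseError(f"{path_name}: non-numeric {column} {raw!r}", line=lineno) from exc


def load_drug_catalog(path: str | Path) -> list[DrugProduct]:
    """Read a drug price catalogue; abbreviations must be unique."""
    path = Path(path)
    products: list[DrugProduct] = []
    seen: set[str] = set()
    required = ("name", "abbreviation", "pack_price", "pack_quantity", "daily_intake")
    for lineno, row in _reader(path, required):
        abbrev = row["abbreviation"].strip()
        if abbrev in seen:
            raise SchemaError(f"{path.name}: duplicated abbreviation {abbrev!r}")
        seen.add(abbrev)
        price = _parse_price(row["pack_price"], path_name=path.name, lineno=lineno, column="pack_price")
        try:
            quantity = int(row["pack_quantity"])
            intake = int(row["daily_intake"])
        except ValueError as exc:
            raise CatalogParseError(f"{path.name}: non-integer quantity/intake", line=lineno) from exc
        products.append(DrugProduct(row["name"].strip(), abbrev, price, quantity, intake))
    return products


def load_fee_schedule(path: str | Path) -> list[FeeItem]:
    """Read an outpatient fee schedule; every row must carry a known role."""
    path = Path(path)
    items: list[FeeItem] = []
    required = ("service_name", "code", "points", "unit_price", "frequency_role", "payer_group")
    for lineno, row in _reader(path, required):
        price = _parse_price(row["unit_price"], path_name=path.name, lineno=lineno, column="unit_price")
        if price < 0:
            raise CatalogParseError(f"{path.name}: negative unit_price", line=lineno)
        points_raw = (row["points"] or "").strip()
        points = int(points_raw) if points_raw else None
        items.append(
            FeeItem(
                service_name=row["service_name"].strip(),
                code=row["code"].strip(),
                unit_price=price,
                frequency_role=row["frequency_role"].strip(),
                payer_group=row["payer_group"].strip(),
                points=points,
            )
        )
    return items


def load_published_options(
    path: str | Path | None = None,
    weights: WeightConfig | None = None,
) -> list[TreatmentOption]:
    """Read the as-published 20-option table and attach block weights.

    The printed cells are preserved verbatim, internal inconsistencies
    included; weight assignment follows the table's block annotations
    (0.84/8 per macrolide-susceptible cell, 0.16/12 per amikacin cell).
    Raises :class:`ValidationError` if the weights do not sum to 1.
    """
    path = Path(path) if path is not None else published_options_path()
    weights = weights or WeightConfig()
    options: list[TreatmentOption] = []
    required = ("regimen_label", "category", "duration_months", "daily_drug_cost",
                "drug_cost", "monitoring_cost", "total_cost")
    for lineno, row in _reader(path, required):
        category = row["category"].strip()
        if category not in CATEGORIES:
            raise SchemaError(f"{path.name}: unknown category {category!r} (line {lineno})")
        weight = (weights.susceptible_weight if category == "macrolide_susceptible"
                  else weights.amk_weight)
        options.append(
            TreatmentOption(
                regimen_label=row["regimen_label"].strip(),
                category=category,
                duration_months=int(row["duration_months"]),
                daily_drug_cost=_parse_price(row["daily_drug_cost"], path_name=path.name,
                                             lineno=lineno, column="daily_drug_cost"),
                drug_cost=_parse_price(row["drug_cost"], path_name=path.name,
                                       lineno=lineno, column="drug_cost"),
                monitoring_cost=_parse_price(row["monitoring_cost"], path_name=path.name,
                                             lineno=lineno, column="monitoring_cost"),
                total_cost=_parse_price(row["total_cost"], path_name=path.name,
                                        lineno=lineno, column="total_cost"),
                weight=weight,
            )
        )
    total_weight = math.fsum(o.weight for o in options)
    if abs(total_weight - 1.0) > 1e-9:
        raise ValidationError(f"option weights sum to {total_weight!r}, expected 1")
    return options


def build_regimens(drugs: Sequence[DrugProduct],
                   iv_course_days: int = IV_COURSE_DAYS) -> list[Regimen]:
    """Materialize the ten modelled regimens against a drug catalogue."""
    by_abbrev = {d.abbreviation: d for d in drugs}
    missing = {a for _, abbrevs, _ in REGIMEN_DEFS for a in abbrevs if a not in by_abbrev}
    if missing or "AMK" not in by_abbrev:
        missing |= {"AMK"} - set(by_abbrev)
        raise ConfigurationError(f"drug catalogue lacks {sorted(missing)}")
    amk = by_abbrev["AMK"]
    regimens = []
    for label, abbrevs, category in REGIMEN_DEFS:
        iv = None if category == "macrolide_susceptible" else IVComponent(amk, iv_course_days)
        regimens.append(
            Regimen(label, tuple(by_abbrev[a] for a in abbrevs), category, iv)
        )
    return regimens


def default_drug_catalog() -> list[DrugProduct]:
    """The bundled as-published drug price catalogue."""
    return load_drug_catalog(_data_path("drugs.csv"))


def default_fee_schedule() -> list[FeeItem]:
    """The bundled as-published outpatient fee schedule."""
    return load_fee_schedule(_data_path("fees.csv"))


# ---------------------------------------------------------------------------
# report serialization

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Decimal):
        return str(obj)
    if isinstance(obj, float):
        if math.isnan(obj) or math.isinf(obj):
            raise ValidationError("refusing to serialize a non-finite value")
        return obj
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(result, path: str | Path, format: str = "json") -> None:
    """Serialize a result object (dataclass or mapping) to disk.

    ``json`` writes a structured-text document; ``csv`` writes one
    key,value line per scalar field.  Round-trips losslessly to the cent;
    non-finite numbers are rejected rather than silently written.
    """
    path = Path(path)
    payload = _jsonable(result)
    if format == "json":
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    elif format == "csv":
        if not isinstance(payload, dict):
            raise ConfigurationError("csv report format requires a mapping-like result")
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["field", "value"])
            for key, value in payload.items():
                writer.writerow([key, value])
    else:
        raise ConfigurationError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "json") -> dict:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    if format == "json":
        return json.loads(path.read_text(encoding="utf-8"))
    if format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            return {row["field"]: row["value"] for row in reader}
    raise ConfigurationError(f"unknown report format {format!r}")


def write_option_set_csv(options: Sequence[TreatmentOption], path: str | Path) -> None:
    """Write an option list in the same dialect as the bundled fixture."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["regimen_label", "category", "duration_months", "daily_drug_cost",
                         "drug_cost", "monitoring_cost", "total_cost", "weight"])
        for o in options:
            writer.writerow([
                o.regimen_label, o.category, o.duration_months,
                "" if o.daily_drug_cost is None else f"{o.daily_drug_cost:.2f}",
                f"{o.drug_cost:.2f}", f"{o.monitoring_cost:.2f}", f"{o.total_cost:.2f}",
                repr(o.weight),
            ])
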