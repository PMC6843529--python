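"""The 20-option space and its exact moments."""

import csv
import math
import random
from decimal import Decimal
from fractions import Fraction

import pytest

from ntmcost.catalog import (
    ConfigurationError,
    DrugProduct,
    TreatmentOption,
    published_options_path,
)
from ntmcost.options import OptionSet, analytic_moments, enumerate_options


def weighted_mean_oracle(column: str) -> Fraction:
    """Exact weighted mean over the published table, by brute enumeration.

    Independent of the package's option/moment code: reads the fixture
    with the stdlib csv module and does all arithmetic in Fractions with
    the block weights 84/100/8 and 16/100/12.
    """
    w_susceptible = Fraction(84, 100) / 8
    w_amk = Fraction(16, 100) / 12
    total = Fraction(0)
    with open(published_options_path(), newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            w = w_susceptible if row["category"] == "macrolide_susceptible" else w_amk
            total += w * Fraction(row[column])
    return total


class TestAsPublished:
    def test_extremes_match_summary_table(self, published_options):
        m = analytic_moments(published_options)
        assert m.minimum == 4644.67
        assert m.maximum == 15806.78

    def test_weighted_mean_total_against_brute_force(self, published_options):
        oracle = weighted_mean_oracle("total_cost")
        assert round(float(oracle), 2) == 8715.80
        m = analytic_moments(published_options)
        assert m.mean == pytest.approx(float(oracle), abs=1e-6)

    def test_weighted_mean_drug_against_brute_force(self, published_options):
        oracle = weighted_mean_oracle("drug_cost")
        assert round(float(oracle), 2) == 6170.01
        m = analytic_moments(published_options, field="drug_cost")
        assert m.mean == pytest.approx(float(oracle), abs=1e-6)

    def test_daily_rate_times_days_reproduces_most_published_cells(self, published_options):
        """Printed course cells equal daily rate x 420/540 days (+ IV block),
        except the two cells where the source table disagrees with its own
        daily column."""
        known_breaks = {("R-E-MOX-AMK", 18), ("RBT-E-ATM-AMX", 18)}
        for o in published_options:
            days = o.duration_months * 30
            iv = Decimal("4284.00") if o.uses_amk else Decimal("0.00")
            implied = o.daily_drug_cost * days + iv
            if (o.regimen_label, o.duration_months) in known_breaks:
                assert implied != o.drug_cost
            else:
                assert implied == o.drug_cost


class TestRecomputed:
    def test_agrees_with_published_where_daily_rates_agree(self, published_options):
        """Rows whose daily rate survives recomputation match the printed
        table to the cent when the published monitoring constants are used."""
        recomputed = {(o.regimen_label, o.duration_months): o
                      for o in enumerate_options(mode="recomputed")}
        published = {(o.regimen_label, o.duration_months): o for o in published_options}
        agreeing = [
            ("R-E-CLAM", 14), ("R-E-CLAM", 18),
            ("R-E-AZM", 18),            # the 14-month total is misprinted (5287.87 vs 5278.87)
            ("R-E-CLO-AMK", 14), ("R-E-CLO-AMK", 18),
            ("R-E-CLAM-AMX", 14), ("R-E-CLAM-AMX", 18),
            ("R-E-ATZ-AMX", 14), ("R-E-ATZ-AMX", 18),
        ]
        for key in agreeing:
            assert recomputed[key].total_cost == published[key].total_cost
        # the misprinted cell still matches on the drug-cost column
        assert recomputed[("R-E-AZM", 14)].drug_cost == published[("R-E-AZM", 14)].drug_cost

    def test_zero_prices_leave_only_monitoring(self, drug_catalog):
        free = [DrugProduct(d.name, d.abbreviation, Decimal("0"), d.pack_quantity,
                            d.daily_intake) for d in drug_catalog]
        opts = enumerate_options(drugs=free, mode="recomputed")
        for o in opts:
            assert o.drug_cost == Decimal("0.00")
            assert o.total_cost == o.monitoring_cost

    def test_recomputed_options_are_additive(self):
        assert all(o.is_additive() for o in enumerate_options(mode="recomputed"))

    def test_fee_line_monitoring_variant(self):
        opts = enumerate_options(mode="recomputed", monitoring_totals="recomputed")
        by_key = {(o.regimen_label, o.duration_months): o for o in opts}
        assert by_key[("R-E-CLAM", 14)].monitoring_cost == Decimal("2389.29")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            enumerate_options(mode="imagined")


class TestMoments:
    def test_single_option_degenerate(self):
        opt = TreatmentOption("X", "macrolide_susceptible", 14,
                              Decimal("10"), Decimal("5"), Decimal("15"), 1.0)
        m = analytic_moments(OptionSet((opt,), "recomputed"))
        assert (m.mean, m.variance) == (15.0, 0.0)

    def test_mean_invariant_under_permutation(self, published_options):
        shuffled = list(published_options)
        random.Random(0).shuffle(shuffled)
        m1 = analytic_moments(published_options)
        m2 = analytic_moments(OptionSet(tuple(shuffled), "as_published"))
        assert m2.mean == pytest.approx(m1.mean, abs=1e-9)
        assert m2.variance == pytest.approx(m1.variance, rel=1e-12)

    def test_mean_invariant_under_half_weight_split(self, published_options):
        import dataclasses
        first, *rest = list(published_options)
        halves = [dataclasses.replace(first, weight=first.weight / 2) for _ in range(2)]
        split = OptionSet(tuple(halves + rest), "as_published")
        assert analytic_moments(split).mean == pytest.approx(
            analytic_moments(published_options).mean, abs=1e-9)

    def test_weight_sum_enforced(self, published_options):
        import dataclasses
        bad = [dataclasses.replace(o, weight=o.weight * 0.5) for o in published_options]
        with pytest.raises(Exception, match="sum"):
            OptionSet(tuple(bad), "as_published")

    def test_weights_sum_exactly_blockwise(self):
        # 8 x 0.84/8 + 12 x 0.16/12 = 1
        assert math.fsum([0.84 / 8] * 8 + [0.16 / 12] * 12) == pytest.approx(1.0, abs=1e-12)
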