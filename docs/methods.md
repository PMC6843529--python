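# Methods

## Model

The package computes the direct medical cost of guideline-based care for
pulmonary *Mycobacterium avium* complex disease (MAC-PD) as borne by
German statutory health insurance, separately for the outpatient and the
hospital sector, at 2019 prices. It is a deterministic costing model with
a single stochastic layer: uncertainty about which treatment option a
patient receives.

### Treatment options and weights

Ten regimens are modelled: four macrolide-susceptible combinations
(rifampicin or rifabutin + ethambutol + clarithromycin or azithromycin,
oral only), two macrolide-resistant ones (clofazimine or moxifloxacin
replacing the macrolide) and four severe-disease ones (the susceptible
combinations again), the latter six each adding a 60-day IV amikacin
block. Crossed with the two treatment durations — 14 months after
culture conversion at 2 months, 18 months after conversion at 6 months,
treated as equiprobable — this yields 20 options. Based on literature
rates of macrolide resistance/cavitary disease of roughly 16%, a
probability of 0.84 is spread uniformly over the 8 susceptible cells
(0.105 each) and 0.16 over the 12 amikacin cells (0.16/12 each). The
option labels are kept exactly as printed in the source table, including
its spelling variants (the `-AMX` suffix for the IV block, `ATZ`/`ATM`
for azithromycin).

### Drug costing

Per-day drug cost = pack price ÷ pack quantity × daily intake, rounded
half-up to the cent. A regimen's daily rate is the sum of its components'
*already rounded* per-day costs (`rounded_components`); the alternative
of rounding the exact sum once (`round_sum`) is available because the
published daily-rate column is internally split between the two — it
prints the round-sum value for RBT-E-CLAM (14.08) but the
rounded-components value for R-E-AZM (7.42). Courses use 30-day months
(14 months ≡ 420 days), the only convention consistent with the
published course cells (5.91 × 420 = 2482.20). The IV block is priced
separately (71.40/day × 60 days = 4284.00) and does not scale with
treatment duration.

### Monitoring schedule and billing

Event counts are deterministic functions of four parameters (treatment
months, 12 post-treatment months, conversion month, amikacin flag):

| counter | rule | 14 mo/fast | 18 mo/slow |
|---|---|---|---|
| sputum microscopy+culture sets | 3 baseline + monthly until conversion + 8 | 13 | 17 |
| blood-work visits | biweekly for 2 months (4) + monthly thereafter | 16 | 20 |
| ophthalmology | monthly under ethambutol | 14 | 18 |
| CT (with contrast) | baseline + every 6 months | 3 | 4 |
| X-rays | see below | 11 | 15 |
| ECG | weeks 0/2/12/24, never separately billable | 4 | 4 |
| physician quarters | ⌈(treatment + 12)/3⌉ | 9 | 10 |
| audiometry / amikacin levels | 3 each, only with IV amikacin | 0 | 0 |

X-rays follow the stated rule (baseline, weeks 4 and 8, months 4 and 6,
every 3 months thereafter including an end-of-treatment film, plus 6, 12
and 24 months post-treatment) for the 14-month fast-conversion course,
where it reproduces the published 11; the longer/slow-conversion count
is the published 15 applied as a configured override, because the
placement of the extra films is not derivable from the rule.

Each fee line bills unit price × count and aggregates by payer group.
Quarterly physician revenue is flat: the GP items sum to €57.46/quarter
(9 quarters → €517.14), the pneumologist items to €27.17/quarter plus
once-off bronchoscopy and lavage (€133.12) → €377.65. Following the
published convention, monthly revenue divides by 26 or 30 months (not
the 27/30 a quarter count would imply), giving €34.42 and €32.65.

Two monitoring course totals coexist deliberately. The published
constants (2162.47/2895.75 without amikacin; +100.83 = 3 × 15.91 +
3 × 17.70 with it) are what the option table adds to drug costs and are
the default in option costing. The transparent fee-line sums are
2389.29 and 2895.35 — the source never reconciles the 14-month gap of
226.82 (≈ one ophthalmology course) — and are available via
`monitoring_totals="recomputed"`. The 18-month blood-count line is
billed at the printed 22.20 (20 × 1.10 = 22.00) by a per-line override,
removable with `use_published_line_totals=False`.

### Simulation

The "random walk" over options is categorical sampling with the option
weights, 10,000 draws per stage, using numpy's PCG64 generator with
explicit integer seeding; the two stages (drug costs, then total costs)
run on independent sub-streams spawned from one seed. Summaries use the
sample SD with the n−1 denominator and a fixed z = 1.96 normal interval,
matching the published interval identity (upper − mean = 1.96·s/√n).
Exact weighted moments (`analytic_moments`) serve as the oracle: over
the as-published table the expectations are €8715.80 (totals) and
€6170.01 (drug costs), with 3·σ/√n ≈ €90 at n = 10,000. The published
means (8675.22, 6130.25) are single Monte-Carlo realizations inside that
band; since no seed was published, agreement is assessed within sampling
error, not bit-for-bit.

### Hospital side

The NTM hospital group (E76C) pays base rate × cost weight =
3544.97 × 0.937 = €3321.64 flat for any stay up to 14 days; the grouper
that assigns cases to the group is out of scope and its published
parameters are plain configuration. Per-bed-day rate: the unrounded
case payment ÷ 6.4 days mean stay = €519.0 at display precision (one
decimal), €519.01 at cent precision.

### Intersectoral shares

Shares are computed from unrounded cent-level values and rounded once to
one decimal: at the published outpatient mean, doctor revenue is 10.3%
(26 months) / 11.3% (30 months), drugs 70.7%, and the hospital case
payment 38.3% of the whole outpatient pathway.

## Fidelity to the source, and its inconsistencies

The `as_published` option fixture preserves the printed table verbatim,
including three defects the recomputation exposes:

* Two cells are non-additive (drug + monitoring ≠ total): R-E-AZM at
  14 months (5287.87 printed vs 5278.87 implied) and RBT-E-ATM-AMX at
  18 months (15,806.78 printed vs 15,836.78 implied) — both look like
  digit transpositions. Option additivity is therefore enforced as an
  invariant only in recomputed mode.
* The RBT-E-AZM daily rate prints 19.54 while its components sum to
  15.58; two 18-month course cells disagree with their own daily rates
  (8556.2 vs 7.93 × 540 + 4284 = 8566.2; 12,840.2 vs 19.54 × 540 + 4284
  = 14,835.6).

Because the published summary statistics are computed over the printed
cells, reproducing them requires the verbatim fixture; honest modelling
requires the recomputed path. Both are exported, and the tests pin the
exact set of cells on which they disagree.

## Synthetic data generator

`ntmcost.synthetic` exists so structural claims are not tested on a
single fixed table. It perturbs pack prices with multiplicative
log-normal noise (sd 0.1 by default — a plausible scale for retail price
revisions; positivity holds without truncation) and generates random
weighted option spaces: random oral-drug subsets, a random IV flag,
symmetric-Dirichlet weights (concentration 1.0 by default), with costs
built by the real costing and billing engines so every invariant of a
real option set holds by construction. Generator seeds are independent
of simulation seeds. What it emulates is the *statistical structure* of
the option space — weighted discrete costs with realistic magnitudes —
not the German drug market: passing tests show the pipeline is correct
for any catalogue shaped like the published one, not that the published
prices themselves are current.

## Numerical choices

Currency is `decimal.Decimal` end to end, rounded half-up at defined
boundaries (per-day rate, invoice line, course total); floats appear
only in weights and Monte-Carlo draws, which are never accumulated back
into billing. Weight sums are validated to 1 within 1e-9. Degenerate
inputs fail loudly: empty regimens, zero pack quantities, negative
durations, conversion after treatment end, empty draw vectors, and
schedules with unbilled active counters all raise typed errors.

## Problem sizes

Every computation is desk-scale: 20 options, ≤ 36 fee lines, 10,000
draws per simulation stage. The full test suite (161 tests, including
50 simulated synthetic spaces at n = 10,000) runs in a few seconds; the
acceptance script in well under a second per seed.

## Known limitations

No patient-level heterogeneity, adherence, or resistance dynamics; no
calendar placement of visits (only counts are billable); no drug
discount agreements or currency conversion; no time discounting over the
26–30-month pathway; the DRG grouper's internal logic (secondary
diagnoses, surgical groups, outlier surcharges) is not modelled beyond
the flat E76C parameters. The weights 0.84/0.16 are literature-informed
assumptions, not observed prescribing frequencies.
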