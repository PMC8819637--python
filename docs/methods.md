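# Methods

`prepcost` implements a provider-perspective, ingredients-based (bottom-up)
costing of PrEP delivery through community-based HIV counselling and
testing (CBCT) platforms, following standard reference-case practice for
global-health costing.  This note records the model, its assumptions, the
calibration of the synthetic-data generators, and the numerical and design
choices made where the design was genuinely open.

## Costing model

**Unit of output.** The denominator is the person-month of PrEP: one month
of medication dispensed to one client.  Cost per person-month is total
annual cost divided by person-months dispensed over the costing year
(1 Nov 2018 – 1 Nov 2019).

**Fixed vs variable.** Six categories are fixed (volume-independent):
capital, training, demand creation, supervisory personnel, site overheads
and admin/monitoring supplies.  The remainder are variable:
service-delivery staff time, PrEP medication, miscellaneous consumables and
four laboratory tests (HIV serology, HBsAg, creatinine, pregnancy; syphilis
is carried as a category but costs zero in every built-in scenario since it
never appears in the program accounts).  Fixed categories are taken from
the expenditure ledger as given — their totals are accounting facts, and
the package does not pretend to re-derive them from first principles.
Site-level fixed costs are attributed in full to each service model,
because the costing question is counterfactual: what would the program cost
if run entirely under that model.

**Personnel.** Per-minute staff cost is annual salary (including
allowances) divided by 2080 paid hours (260 days × 8 h) and by 60.  Annual
variable personnel cost is Σ over (visit type, role) of mean active minutes
× per-minute cost × event count.  Club group-counselling cells are charged
once per group session, ⌈clients / 7⌉ sessions.  Reminder calls/texts
(2 social-worker minutes per participant-visit) are a distinct visit type
charged in all arms.  Standard care has no counsellor cadre of its own; its
residual social-worker minutes are priced at the individual-counsellor
salary, the cheaper of the two counsellor cadres.

**Capital.** Annuity-factor annualization, `price · r / (1 − (1+r)^−L)`,
with r = 3 % (supported range 0–5 %) and L = 3 years for all items.  At
r = 0 the formula degenerates to straight-line `price / L`; the
implementation handles that limit explicitly and the annuity identity
(discounted payments sum back to the price) is enforced by test.

**Overheads.** Allocated proportionally: site overhead × (PrEP client
activities / all site client activities).  The fraction is an input; the
package validates it to [0, 1].

**Tests and drug.** Test cost = unit cost × events, with events implied by
the visit log: once per initiation where required, plus once per quarterly
refill visit for tests with a ≤3-month periodicity (blood draws happen at
quarterly visits).  Drug cost = per-month supply cost × person-months.
Under the public-sector scenarios creatinine is excluded (not essential for
this age group) and pregnancy testing occurs at no cost to the PrEP program
(via family planning), so both render as excluded categories.

**Recorded vs computed variable costs.** For each variable category a
scenario may carry a recorded expenditure total; the record then takes
precedence over the ingredient computation.  The built-in scenario specs
carry the program's recorded totals, so they reproduce the published cost
columns to the cent; with `use_recorded_variable=False` every variable
category is recomputed bottom-up.  The ingredient path reproduces recorded
public-sector medication and test costs within 1 % and variable personnel
within ~2.5 % for standard care and individual; the club arm lands ~5–6 %
high, which we attribute to unpublished exact visit counts and group
formation during the study year.  Miscellaneous consumables have no
ingredient model (they exist only as expenditure records) and compute to
zero when no record is supplied.

**Reconstructed inputs.** Visit volumes for the study year were not
published directly.  They are reconstructed in `prepcost.reference`:
quarterly refills (170) from recorded public-sector HIV-test spending at
the national unit cost (tests run at initiation and every quarterly visit:
3434.27 / 4.44 ≈ 773 = 603 initiations + 170), monthly refills (507) from
closing the 1280 person-month total at one dispensed month per visit.
As-implemented test unit costs are likewise back-derived from recorded
annual totals and these event counts, and are flagged reconstructed.

## Capacity model

The nurse and social worker see each client in series — they cannot serve
different clients in parallel — so the daily client ceiling divides the
productive workday (480 min, matching the 8-hour salary basis) by the
combined expected staff minutes per client under the observed visit mix
(initiation / monthly / quarterly shares of 54/35/11, 63/27/10 and 46/40/14
for standard care, club and individual).  Club group-counselling time is
amortized over the average group size of 7: over a year of operation
part-filled groups pool across days, so each group-visit client consumes
t_group/7 social-worker minutes in expectation.  Per-cadre ceilings
(workday / one cadre's expected minutes) are reported alongside — the
standard-care nurse ceiling is ⌊480 / 22.22⌋ = 21 clients/day — and the
bottleneck cadre is the one with the larger total service time across the
three visit types (ties resolve to the nurse).  Annual person-months
assume one month dispensed per attended visit and 260 service days.

Under this model the throughput ordering is individual < club < standard
care (11 < 12 < 14 clients/day with the built-in profile): individualized
counselling is the most staff-intensive, group clubs recover part of the
gap.  The published at-scale person-month volumes (10,171 / 9,360 / 5,069)
come from a spreadsheet whose internals are not available and cannot be
re-derived from the published staff times and visit mixes alone; the
scenario engine therefore takes at-scale volumes as inputs, defaulting to
the published figures, and the capacity module is a documented,
parameterized estimator rather than the authoritative source of those
numbers.

## Synthetic-data generators

No raw observation logs, visit logs or itemized ledgers are published; the
generators produce stand-ins with the statistical structure the pipeline
assumes, all pure functions of (config, seed).

**Enrolment/visits.**  603 initiators, arms allocated 1:1:1, follow-ups on
the program calendar (monthly refills at months 1, 2, 4, 5, 7, 8, 10, 11;
quarterly at 3, 6, 9, 12).  Retention has three parts: 40 % of initiators
never return (this pins the median time on PrEP at 1 month); returners
remain on-program for a geometric window (continuation 0.80/month, capped
at 12); each scheduled visit inside the window is attended with probability
0.402 (skipped visits with later return were evidently common, given the
published visit composition).  Calibration is analytic: mean months on
PrEP = 1 + 0.6 × 0.402 × 4.657 = 2.123 (so ~1280 person-months over 603
initiators), P(1 month) = 0.538 giving median 1 with an IQR upper bound of
3, and an expected follow-up stream of ≈500 monthly + 178 quarterly
refills, matching the reconstructed study-year volumes.  The generator
matches these summary statistics, not the full (unpublished) distribution,
and carries optional per-arm retention overrides.

**Observations.**  50 visit observations at the study's counts (9
initiation, 15 standard care, 8 club, 18 individual; follow-ups split ~2:1
monthly:quarterly) plus 10 reminder-contact timings.  Service durations are
log-normal (non-negative, right-skewed like the reported IQRs) located at
per-role medians consistent with the reported visit-level medians
(initiation 51 = 32 nurse + 19 social worker; standard monthly 6; club
quarterly 57; ...), with σ = 0.3 on the log scale.  Every observation
carries waiting and research segments that the pipeline must strip.  With
as few as 3 visits per cell, single-run medians are noisy; calibration
tests therefore bound the across-seed mean of the sample medians.

**Ledgers.**  Category targets (defaults: the as-implemented accounts,
fixed categories shared, variable per model) are split into 1–10 random
dated items whose sum is exact by construction, so ledger aggregation
conserves the targets to float precision.

**What passing tests do not show.**  The generators reproduce published
summary statistics under idealized randomness (independent participants,
stationary retention, log-normal durations).  Real programs have site
effects, seasonality, arm-specific retention and observer effects that the
stand-ins do not model, so generator-based closure tests validate the
pipeline's arithmetic and plumbing, not field realism.

## Numerical choices

- Monetary arithmetic at full float precision; rounding to cents only at
  report boundaries.  Currency conversion at the study-period average
  14.31 ZAR/USD; round trips recover amounts to 1e-9 relative.
- Quartiles: linear interpolation between order statistics (numpy default),
  fixed everywhere.
- Percent increments are reported as whole percents (banker-free
  `round`); they are invariant under uniform currency rescaling.
- One published column total (club, as-implemented) sits exactly 2 cents
  above the sum of its own printed categories; consistency checks use an
  inclusive ±0.02 band.  The as-implemented cost-per-person-month values
  are computed as total/1280 (the tabulated 105.74/105.61 variants arise
  from summing independently rounded per-category unit costs).
- The switch from research to public-sector pricing computes to a 47.5 %
  decrease in total annual cost under total-ratio arithmetic; the package
  reports the computed value.
- Degenerate inputs: zero workday → zero capacity; an all-zero time profile
  is refused (unbounded capacity); zero person-months raises on division;
  missing profile cells and missing fixed categories are hard errors naming
  the cell/category.

## Known limitations

- The two study sites (rural/urban) are costed jointly; the data model
  carries no site dimension.
- At-scale person-month volumes are inputs, not derivations (see the
  capacity section).
- No cost-effectiveness, budget-impact or probabilistic sensitivity
  analysis; no STI-testing costs (not part of standard-of-care PrEP in this
  setting); single costing year, no inflation or multi-year modelling.
- Club-arm ingredient personnel costs carry the ~5 % residual noted above.
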