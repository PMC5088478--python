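# Methods

## Model structure and assumptions

The package implements a deterministic, cohort-level, value-based
cost-utility model of genetic screening for progression of Category 3 AMD
to neovascular AMD, with a stochastic patient-level counterpart used as a
cross-check.  Core assumptions:

* **Horizon and discounting.**  12 years (mean life expectancy of an NVAMD
  patient at presentation), end-of-year discrete discounting at 3 %/year
  for both QALYs and dollars, 2012 US dollars throughout.  End-of-year
  (not mid-cycle, not continuous) discounting is the convention consistent
  with the model's own compounding arithmetic ($1,461 × 1.03⁹ = $1,906).
* **Screening and treatment timing.**  Screening at age 65; mean first
  NVAMD presentation at 75.  The gap enters only through compounding of
  the test cost; nine annual periods reproduce the printed chain (ten
  would give $1,963), so 9 is the default and the period count is an
  ordinary config parameter.
* **Value arises solely from stratum shift.**  Early and late ranibizumab
  treatment have identical direct ophthalmic costs; the entire incremental
  benefit of screening is moving patients from the late (≤ 20/160) to the
  early (20/40–20/80) baseline-acuity stratum.
* **Arm accruals are inputs.**  The 12-year accruals (sham 5.990, early
  7.924, late 6.561 QALY) are carried as primary inputs.  The monthly
  vision trajectory behind them (trial years 1–2, last observation carried
  forward thereafter, with the bilateral-good-vision bonus 0.121, first-eye
  gain 0.0884 and adverse-event disutility 0.045 "weighted appropriately")
  is under-specified, so a recomputation from the 0.789-utility annuity is
  exposed as `early_accrual_consistency` with a ±0.05 QALY band and is
  never a computation path.

## Fellow-eye conversion

Cumulative incremental conversion A(t) of baseline-unilateral cases:
A(1) = 21.2, A(2) = 38.0 (observed); for t ≥ 3,
A(t) = A(t−1) + h·(100 − A(t−1)) with h the arithmetic mean of the two
observed incremental conversions, (21.2 + 16.8)/2 = 19.0 %/year.  This is
the only reading of "average incidence, carried forward" that reproduces
both the year-3 (49.8) and year-12 (92.5) cells; intermediate published
cells differ by ≤ 0.2 points (plausibly year-varying hazards in the
original Markov run), so tests on those cells use a ±0.3 band.  Bilateral
involvement is B = 46.4 + 0.535·A, capped at 100; the 0.535 unilateral
share follows the formula as printed rather than the 0.536 prose figure
(override available).

## Adjustment multipliers and printed-precision conventions

The cohort-averaging factor is 0.780 × 0.622 × 0.90 = 0.436644 ("43.7 %");
with the 85.7 % combined-eye multiplier, 37.4 %.  Where the source prints
two variants of a constant (66,873 vs 66,180; 85.7 % vs 85.3 %; 53.5 % vs
53.6 %), the registry defaults to the member of each pair used in the
source's own downstream arithmetic and stores the alternate as metadata.
The adjusted gain entering every cost-utility expression is
round(1.363 × 0.436644, 3) = 0.595: the published tables were built from
3-decimal intermediates, and carrying full precision would reproduce them
slightly *less* well.  Patient counts stay real-valued (1 % of the cohort
is 1,617.54 patients) and are rounded only in report formatting.

Known irreproducibles, reported as recomputed values rather than pinned:
the per-screened QALY gain (printed 0.0185 and 0.0177; direct division
gives 0.0196), the patient-row payer ROI (printed 16,945 %; its own cells
give 16,813 %), the ~0.845 adjusted early-vs-sham gain (printed inputs
give 0.844), and the unadjusted early quality-of-life percentage (printed
32.8 %; the gain/sham rule gives 32.3 %).

## Costs

Negative costs (savings) are stored as negative numbers; the societal
perspective sums direct non-ophthalmic medical, caregiver and employment
buckets (−$227,455 per early case after adjustment), the third-party
perspective keeps only the first (−$40,914).  The $299 monitoring add-on
is a per-capita lump (the 22.5 % high-risk weighting is folded into it, as
in the printed $1,906 + $299 = $2,205); an explicit
visits × price mechanism backs the sensitivity scenarios, at $299 per
extra annual exam+OCT visit (the only unit price consistent with the base
case).  Savings nominally begin at month 7 after treatment initiation;
at the model's annual resolution this does not change any 12-year total
and is carried as ledger metadata.

## Cost-utility and break-even

CUR(p) = [S + n(p)·c_neg] / [n(p)·g] with S the national screening outlay,
n(p) = p/100 × 161,754, c_neg the signed per-case negative cost and
g = 0.595.  CUR is strictly decreasing and continuous in p and changes
sign exactly where total cost does (~5.66 % societal uptake).  Break-even
uptake solves the closed form n = S / (−c_neg + T·g) for threshold T;
an infinite T recovers the financial zero-crossing.  When g = 0 (a
null-effect configuration) the CUR is reported as infinite — a flagged
"unattainable" rather than an error.

## Sensitivity scenarios

Scenarios are named override bundles evaluated through the full pipeline
at the fixed published points (4.1 % societal, 10.1 % third-party).
Conventions:

* overridden genetic-test prices enter **uncompounded** ($500 + $299 =
  $799 per capita), which reproduces the published $754,576k and
  $1,226,776k screening totals exactly;
* screening-age changes are expressed as extra compounding periods — the
  published age-change totals are not reproducible from any stated
  convention (the age-60 total implies ≈ 10.3 extra periods rather than
  5), so the mechanism is provided and only its monotonicity is asserted;
* the double-injection scenario adds a per-early-case differential
  (22 extra injections × $853, the unit cost back-inferred from the
  published screening-side lump and flagged as such) times the number of
  early cases.  The published ~6.0 % break-even under this scenario is
  likewise not recoverable from printed numbers and is not asserted.

## Microsimulation

`simulate_cohort(n, seed, params)` draws each screened patient through a
single seeded PRNG stream in fixed order: risk class (P(high) = 0.225),
progression (P = 0.80 given high, ≈ 0.026 otherwise — the unique joint
distribution matching the stated margins P(progress) = 0.20 and
P(high | progress) = 0.90), detection (= high class among progressors),
per-eye presentation strata (0.780 / 0.622, independent — independence
reproduces the published 48.5 % both-eyes-late product), and a fellow-eye
conversion year sampled from the extended trajectory's increments
(46.4 % mass at baseline-bilateral, residual past year 12 = "never").

Per-early-case quantities average over progressors — the incremental
NVAMD patient slots of the deterministic tables — with detection and
both-eyes-late as Bernoulli gates on the unadjusted payloads (1.363 QALY;
−$520,917 societal / −$93,699 third-party savings against the $66,873
screening allocation).  By construction the population means converge to
0.595 QALY and −$160,582, which is exactly what makes the simulation an
independent oracle: it shares only the *inputs* with the deterministic
model, not its algebra.  At n = 200,000 (~40,000 progressors) the
Monte-Carlo standard errors are ≈ 0.0034 QALY and ≈ $1,290, and a
20-seed calibration test checks that per-seed means scatter consistently
with the reported SE.  Per-year utility/cost streams are a stylized
allocation of each patient's scalar totals (screening in year 1, savings
spread uniformly) and exist to make per-patient accounting inspectable,
not to add dynamics.

What the generator does **not** emulate: individual mortality, AREDS
supplement effects, treatment switching, correlated presentation between
eyes, or uptake behavior.  Passing convergence tests therefore validates
the arithmetic chain under the model's stated distributions — not the
epidemiological realism of those distributions.

## Problem sizes and numerical choices

Deterministic components are closed-form arithmetic and run in
milliseconds at full size.  The microsimulation uses n = 200,000 in the
convergence checks (3-SE bands of roughly ±0.010 QALY / ±$3,900, tight
enough to detect any mis-specified factor) and 20 × 20,000 in the seed
calibration; larger n changes nothing but the bands.  Whole-dollar
rounding is applied at the two points where the published chain rounds
(CPT total, compounded cost); everything else carries float precision to
output formatting.

## Known limitations

* The 30.3 screened-per-early-case ratio is a primary input; it is not
  derivable from the other parameters (30.3 × $2,205 = $66,812 ≠ $66,873),
  and the per-screened QALY gain inherits that ambiguity.
* The third-party break-even at the WHO threshold computes to 10.17 %
  (16,450 patients) against a published 10.1 % (16,504); the recomputed
  value is primary.
* No probabilistic sensitivity analysis and no league-table comparisons —
  the scenario engine is deliberately one-way, matching the scope of the
  analysis it reproduces.
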