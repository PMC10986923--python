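# Methods

## Cohort model

The herd is a closed cohort: no culling, mortality, or replacement
transitions, and no cow-level covariates (parity, stage of lactation). State
is the ulcer indicator; each 2-month cycle applies three events in a pinned
order:

1. **Selection.** The prevalence `s` at cycle start splits into the four
   trimmed×ulcer compartments using the strategy's selection pair
   `(P(trim|SU), P(trim|no SU))`. Selection must precede cure because the
   cure probabilities are defined conditional on being trimmed.
2. **Cure.** Ulcers resolve with probability 0.85 (trimmed) or 0.20
   (untrimmed). The spontaneous 0.20 applies to every untrimmed ulcer
   cow-cycle in both arms, including between whole-herd sessions.
3. **Onset.** Healthy cows — including those cured this cycle — develop an
   ulcer with the per-cycle onset probability. Applying onset last keeps the
   process memoryless (a cured cow can relapse immediately).

The published inputs condition selection on the previous cycle's trim status
as well, but the four conditional values collapse to two (0.54 / 0.1699), so
the chain depends on ulcer status only; the trace still reports all four
compartments. Whole-herd sessions are placed at cycles 0, 3, …, 15 (trim at
the start of the horizon), which yields exactly 6 sessions and 600
cow-trimmings over 18 cycles. Cycle indexing is 0-based; cycle `k` spans
months `[2k, 2k+2)`.

Under the constant partial policy the prevalence recurrence is
`s' = s(1−c) + (1 − s(1−c))·i` with `c = 0.54·0.85 + 0.46·0.20` and onset
`i`; its fixed point `s* = i / (1 − (1−c)(1−i))` is used as an analytic
check of the engine (a 600-cycle run reaches it to machine precision).

## Cost and benefit accounting

All accounting is in 2019 USD; CAD inputs convert at 0.77 USD/CAD. Two CAD
means in the source cost table are treated as typographical errors (2.63 →
26.30 and 886.75 → 286.75); after the correction every row satisfies
`usd = cad × 0.77` to well under 0.5%, which the config validator enforces.
No inflation machinery is included: all prices are already 2019-adjusted.

Accrual conventions, per cycle:

* **Trim**: expected trims × US$15.02.
* **Block**: expected ulcer-trims × US$20.25, where 20.25 is already the
  *expected* block cost per ulcer trim (price 28.88 × application
  probability 0.70); the 70% is never applied a second time. It is retained
  separately only for the sensitivity analysis, which recomputes
  price × probability when either component is varied.
* **Labor**: per session, not per cow — US$13.34 every cycle for the partial
  strategy (45 min of sorting at US$17.79/h), US$2.96 at whole-herd session
  cycles (10 min).
* **Reproduction**: 1/6 of the annual artificial-insemination cost per
  cow-cycle, conditional on ulcer state at cycle start (US$220.80/yr with an
  ulcer — 5 services — vs US$132.48/yr — 3 services). This is the simplest
  convention consistent with summing costs per 2-month cycle; the source
  spreadsheet's exact AI accrual is not recoverable (see Limitations).
* **Production loss**: per ulcer cow-cycle, US$101.63 (5% of a replacement
  cow, quota system) or US$73.50 (direct milk loss, the no-quota scenario);
  the two modes are exclusive.

Ulcer state is counted at cycle **start**, before cure: a cow trimmed for an
ulcer this cycle still incurs that ulcer's block and production costs.

Discounting groups cycles into model years (6 cycles) and weights year `y`
by `1/1.015^y`, `y = 0, 1, 2` (beginning-of-year accrual). Components are
reported undiscounted and totals discounted, mirroring the source table's
reporting convention — with this convention 3-year benefits for 100 cows are
660,510 × (1 + 1/1.015 + 1/1.015²) = US$1,952,390.6, within 0.0002% of the
published US$1,952,388. Benefits are identical in both arms, so the
net-benefit difference equals the discounted cost gap exactly.

## Probabilistic analysis

Each of the 2000 iterations redraws every Beta-specified probability and
every Normal-specified price (CAD draw × 0.77; negative draws are resampled,
effectively never with sd 0.1). The per-cycle onset probability is recomputed
per draw from the drawn annual incidence risk. Two deliberate fidelity
choices:

* The incidence-risk distribution Beta(465, 1624.7) has mean 0.2225 even
  though the deterministic risk is 7.8%; both are used exactly as published.
  The PSA's onset probability therefore averages ≈0.0411 (verified by
  quadrature of the transform against the Beta density) versus the
  deterministic 0.0134 — this single inconsistency is what moves the
  probabilistic mean difference away from the deterministic difference.
* Price uncertainty (CAD sd 0.1) is negligible by design; essentially all
  PSA variance comes from the Beta draws.

The "95% CI" is the empirical 2.5–97.5 percentile interval of the draws.
Each iteration receives its own RNG stream spawned from the master seed
(`numpy.random.SeedSequence.spawn`), so results are independent of execution
order and bit-reproducible. The same scheme seeds microsimulation replicates.

## Sensitivity and scenarios

The tornado varies one input at a time to its published bounds. Three rows
need derived recomputation: the overall partial-trim probability bound
(10–30%) scales both conditional selection probabilities by `bound/0.18`,
preserving the targeting ratio; the block price and block probability bounds
recompute the expected block cost as price × probability; the labor bound
varies the hourly wage, moving the 45-minute partial and 10-minute
whole-herd session costs together. The single AI bound (±US$38.50) shifts
both annual AI costs simultaneously. Benefit inputs (milk, cattle sales)
cancel between arms and produce zero-width bars by construction.

* **Scenario 1 (random selection)**: both partial-herd selection slots point
  at the overall trim-probability parameter, so a single Beta(43.74, 199.26)
  draw per iteration applies to cows with and without ulcers alike — the
  headline is reported from the whole-herd perspective.
* **Scenario 2 (targeting sweep)**: for ulcer-selection levels 0.18 / 0.54 /
  1.00 the healthy-cow probability is solved by root finding (Brent, budget
  matched to ±0.01 trims) so the partial arm spends exactly 324
  cow-trimmings; selection feeds back on prevalence, so the trace is re-run
  at every trial value. The sweep reports the deterministic difference and,
  optionally, the probabilistic mean with the solved pair held fixed across
  draws. The two columns differ in sign at the 0.18 level: deterministically
  (onset 0.0134) the partial arm still wins narrowly, while under the PSA's
  onset distribution the whole herd wins — consistent with Scenario 1.
* **Scenario 3 (herd size)**: labor is the only herd-size-independent
  component, so the difference is exactly affine in herd size; the sweep
  reports the least-squares line (R² ≈ 1; the intercept is the labor
  asymmetry and vanishes when labor is zeroed).
* **Scenario 4 (no quota)**: the PSA with production loss priced as direct
  milk loss.

## Microsimulation oracle

The per-cow simulator realizes the identical event structure as Bernoulli
draws per cow and cycle (cows independent — no contagion or pen effects) and
tallies costs under the identical accrual rules, so the cohort model is
exactly the expectation of the microsimulation. The validation report checks
every tallied quantity in both arms against the replicate mean within 3
Monte Carlo standard errors (an absolute floating-point floor covers
deterministic tallies such as the whole-herd trim count, which must agree
exactly). This equivalence, not any published number, is the structural
correctness test of the package. What passing does **not** show: that real
herds behave like the model — the generator emulates the model's assumed
event structure, not field data (no seasonality, no producer treatment
between trims, no correlation between cows, no lesion severity).

## Problem sizes

The default analyses use the study conditions throughout: 100 cows, 18
cycles, 2000 PSA iterations, 2000 microsimulation replicates. The full test
suite runs in well under a minute; the acceptance script in a few seconds.

## Limitations

* The source's reproduction costs (partial arm *higher* than whole arm)
  cannot be reproduced by any per-cow-cycle state accrual, which necessarily
  makes the arm with more ulcer cow-cycles (whole) at least as costly; the
  source hints at an annual "chronically affected" rule it does not define.
  Likewise its block costs imply fewer ulcer-trims than the trace contains
  under either before- or after-cure counting. The conventions above are
  documented and pinned; headline results remain inside the published
  uncertainty intervals, but the deterministic difference (US$4,134) and PSA
  mean (≈US$4,800) sit above the published point values (US$3,652 /
  US$4,337).
* `P(trim | no SU) = 0.1699` is used verbatim although it is not consistent
  with solving 0.54·0.064 + x·0.936 = 0.18 (which gives 0.1554).
* Mastitis correlation, culling, genetics, preventive effects of trimming,
  and producer-administered treatment between trims are outside the model.
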