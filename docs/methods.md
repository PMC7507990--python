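# Methods

## Model structure and assumptions

The model is a three-state Markov cohort (progression-free on first-line
therapy → progressive disease → dead) advanced in 6-week cycles for 174
cycles (20 years × 365.25 d / 42 d, floored, plus the starting cycle).
State membership is counted at cycle start; events occur during the cycle.

Each arm contributes two Weibull endpoints, S(t) = exp(−λ·t^γ) with t in
6-week cycles.  The time unit matters: the bundled scale parameters only
reproduce trial-scale survival (e.g. the chemotherapy arm's median OS of
≈10 cycles ≈ 14 months in the ≥50% stratum) when t is counted in cycles,
and `survival.scale_to_cycles` converts parameters fitted on other units.

Per-cycle transition probabilities are conditional hazards
M(t) = 1 − S(t+1)/S(t).  The OS-curve hazard is applied as the death
probability in **both** alive states, and PFS→PD progression is
max(0, M_pfs(t) − M_os(t)).  This is the standard construction when the
only survival inputs are one OS and one PFS curve per arm: it keeps the
simulated alive fraction exactly on the OS curve and PFS occupancy on the
PFS curve (exact whenever the PFS hazard dominates, which holds essentially
everywhere for the bundled parameters; the floor is logged when it binds).
The test suite asserts this partitioned-survival consistency within 2% at
every cycle, occupancy conservation to 1e−9, monotone death, and agreement
of undiscounted life-years with the restricted mean survival time of the
OS curve within one cycle length.

A consequence worth stating plainly: with this construction no arm can
accumulate more (discounted or undiscounted) life-years than its OS curve
contains.  The source evaluation from which the bundled parameter tables
are taken prints per-arm totals that exceed that bound (its chemotherapy
life-years exceed even the undiscounted restricted mean of its own
chemotherapy OS Weibull), which is only possible if mortality there acted
solely through the progressive-disease state.  We deliberately keep the
OS-anchored construction — it is the defensible one given the inputs — and
note that *incremental* life-years and QALYs between arms are far more
stable across these structural choices than absolute totals; users
comparing against the printed per-arm totals should expect our absolute
costs and effects to differ while the incremental effectiveness agrees
closely.

## Accrual conventions

* **Active treatment.**  The immunotherapy doublet (nivolumab $17,517.15 +
  ipilimumab $10,718.96 per cycle) accrues on PFS occupancy until
  progression, with no duration cap by default
  (`settings.treatment_cap_cycles` imposes one; 18 cycles ≈ the 2-year
  stopping rule used in the source trial).  Chemotherapy accrues two
  3-week administrations per cycle of the histology-weighted doublet
  (70.8% or 75.3% non-squamous; pemetrexed+platinum vs
  gemcitabine+platinum; platinum split carboplatin/cisplatin 50/50 by
  default since the trial does not report it — the choice moves costs by
  under $60/cycle) for the first two model cycles, then pemetrexed
  maintenance for the non-squamous share while progression-free.
* **Administration** ($139.61/cycle) accrues only while on active
  treatment; **CT surveillance** ($231/cycle) accrues at the 6-week rate in
  PFS and prorated ×6/9 in PD (9-week post-progression interval);
  **laboratory** ($315/cycle) accrues in both alive states.
* **Adverse events.**  Σ(incidence × management cost) per arm, charged once
  at model entry.  Fatigue carries a zero management cost, making it a
  natural zero-effect probe for the tornado analysis.
* **Subsequent therapy.**  Per-cycle items (post-study immunotherapy,
  pembrolizumab, subsequent chemotherapy, targeted therapy) accrue on PD
  occupancy for the whole PD residence, uptake-weighted; radiotherapy is
  priced per course and charged on the newly-progressing flow.  The
  duration of post-progression immunotherapy is the single most
  consequential unstated convention: `settings.subsequent_cap_cycles`
  exposes it.
* **Discontinuation.**  The trial-reported discontinuation proportions are
  stored on each arm but not applied by default (their computational role
  in the source evaluation is unstated); `settings.apply_discontinuation`
  multiplies active drug cost by (1 − proportion).
* **Discounting** is 3%/year for costs and outcomes alike, compounded on
  fractional years per cycle.  Half-cycle correction is off by default
  (trapezoid occupancy behind `settings.half_cycle_correction`).

## Sensitivity analyses

One-way analysis reruns the pipeline at each parameter's published range
bounds; entries are ranked by ICER span, ties broken by declaration order,
and undefined ICERs (dominance) propagate as missing spans.  The
probabilistic analysis draws the parameters that carry a distribution
family — beta for utilities and adverse-event risks, gamma for costs — by
method of moments from (baseline mean, SD = range/3.92, ranges read as 95%
intervals; `settings.range_sd_divisor` selects e.g. range/4 instead).
Draws are independent (no published correlation structure), a single seed
drives one generator over parameters in declaration order, and degenerate
ranges collapse to exact point masses so an all-degenerate run reproduces
the base case bit for bit.  Weibull parameters carry no published ranges
and are held fixed — a real limitation: the acceptability curves understate
survival-extrapolation uncertainty, and because the deterministic ICERs
sit far from $150,000/QALY under our accrual conventions, the simulated
probabilities of cost-effectiveness are correspondingly extreme rather
than the published mid-range values.  Threshold pricing bisects the least
fractional price cut with non-negative net monetary benefit (monotone in
the cut), to 0.1%.

## Synthetic data

`synthetic.simulate_km` emulates the digitization stage: inverse-CDF
Weibull event times for n patients, administrative censoring at a fixed
cycle, product-limit estimation on a reading grid, and optional additive
survival-fraction noise (default SD 0.005, ≈ half a percentage point of
reading error) repaired by a monotone clamp.  It reproduces what matters
for the fitting stage — sampling noise shrinking with cohort size, a
censoring-truncated tail, grid readout — but not real-world curve defects:
no rounding to pixel grids, no mis-read plateaus, no informative censoring,
no number-at-risk mismatch.  Passing recovery tests therefore demonstrate
estimator correctness under clean digitization, not robustness to a poor
scan.  `synthetic.make_test_scenario` jitters every ranged economic input
uniformly within its published range for robustness sweeps.

## Numerical choices

Weibull fitting is ordinary least squares on log(−log S) against log t
(points with S = 1 or t = 0 dropped, tied times rejected, ≥3 usable points
required), optionally weighted by interval event counts reconstructed from
numbers at risk; the full at-risk-table reconstruction is not implemented.
An independent maximum-likelihood fit (lifelines) serves as a cross-check
in the tests, never as the implementation.  RMST uses adaptive quadrature
(relative tolerance 1e−10).  Property-test parameter ranges keep
λ·t^γ within double precision so survival neither underflows nor rounds
conditional probabilities to 1.

## Known limitations

Single comparator pair per scenario (no multi-strategy frontier); cohort
fractions only (no microsimulation, no patient-level heterogeneity); no
alternative survival families (the source fits selected Weibull by AIC but
reports no competing parameters); no vial rounding, inflation, or currency
conversion; no value-of-information analysis; and the absolute-total
caveats above when comparing against the published per-arm figures.
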