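# nsclc-cea

A Markov cohort cost-effectiveness model of first-line **nivolumab plus
ipilimumab versus platinum-doublet chemotherapy** in advanced non-small-cell
lung cancer (NSCLC), for health-economics and outcomes researchers who want
the full decision pipeline — survival extrapolation, cohort simulation,
costing, incremental analysis, and sensitivity analysis — as tested,
scriptable Python rather than a spreadsheet or TreeAge file.

## The model

Patients start progression-free (PFS) on first-line therapy, may progress
(PD) and then die, in discrete 6-week cycles over a 20-year horizon.  Both
endpoints of each arm are Weibull curves fitted to digitized Kaplan–Meier
coordinates,

S(t) = exp(−λ·t^γ),  λ > 0, γ > 0, t in 6-week cycles,

and the per-cycle transition probability out of a curve is the conditional
hazard M(t) = 1 − S(t+1)/S(t).  Death strikes both alive states with the
OS-curve hazard; progression removes from PFS the excess of the PFS-curve
hazard over death.  Costs (drug acquisition, administration, CT
surveillance, laboratory monitoring, one-time grade ≥3 adverse-event burden,
post-progression therapy mixes) and utility-weighted life-years accrue on
the state occupancies, everything discounted at 3% per year.  The headline
statistic is the incremental cost-effectiveness ratio
ICER = ΔC/ΔE (USD per QALY), judged against a willingness-to-pay threshold
of $150,000/QALY via net monetary benefit NMB = WTP·ΔQALY − ΔC.

Three parameter bundles ship with the package — PD-L1 expression ≥50%, ≥1%
and <1% strata, with published per-arm Weibull parameters, utilities
(0.784 / 0.693 progression-free, 0.473 post-progression), US per-cycle
prices, adverse-event risks and costs, and subsequent-therapy mixes — plus
one-way (tornado), probabilistic (1000-draw Monte Carlo, beta/gamma by
method of moments, acceptability curves) and threshold-price analyses.

## Worked example

```python
from nsclc_cea import builtin_scenario, evaluate, nmb

scenario = builtin_scenario("pdl1_ge50")
res = evaluate(scenario)
print(f"intervention: ${res.intervention.total_cost:,.0f}, "
      f"{res.intervention.qaly:.2f} QALYs")
print(f"comparator:   ${res.comparator.total_cost:,.0f}, "
      f"{res.comparator.qaly:.2f} QALYs")
print(f"ICER: ${res.cea.icer_per_qaly:,.0f}/QALY, "
      f"NMB at $150k: ${nmb(res.cea, 150_000):,.0f}")
```

prints

```
intervention: $523,558, 2.24 QALYs
comparator:   $166,864, 1.00 QALYs
ICER: $286,915/QALY, NMB at $150k: $-170,213
```

i.e. in the ≥50% stratum the combination buys 1.24 extra QALYs at ≈$357k
extra cost under this model's accrual conventions (treatment to progression
with no duration cap; see `docs/methods.md` for how convention choices move
these totals).  The same pipeline is available from the shell:

```sh
nsclc-cea base-case pdl1_ge50 --out-dir results/ge50   # Table-2-style CSVs
nsclc-cea psa pdl1_ge50 --draws 1000 --seed 7 --out-dir results/psa
nsclc-cea threshold pdl1_lt1 --out results/threshold.json
nsclc-cea fit-km my_digitized_km.tsv --out fit.json
```

The threshold command reports, for example, that a ≈23% cut in the
nivolumab acquisition price would make the PD-L1 <1% stratum cost-effective
at $150,000/QALY.

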