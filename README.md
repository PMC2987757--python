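# medworkforce

A system-dynamics simulator for medium- and long-term planning of the
medical-specialist workforce. It is written for health-workforce planners
and researchers who need to answer "what if?" questions — What happens to
the supply of anesthesiologists if medical-school admissions rise 20%?
How much larger does the specialist deficit get under rapid population
growth? — over decade-scale horizons where training delays dominate.

## The model

The workforce of each specialty is a **stock** indexed by sex and
single-year age (ages 30–65, 36 groups), advanced annually by the
stock-flow balance

```
Stock(t+1) = Stock(t) + Inflow(t) − Outflow(t)
```

- **Inflows**: residency completions (a cohort admitted to medical school
  in year *y* becomes specialists in year *y + D_med + D_res*, with
  D_med = 6 and D_res ∈ {4, 5}; intake is capped by residency positions)
  and net immigration.
- **Outflows**: mandatory retirement at a schedulable age, mortality,
  drop-out, and optional early retirement — applied per sex and age.

**Need** per specialty is a normative standard *r* (specialists per
100 000 inhabitants) compounded at a demand-group growth rate *g* and
scaled by a population projection *P(t)*:

```
Need_s(t) = r_s · (1 + g_s)^(t − t0) · P(t) / 100 000
```

with default group rates +1.3% (sharply increasing), +0.6%
(stable/increasing), 0% (stable) and −0.6% (decreasing) per year.

The headline gap metric is the **deficit fraction**
`(supply − need) / supply` (negative = shortage), alongside the ratio per
100 000 inhabitants, FTE supply (headcount × sex/age conversion ratios),
and pyramid summaries (% women, % under 51).

Every policy lever — numerus clausus, residency positions per specialty,
retirement age, FTE ratio, net immigration — is a per-year schedule with
carry-forward semantics. The simulation is fully deterministic; the only
randomness in the package is in the synthetic fixture generator, which is
seeded.

## Worked example

```python
import medworkforce as mw

scn = mw.generate_spain_like_scenario(seed=1)   # synthetic 43-specialty baseline
res = mw.run_scenario(scn)
print(res.summary().to_string(float_format=lambda v: f"{v:,.1f}"))
```

```
year                   2008         2015         2025
inhabitants    44,366,332.0 46,333,661.0 48,018,184.0
supply_head       141,579.0    152,484.9    163,640.0
supply_fte        131,583.4    140,337.2    148,918.6
need              144,410.0    157,390.5    173,918.0
deficit_head       -2,831.0     -4,905.6    -10,278.0
deficit_pct            -2.0         -3.2         -6.3
ratio_per_100k        319.1        329.1        340.8
pct_women              47.1         53.1         60.0
pct_under_51           61.7         63.6         61.5
```

The generated baseline opens in 2008 with 141 579 specialists against a
need of 144 410 — a 2.0% deficit (2 831 heads) and 319 specialists per
100 000 inhabitants — and the deficit widens to 6.3% by 2025 as need
(driven by population and demand-group growth, +20.4% over the horizon)
outpaces the training pipeline. `pct_women` rises because two of every
three new entrants are women. Per-specialty trajectories are in
`res.by_specialty`; `mw.rank_specialties(res, 2025)` orders specialties
by shortage severity.

The same run from a shell:

```
medworkforce fixtures --seed 1 --out fixture/
medworkforce simulate --config fixture/scenario.yaml --out run/
medworkforce sweep --config fixture/scenario.yaml --param retirement_age \
    --values 65 --values 66 --values 67 --out sweep/
```

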