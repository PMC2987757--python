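# Methods

## Model structure

The simulator is a deterministic, discrete-time (annual Euler step)
system-dynamics model with two submodels.

**Supply.** The state is a stock of headcounts per (specialty, sex,
single-year age), ages 30–65 inclusive (36 groups, the age at which
specialists enter practice through the age of mandatory retirement).
Counts are continuous reals: fractional people are allowed, which is the
usual deterministic system-dynamics convention and keeps runs exactly
reproducible. Each step applies, in a fixed order:

1. **mandatory retirement** — all cells at age ≥ the year's retirement
   age are removed;
2. **multiplicative exits** — mortality, then drop-out, then optional
   early retirement, each as a fraction of the survivors of the previous
   exit;
3. **aging** — every cohort shifts one year older; anyone shifted past
   age 65 leaves as an explicit `aged_out` flow (only possible when the
   retirement age exceeds the age range);
4. **training completions** — added at the entry-age distribution
   (default: point mass at age 30);
5. **net immigration** — spread over a sex split and an age distribution
   (default: uniform over 30–40, half female).

The within-year order is a modelling choice that matters at the third
decimal; it is fixed, documented and tested rather than configurable.
Every flow is recorded in a ledger so that
`total(t+1) − total(t) = inflows − outflows` holds to 1e-9 at every step
(tested on random instances), and the vectorized update is checked
cell-by-cell against an independent scalar reference implementation.

A stock labelled year *t* includes the residency cohort completing in
*t*: a cohort admitted to medical school in year *y* first appears in
the stock of year *y + D_med + D_res*. This is what makes an admissions
change in 2009 first visible in 2019 supply under 6-year degrees and
4-year residencies.

**Training pipeline.** Admissions (the numerus clausus) are split by a
per-cohort female fraction (default 2/3, matching the observed
feminization of new doctors), scaled by an exam pass fraction, and
allocated to specialties in proportion to available residency positions
with a per-specialty cap: `intake_s = positions_s × min(1, graduates /
total positions)`. Completions are intake × a per-specialty completion
fraction, D_res years later. Pass and completion fractions default
to 1.0. Warm-up cohorts before the first scheduled year reuse the
earliest scheduled value, so a 2008-anchored scenario implicitly holds
pre-2008 admissions at their 2008 level.

**Demand/need.** `Need_s(t) = r_s (1+g_s)^(t−t0) P(t)/100 000`, with the
standard r in specialists per 100 000 set externally (e.g. by expert
consensus) and g one of four demand-group rates (+1.3%, +0.6%, 0,
−0.6%/yr by default, overridable per scenario). Growth compounds
geometrically — required for the annual and 17-year cumulative rates to
be mutually consistent (0.6%/yr ⇒ +10.7% over 2008–2025).

**Gap metrics.** Deficit fraction is `(supply − need)/supply`; this
divisor convention is the one under which a 152 160-supply /
173 918-need year is a 14.3% deficit. "Under 51" means attained age
≤ 50. Deficits are computed on headcount by
default; FTE supply is reported alongside. The aggregate deficit is
`(Σ supply − Σ need)/Σ supply`.

## Parameters that matter

| parameter | default | units / notes |
|---|---|---|
| retirement age | 65 | schedulable per year; values above 66 are inert because the state space ends at 65 |
| D_med, D_res | 6, 4 (or 5) | years; D_res per specialty |
| entrant sex split | 2/3 female | fixed at admission, preserved through the pipeline |
| entry age | 30 | point mass; configurable distribution |
| immigration age/sex | uniform 30–40, 50% female | configurable |
| demand-group rates | +1.3/+0.6/0/−0.6 %/yr | overridable per scenario |
| FTE ratio | 1.0 | per (sex, age), in (0, 1.5] |

Population paths: the moderate path interpolates the 2008/2015/2025
anchors (44 366 332 / 46 333 661 / 48 018 184) geometrically, which
reproduces the anchors exactly and implies ≈0.47%/yr. The rapid
(1.2%/yr) and slow (0.25%/yr) paths compound from the same 2008 base;
they were chosen once to bracket the moderate path at magnitudes
consistent with a doubling (rapid) and halving (slow) of the projected
end-of-horizon gap, and are configuration, not calibrated constants.

## Synthetic data

The fixture generator emulates the structure of a national specialist
registry without reproducing any real per-specialty values (names are
`synthetic_specialty_NN`). Age pyramids are discretized Beta densities:
old-heavy (Beta(5,2), mean age ≈ 55, 25% women), uniform, and
young-feminized (Beta(2,5), mean age ≈ 40, 65% women), cycled across 43
specialties with seeded jitter. Specialty sizes are seeded lognormal
weights normalized so the 2008 total matches the calibration target
(141 579 by default). Mortality is Gompertz-like,
`m(a) = m0·e^{β(a−30)}` with m0 = 5e-4, β = 0.09, female mortality 0.6×
male; drop-out is constant by sex (0.4% women, 0.2% men); FTE ratios are
0.85 (women) and 1.0 (men).

The Spain-like baseline scenario sets need standards whose total equals
the 2008 need target (144 410, i.e. 325.5 per 100 000) and solves the
demand-group need-share mix in closed form so that aggregate need grows
by the 2025/2008 anchor ratio (≈1.2043) under the moderate population
path, with the stable and decreasing groups fixed at 20% and 10% need
share. Baseline policies are constant: 4 500 admissions/yr (the
admissions level of the cohorts whose residencies complete within the
horizon — the training pipeline means 2008–2025 completions were largely
admitted 1997–2015), 7 000 residency positions/yr split in proportion to
need, retirement at 65, net immigration of 1 000/yr split by specialty
size.

What passing tests on these fixtures do **not** show: real registries
have irregular pyramids (hiring waves), specialty-specific exit
behaviour, geographic structure, and inter-specialty mobility, none of
which the generator emulates; calibration is aggregate-only, so
per-specialty results on synthetic fixtures are structurally plausible
but not estimates for any real specialty.

## Numerical choices and edge cases

- Conservation and oracle-equivalence tolerances are 1e-9 absolute on
  headcounts; CSV round trips use `%.17g` formatting and round-trip
  float parsing, making them lossless at double precision.
- Negative stock cells are errors naming the offending cell (they can
  arise only from net emigration exceeding a cell); tiny negative
  residuals below 1e-9 from float cancellation are clamped to zero.
- Empty specialties make pyramid fractions undefined and raise rather
  than returning 0.
- Ranking ties break by ascending specialty id (stable).
- Schedules carry forward; with carry-forward disabled every simulated
  year must be explicit and each gap is reported as (parameter, year).
- An aggregate need-growth target outside the hull of the four group
  rates makes the group-share solve infeasible and raises.

## Known limitations

- No sub-annual dynamics, no stochastic demography, no inter-specialty
  or geographic mobility, and no feedback from projected shortage to
  admissions — policies are exogenous inputs by design, so the tool
  answers "what if", not "what should".
- Ages above 65 are outside the state space; retirement ages above 66
  therefore have no effect.
- Need standards are inputs; the model propagates them but cannot
  validate them against utilisation or outcomes data.
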