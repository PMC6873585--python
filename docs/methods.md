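# Methods

## Model structure

Seven-state Markov cohort model, 1-year cycles, 49 cycles. States:
`DFS`, `CHF`, `REC_Y1`, `REC_LATER`, `MET_Y1`, `MET_LATER`, `DEATH`.
The two `*_Y1` states are tunnel states occupied for exactly one cycle;
they exist only to carry the first-year vs later-year cost split for
local recurrence and distant metastasis and share their parent state's
utility and transition probabilities. The cohort enters with unit mass
in DFS; `occupancy[t]` records the distribution at the end of cycle `t`
(so cycle-1 flows already reflect one transition). Death is absorbing.

Annual transition probabilities (all parameters live in the packaged
`table1.yaml`):

| from | to | symbol | mean (SE) |
|---|---|---|---|
| DFS | CHF | `tp_dfs_chf` | 0.0053 (0.0024) |
| DFS | recurrence | `tp_dfs_rec` | 0.0294 (0.0029) |
| DFS | metastasis | `tp_dfs_met` | 0.0785 (0.0140) |
| DFS | death | `tp_dfs_death` | 0.0020 (0.0001) |
| CHF | rec / met / death | `tp_chf_*` | 0.0294 / 0.0785 / 0.15 |
| recurrence | met / death | `tp_rec_*` | 0.0785 / 0.2950 (0.2066) |
| metastasis | death | `tp_met_death` | 0.2950 (0.2066) |

CHF is a once-only, largely reversible event: entry is open only during
the treatment year (cycle 1) in both arms, the trastuzumab arm's entry
probability is multiplied by the risk ratio 3.97, and the residual CHF
mass returns to DFS after its single cycle. A `chf_entry="every_cycle"`
flag opens entry in every cycle instead (effect on the ICER: ~+1%).

Treatment effect: during cycles 1–11 (the efficacy window) the
trastuzumab arm's DFS exits to recurrence/metastasis use the DFS hazard
ratio 0.65 and the exit to death the OS hazard ratio 0.67, applied by
the constant-hazard conversion `p' = 1 − (1−p)^HR` (flag
`hr_mode="multiply"` applies the ratio directly on the probability
scale; the difference is second order for these magnitudes). From cycle
12 the arms' matrices coincide.

No background all-cause mortality is layered on the trial-derived
probabilities (none is published as a model parameter), and no
half-cycle correction is applied by default (a `half_cycle` flag
exists). Both choices matter for absolute survival — see "Known
differences" below.

## Costing and outcomes

Per cycle: state costs (direct medical; plus direct non-medical under
the societal perspective) weighted by occupancy, with `REC_Y1`/`MET_Y1`
using the first-year cost rows. The one-off treatment-course cost
(PHP 1,076,607 trastuzumab arm / 194,900 chemotherapy arm) is charged to
the whole entering cohort at cycle 1. Life-years are the occupancy mass
in live states; QALYs weight occupancy by EQ-5D-3L utilities
(DFS 0.832, CHF 0.670, recurrence 0.828, metastasis 0.762). Discounting
is 3.5%/year for costs and outcomes with first-year flows undiscounted
(`(1+r)^-(t-1)`; an exponent-`t` flag exists).

Two published quirks are handled explicitly and configurably:

- The CHF utility's dispersion is printed as "0.6700 (272.71)", which no
  beta distribution can match; the packaged table substitutes the SE
  shared by the other utility rows (0.0262). Edit the YAML to override.
- Two distinct "(after first year)" recurrence cost pairs are printed.
  The default uses 182,437 / 17,817; the alternate pair 516,904 / 5,939
  is stored (`*_alt`) and selected by
  `settings.recurrence_later_costs="alternate"` (ICER effect: ~−1%).

## Uncertainty analysis

PSA distributions from the printed mean/SE pairs: beta by method of
moments for probabilities and utilities, gamma by method of moments for
costs, log-normal for the ratios with `mu = ln(point)`,
`sigma = se/point` (delta method; the sampling median equals the point
estimate — a moment-matched mode is available via
`settings.lognormal_mode="moment"`). Draws whose transition rows would
exceed 1 (about 0.1% of draws, driven by the wide recurrence/metastasis
death distributions) are rejected and fully redrawn, preserving the
feasible-region marginals; the count is reported. One seeded
`numpy.random.Generator` drives everything: same (table, n, seed) ⇒
bit-identical results. Default n = 50,000, seed 2019 (~20 s).

ICERs from the PSA are reported as ratios of mean increments. One-way
tornado ranges default to mean ± 1.96 SE clipped to validity, plus the
published 0–6% discount-rate and 5–49-year efficacy-duration ranges; the
two-way analysis crosses the DFS hazard ratio with the efficacy duration
and reports the higher-NMB strategy per cell at PHP 120,000/QALY.

## Budget impact

Eligible population = national cases × HER2-positivity (23.17%) ×
early-stage fraction (80%), rounded to whole persons: 11,872 prevalent
and 3,903 incident per year. Fiscal year 1 treats prevalent + incident
(15,775) at the per-course cost; years 2–5 each treat a fresh incident
cohort (constant incidence — no growth rate is published). Every treated
cohort contributes follow-up in later years from its *undiscounted*
Markov trace state costs aged by years since treatment, direct medical
costs only (governmental budget holder; societal variant behind a flag).
This reconstruction reproduces the printed year-1 figures exactly and
the later-year "more than PHP 5,200 / 2,300 million" statements; the
published year-by-year decomposition beyond year 1 is not itemised, so
years 2–5 are a documented reconstruction.

## Synthetic tables

`generate_random_table` builds structurally valid random tables for
property testing: probabilities drawn log-uniformly (small annual risks
well represented), exit rows rescaled to keep a 0.05 feasibility margin
*after* worst-case risk-ratio/hazard-ratio inflation, beta SEs capped
below the method-of-moments feasibility bound, costs log-uniform over
10³–2×10⁶ PHP, utilities uniform on [0.3, 0.95]. These tables exercise
validation, conservation and monotonicity — they do not emulate real
parameter correlation (all inputs are independent), so green property
tests establish structural soundness, not clinical realism.

## Known differences from the published figures

The original analysis was a closed Excel model; several structural
choices are unrecoverable from the publication. With this package's
defaults:

- Deterministic ICER: 502,052 PHP/QALY (published probabilistic value
  453,505; +10.7%). PSA-mean ICER: ~388k (−14.5%). The published table
  sits between the two modes.
- Mean incremental cost agrees well (~470k vs 452,128, +4%), but the
  incremental survival benefit is uniformly ~20% larger (ΔLY 1.44 vs
  1.20, ΔQALY 1.21 vs 1.00). The excess largely cancels in the ICER.
  The most plausible cause is background all-cause mortality in the
  original model (its abstract mentions country survival data) that is
  not published as a parameter and is therefore not invented here.
- The probability of cost-effectiveness at PHP 120,000/QALY computes to
  ~15% vs the published 10%. This quantity is controlled almost entirely
  by the very wide printed SE (0.2066) on the recurrence→death and
  metastasis→death probabilities; with the distributions exactly as
  printed the curve cannot be moved to 10% without tuning, which this
  package does not do. The corresponding acceptance test is left
  failing, deliberately.
- In the two-way plane, the extreme corner (DFS hazard ratio at its
  lower CI limit and efficacy ≥35 years) falls just below the threshold
  (ICER ~98–110k), whereas the published plane shows chemotherapy
  winning everywhere.

Arm-level totals (e.g. chemotherapy QALY 7.99) are matched almost
exactly if the entry state is allowed to accrue a cycle-0 flow; the
package follows the stricter convention (no cycle-0 accrual) because
increments — and therefore every decision quantity — are invariant to
it.

## Numerical notes

Row-stochasticity enforced to 1e-12 and trace conservation to 1e-10;
the threshold-price search brackets NMB(price) and solves with Brent's
method to 0.5 PHP, verifying |NMB| < 1 PHP at the root; ICERs are
undefined (None) at zero outcome difference rather than ±inf; dominance
is flagged from the signs of the increments.
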