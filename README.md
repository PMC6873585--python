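# her2cea

A Markov cohort cost-utility and budget-impact model of **1-year adjuvant
trastuzumab added to standard chemotherapy vs chemotherapy alone** for
women with HER2-positive early-stage breast cancer in the Philippines.
It is aimed at health-economists and HTA analysts who want a tested,
scriptable re-implementation of this published spreadsheet-era analysis —
to reproduce it, probe its structural assumptions, or adapt it to new
prices and epidemiology. All monetary values are 2017 PHP.

## The model

A cohort of 50-year-old women enters at disease-free survival (DFS) and
moves through five health states — DFS, congestive heart failure (CHF,
the cardiotoxic adverse event of trastuzumab), local recurrence, distant
metastasis, death — over 49 one-year cycles (lifetime horizon).
Recurrence and metastasis are expanded internally into first-year /
later-year tunnel sub-states so first-year costs can differ.

Treatment effect enters on the DFS exits during an 11-year efficacy
window via pooled hazard ratios (`HR_DFS = 0.65` on recurrence and
metastasis, `HR_OS = 0.67` on death), converted to per-cycle
probabilities as `p' = 1 − (1−p)^HR`; cardiotoxicity enters as a risk
ratio (`RR_CHF = 3.97`) on the CHF entry probability in the treatment
year. Costs and outcomes are discounted at 3.5%/year, and

```
ICER = (C_trast − C_chemo) / (E_trast − E_chemo)   [PHP per LY or QALY]
NMB(λ) = λ·ΔQALY − ΔCost,  λ = PHP 120,000 per QALY (national threshold)
```

Uncertainty propagates through a 50,000-replication probabilistic
sensitivity analysis (beta distributions for probabilities/utilities,
gamma for costs, log-normal for ratios, all parameterised from the
published mean/SE pairs by method of moments), summarised as a
cost-effectiveness plane and acceptability curves. A bisection search
reports the bundle price at which trastuzumab becomes cost-effective,
and a five-fiscal-year budget-impact module scales per-patient costs to
the national eligible population (early-stage fraction of HER2-positive
breast-cancer prevalence/incidence).

## Worked example

```
$ her2cea run-base
[healthcare_system] ICER: 502,052 PHP/QALY (420,271 PHP/LY); dCost 667,757 PHP, dQALY 1.330
[societal] ICER: 507,559 PHP/QALY (424,881 PHP/LY); dCost 675,081 PHP, dQALY 1.330

$ her2cea threshold-price
[healthcare_system] cost-effective bundle price at 120,000 PHP/QALY: PHP 568,457
[societal] cost-effective bundle price at 120,000 PHP/QALY: PHP 570,565

$ her2cea run-bia
eligible: 11,872 prevalent + 3,903 incident/yr
incremental budget, year 1: PHP 13,909 million; years 2-5: PHP 1,638-2,951 million/yr
```

Reading: at the deterministic means, adding trastuzumab costs an extra
PHP 667,757 per patient for 1.33 extra QALYs — an ICER of ~PHP 502k per
QALY, about four times the PHP 120k national willingness-to-pay
threshold, so the therapy is not cost-effective at its current price;
the bundle price would have to roughly halve (to ~PHP 568k) to reach the
threshold. Covering every eligible patient nationally would cost an
extra ~PHP 13.9 billion in year one. `her2cea run-psa` adds the
Monte-Carlo view (PSA-mean ICERs are lower, ~PHP 388k/QALY, because the
heavily right-skewed death-probability distributions raise mean survival
in both arms), and `her2cea run-dsa` writes tornado and two-way tables.
Each command accepts `--config` (parameter YAML; defaults to the
packaged table), `--seed`, `--perspective` and `--outdir`, and writes
CSV tables, plots and a JSON manifest.

As a library:

```python
from her2cea import table1_fixture, deterministic_results, Perspective

table = table1_fixture()
trast, chemo, ce = deterministic_results(table, Perspective.HEALTHCARE)
print(f"{ce.icer_per_qaly:,.0f} PHP/QALY")   # 502,052 PHP/QALY
```

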