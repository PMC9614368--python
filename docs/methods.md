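# Methods

`pgxcea` models the health-economic consequences of pre-emptive
pharmacogenomic (PGx) screening before clozapine initiation in
treatment-resistant schizophrenia.  Clozapine-induced agranulocytosis/
granulocytopenia (CIAG) forces discontinuation and a switch to a less
effective substitute antipsychotic; a genetic panel (HLA-DQB1 126Q +
HLA-B 158T, plus the SLCO1B3-SLCO1B7 intronic SNP rs149104283) identifies a
subset of patients at elevated risk, in whom closer monitoring and early
temporary cessation can avert part of that risk.

## Decision model

Two mutually exclusive strategies are compared from a third-party payer
perspective over 10 years:

* **Standard of care** — all patients start clozapine under the usual
  blood-monitoring schedule; CIAG occurs with 10-year cumulative risk
  `p = 3.43%`.
* **PGx-guided** — all patients are genotyped once (£110) before starting
  clozapine.  Test-positive patients still receive clozapine; the only
  modelled effect of a positive test is that destined CIAG cases flagged by
  the panel are averted with probability 30% (the prevention rate).  The
  cumulative incidence therefore falls to
  `p · (1 − sensitivity × prevention_rate)`.

Panel aggregation assumes independent carriage: union sensitivity
`1 − Π(1 − sᵢ)` and product specificity `Π specᵢ`, giving 43.0% / 86.9% for
the combined panel.  Because test-positive non-destined patients receive
identical care and costs, panel **specificity never enters the cohort
dynamics** — the ICER is structurally invariant to it, and the one-way
sensitivity analysis confirms a flat line.  The number needed to genotype
is `100 / (prevalence% × sensitivity)`, rounded to the nearest integer.

## Markov cohort engine

States: `ON_CLZ_AT_RISK`, `ON_CLZ_SAFE`, `ON_SUBSTITUTE` (absorbing; no
rechallenge, no death state).  Cycle length one month, 120 cycles.  The
cumulative incidence is spread over an initial **risk window** as a
constant per-cycle hazard `h` solving `1 − (1 − h)^window = incidence`;
after the window the remaining clozapine users become permanently safe.

Per-cycle rewards: clozapine states accrue drug cost
(£1.23/day × 30.4375 days) plus blood-monitoring cost (£10.6/cycle) and
utility 0.693/12; the substitute state accrues £5.11/day × 30.4375 and
utility 0.560/12 (substitutes require no monitoring).  A CIAG transition
adds a one-off £469.48 treatment cost; the transition cycle takes the
destination state's reward (no half-cycle correction).  All cycle-` t`
rewards are discounted by `(1.035)^(−t/12)`; the genetic test is paid
undiscounted at cycle 0.

**Risk-window calibration.**  The source analysis does not report how CIAG
events were distributed in time, and the ICER depends strongly on that
choice: events concentrated in the first months maximise the time spent on
the (cheaper, higher-utility) substitute-avoidance benefit, while events
spread over the whole horizon shrink it.  With the published inputs the
deterministic ICER ranges from ≈£12,400 (5-cycle window) to >£30,000
(hazard uniform over all 120 cycles).  A **36-cycle (3-year) window**
simultaneously reproduces the published base-case ICER (£16,329 vs
£16,215), the augmented-panel scenario ICER (£11,652 vs £11,819), the
scenario PSA mean QALY (5.8280 vs 5.83134) and the entire RR × MAF ICER
grid within ±2%, and is therefore the default; it is configurable
(`ciag_risk_window_cycles`) and the `reproduce` pipeline emits a one-way
sweep of it (`dsa_risk_window.csv`).  The below-threshold conclusion
(ICER < £30,000/QALY) holds for any window up to ≈5 years.

A minor inconsistency in the source results is accepted as-is: the
published scenario *total* cost (£4,278/patient) suggests monitoring cost
was excluded from totals, while the published ICERs are only consistent
with monitoring cost accruing during clozapine use.  The ICER-consistent
structure is used; per-strategy totals here are ≈£1,000 higher than the
printed total, with no effect on any incremental quantity.

## Probabilistic sensitivity analysis

100,000 Monte Carlo draws from the published distributions — gamma
(shape, rate) for costs: CIAG treatment Γ(4, 0.0085), clozapine/day
Γ(37.8, 30.75), substitute/day Γ(104.4, 20.44); beta for utilities
(575, 255) and (86, 67), prevention rate (24.9, 58.1), panel sensitivity
(169.13, 223.87) and specificity (15531.77, 2342.23).  CIAG prevalence,
genetic-test cost and monitoring cost are fixed.  Each distribution's
analytic mean is checked against its point estimate (≤1% relative) at
registry construction.  Cost-effectiveness at willingness-to-pay λ is
`P(λ·ΔQALY − ΔCost > 0)` (incremental net monetary benefit), evaluated on
a £0–50,000 grid for the CEAC.  For panels whose uncertainty is unreported
(HLA-only 0.36/0.89; augmented scenario panels) sensitivity/specificity
are held fixed while every other distribution samples.  Sampling is fully
vectorised on one seeded generator with a fixed parameter order, so runs
are bitwise reproducible.

Overrides in a configuration file re-centre the affected distribution
shape-preservingly (gamma keeps its shape parameter, beta its
concentration); a boundary mean (0 or 1) degenerates to a point mass.

## Undetected-variant scenarios and power

A hypothetical variant with carrier relative risk RR and minor allele
frequency MAF implies screening performance under a **dominant carrier
model**: carrier frequency `q = 1 − (1 − MAF)²`, baseline risk
`k = prevalence / (q·RR + 1 − q)`, sensitivity `q·RR·k / prevalence`,
specificity `1 − q·(1 − RR·k) / (1 − prevalence)`.  This convention
reproduces the published augmented-panel values (56.8% / 78.9%) to within
0.2 percentage points.  Scenario CEAs add the variant to the base panel by
the union rule and price the extended test at £120 (midpoint of the
£110–£130 band).

Association power uses the 1-df Cochran–Armitage trend test: HWE genotype
frequencies, per-genotype relative risks anchored to the disease
prevalence, case/control genotype frequencies by conditioning, and the
normal approximation with separate null (pooled) and alternative
variances — the construction behind standard GWAS power calculators.  Four
genetic models are available (`dominant`, `multiplicative`, `additive`,
`recessive`).

**Planning convention.**  The published minimum-case grid cannot be
reproduced with the consortium's 13,553 fixed controls: that control pool
gives >99% power at 229 cases for an RR=3/MAF=10% variant under any
standard model, and would imply minimum case counts roughly half the
published ones.  The published counts scale as `(ln RR)⁻²` across rows and
are matched by a **dominant-model trend test with two controls per case**
(anchor cell: 231 vs published 230; power(229 cases) = 0.796 ≈ 0.80;
10 of 15 grid cells within ±10%).  That planning convention
(`control_ratio = 2`) is therefore the default for `PowerQuery`;
fixed-control mode (`control_ratio=None`) is retained.  Residual
discrepancies remain at the grid extremes (−16% at MAF=1%, +11% at
RR=2/MAF=10%): the published grid's MAF-scaling is flatter than binomial
information allows, so the unreported calculator settings cannot be fully
recovered; the full grid is asserted at a ±20% envelope and the qualitative
orderings hold everywhere.

## Microsimulation oracle

`simulate_cohort` draws individual trajectories with exactly the cohort
model's structure: destined status at the prevalence, test result via
sensitivity / 1−specificity, prevention among destined true positives
(PGx arm), event cycle from the truncated-geometric distribution implied
by the per-cycle hazard, and the same rewards and discounting.  Sample
means converge to the cohort expectations by the law of large numbers;
agreement within 3 standard errors at n = 200,000 is a standing test.  The
generator emulates the model's assumptions only — real cohorts would add
covariate heterogeneity (age, sex, ancestry, dose), time-varying
utilities, mortality and informative dropout, so passing these tests
validates the implementation, not the model's external validity.
Randomness is counter-based (Philox) with index-aligned vector draws, so
patient *i* depends only on (seed, *i*).

## Numerical choices and limitations

* Days per cycle 365.25/12 = 30.4375 converts daily drug costs.
* Discounting compounds monthly, `(1+r)^(−t/12)`, rewards at t = 1..120;
  the undiscounted-vs-discounted gap and the zero-prevalence annuity are
  closed-form test oracles.
* ICER classification: dominant / dominated flags when the increment signs
  disagree; undefined when ΔQALY = 0 (within 1e-12).
* Minimum case counts by bisection on the (monotone) power function.
* Known limitations: no mortality or relapse states, no correlation
  between sampled parameters (sensitivity and specificity independent), no
  linkage between panel components, prevention rate treated as
  variant-independent, and the 10-year horizon is not extrapolated.
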