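# pgxcea

Cost-effectiveness analysis of pharmacogenomic (PGx)-guided clozapine
administration.

Clozapine is the antipsychotic of choice in treatment-resistant
schizophrenia, but 1–3% of patients develop clozapine-induced
agranulocytosis/granulocytopenia (CIAG) and must switch to a less
effective substitute.  Genetic risk variants — the HLA-DQB1 (126Q) /
HLA-B (158T) amino-acid pair and the SLCO1B3-SLCO1B7 intronic SNP
rs149104283 — identify a high-risk subset in whom intensified monitoring
can avert part of that risk.  `pgxcea` asks whether genotyping everyone
before the first dose is worth it, and what further (currently
undetected) risk variants would add.

The package is aimed at health-economics and psychiatric-genetics
researchers.  It provides:

* **Panel aggregation** — union sensitivity `1 − Π(1 − sᵢ)`, product
  specificity `Π specᵢ`, confusion fractions and the number needed to
  genotype `100/(prevalence% × sensitivity)`.
* **A monthly Markov cohort model** (states `ON_CLZ_AT_RISK`,
  `ON_CLZ_SAFE`, `ON_SUBSTITUTE`) computing discounted costs and QALYs per
  strategy and the incremental cost-effectiveness ratio
  `ICER = ΔCost/ΔQALY` against the UK £30,000/QALY threshold.
* **Probabilistic sensitivity analysis** — 100,000 vectorised Monte Carlo
  draws from the published gamma/beta distributions, cost-effectiveness
  acceptability curves and incremental scatter plots, plus one-way
  deterministic sweeps.
* **Genetic power scenarios** — Cochran–Armitage trend-test power,
  minimum case counts for 80% power at genome-wide significance over an
  RR × MAF grid, and scenario CEAs for hypothetical "undetected" risk
  variants whose screening performance is derived from (RR, MAF) under a
  dominant carrier model.
* **A patient-level microsimulation** that serves as a brute-force oracle
  for the cohort engine and generates synthetic patient tables.

See `docs/methods.md` for the model, its assumptions and the calibration
of structural choices.

## Worked example

```python
import pgxcea as pg

params = pg.ModelParameters()          # published point estimates
panel = pg.base_panel()                # HLA + SLCO combined panel

print(panel.sensitivity, panel.specificity)
# 0.42976 0.86864                      -> 43.0% / 86.9%

print(pg.number_needed_to_genotype(3.43, 0.43))
# 68                                   patients genotyped per averted case

ce = pg.compare_strategies(params, panel)
print(round(ce.delta_cost, 2), round(ce.delta_qaly, 5), round(ce.icer))
# 67.77 0.00415 16329                  -> ICER ~ GBP 16,329/QALY, below 30,000

reg = pg.default_registry()
draws = pg.run_psa(params, reg, 100_000, seed=42)
print(pg.probability_cost_effective(draws, 30_000))
# 0.86773                              -> ~87% probability of cost-effectiveness

variant = pg.variant_sens_spec(rr=3.0, maf=0.05)
scenario = pg.scenario_cea(params, reg, panel, variant, seed=44)
print(round(scenario.panel.sensitivity, 3), round(scenario.ce.icer))
# 0.569 11652                          -> a found RR=3/MAF=5% variant lifts
#                                         sensitivity to 56.9% and cuts the ICER
```

Interpretation: screening every clozapine starter costs £110/patient but
averts 30% of panel-detected CIAG cases, keeping those patients on the
cheaper, higher-utility drug; at the published inputs the extra cost per
quality-adjusted life-year gained is ≈£16,300, well inside the UK
willingness-to-pay threshold.

The same analyses are available from the shell:

```bash
pgxcea perf --variants hla:0.360:0.890,rs149104283:0.109:0.976
pgxcea run --strategy both --out results/
pgxcea psa --iters 100000 --seed 42 --out results/
pgxcea power --rr 3 --maf 0.10 --n-cases 229
pgxcea simulate --n 200000 --seed 7 --strategy pgx --out patients.csv
pgxcea reproduce --iters 100000 --seed 42 --out results/
```

`pgxcea reproduce` regenerates the full result set (headline summary,
CEAC/scatter, one-way sensitivity analyses, the RR × MAF grid and
figures) with a run manifest for reproducibility.

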