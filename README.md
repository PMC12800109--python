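# anemecon

Health-economic model of algorithmic (digital-avatar) anemia management for
adult in-center hemodialysis patients, from the U.S. Medicare payer and
dialysis-provider perspectives. The package provides:

- **parameters** — a typed registry of every model input with embedded
  defaults (age-band incidence/mortality/costs, clinical effect sizes,
  economic and provider inputs), a flat YAML configuration overlay, and
  calibrators that turn printed summaries (95% CI, IQR, min/mode/max) into
  distribution parameters.
- **effects** — the evidence-synthesis chain mapping a hemoglobin-SD
  reduction to a mortality hazard ratio (exponentiation of the per-1 g/dL
  HR) and an avoided-hospitalization rate (Chinn SMD conversion → OR
  rescaling → OR-to-RR at the baseline annual probability), plus the
  in-range utility-premium scenario.
- **markov** — a two-state (alive/dead) cohort engine with age-band
  mortality and costs, hospitalization accrual among the alive, life-table
  half-cycle correction, mid-cycle discounting, and a <0.1%-alive stopping
  rule.
- **economics** — ICERs with dominance handling, net monetary benefit
  (`NMB = λ·ΔE − ΔC`), its annualization, and a WTP threshold proxied by
  the cost-utility ratio of dialysis versus no treatment.
- **financial** — provider net financial impact (ESA savings + avoided
  quality-program payment reduction − implementation costs, with three cost
  scenarios) and payer budget impact for the incident cohort.
- **uncertainty** — one-way deterministic sensitivity (tornado) and a
  seeded Monte Carlo probabilistic sensitivity analysis drawing full
  parameter sets from Beta-PERT / lognormal / beta / gamma / uniform /
  normal distributions.

## CLI

All subcommands accept `--config <yaml>` (flat key-value overrides),
repeatable `--set key=value`, and `--out-dir`. Every run writes a
`manifest.json` (timestamp, config digest, seed, outputs).

```sh
anemecon run-cea --out-dir out/cea            # lifetime cost-utility + traces
anemecon run-cea --utility-premium            # in-range utility scenario
anemecon run-nfia --scenario full             # provider net financial impact
anemecon run-bia                              # payer budget impact
anemecon dsa                                  # tornado table (NMB)
anemecon psa -n 1000 --seed 20260103          # Monte Carlo PSA
```

Example configuration file:

```yaml
discount_rate: 0.02
utility_hd: 0.74
esa_price_per_ug: 1.5
```

## Notes

The lifetime cost/QALY magnitudes depend on the starting-age construction
of the cohort, which is configurable (`age_bands`, cohort weights derived
from incidence × Medicare share); headline *relative* results — treatment
dominance, tornado ordering, non-negative NMB across PSA draws — are
invariant to admissible cohort choices and are asserted in the test suite.
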