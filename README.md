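# psmkit

A partitioned-survival cost-utility modelling toolkit for oncology health
technology assessment, built around the economic evaluation of first-line
dostarlimab plus carboplatin-paclitaxel (DSR+CP) versus placebo plus
carboplatin-paclitaxel (PBO+CP) for primary advanced or recurrent
endometrial cancer, with mismatch-repair (dMMR/pMMR) biomarker subgroups.

It is written for health economists and HTA analysts who need the whole
pipeline behind such an analysis as inspectable, testable code rather than
a spreadsheet or a proprietary decision tree: survival extrapolation,
curve reconstruction, cohort simulation, discounted accrual, and
uncertainty analysis.

## The model

A three-state partitioned survival model (PSM). State membership at time
*t* comes directly from the two survival curves of each arm:

    PFD(t)   = S_PFS(t)                  progression-free disease
    PD(t)    = S_OS(t) − S_PFS(t)        progressive disease
    Death(t) = 1 − S_OS(t)

evaluated at the midpoints of 21-day cycles over a 16-year horizon.
Costs (drug acquisition with a 6-cycle induction and 3-year maintenance
cap, routine follow-up, adverse-event management, subsequent therapy,
best supportive care) and quality-adjusted life-years
(QALY_i = [PFD_i·u_PFS + PD_i·u_PD]·Δt) accrue per cycle and are
discounted at 3% per year. The decision statistic is the incremental
cost-effectiveness ratio ICER = ΔC/ΔQ against a $90,000/QALY
willingness-to-pay threshold, with one-way deterministic sensitivity
analysis (tornado) and 1,000-iteration probabilistic sensitivity analysis
(cost-effectiveness acceptability curves via net monetary benefit).

Supporting machinery, each its own module:

| module | what it does |
|---|---|
| `survdist` | six parametric survival families (exponential, Weibull, Gompertz, log-logistic, log-normal, generalized gamma), beta-PERT and moment-matched gamma/beta PSA distributions |
| `km_tools` | Kaplan-Meier estimation; Guyot-style pseudo-IPD reconstruction from digitized curve points + numbers-at-risk |
| `fitsel` | censored maximum-likelihood fitting, AIC/BIC model selection |
| `psm_core` | the cohort engine: occupancy, background-mortality blending, costing, discounting, ICER |
| `uncertainty` | one-way DSA, Monte Carlo PSA, CEAC, CE-plane summaries |
| `elicitation` | Delphi-round outlier fences, dispersion statistics, equal-weight pooling of expert three-point estimates |
| `synthetic_data` | seed-deterministic fixtures: simulated trial IPD, emulated digitization, a miniature end-to-end config |
| `io_cli` | YAML config schema with per-value source annotations, the packaged base cases, the `psmkit` command line |

See `docs/methods.md` for the model assumptions, parameter defaults and
their rationale, and known limitations.

## Worked example

Run the packaged overall-population base case from Python:

```python
from psmkit import run_base_case

res = run_base_case("overall")
print(f"DSR+CP: cost ${res.intervention.cost:,.0f}, {res.intervention.qaly:.3f} QALYs")
print(f"PBO+CP: cost ${res.comparator.cost:,.0f}, {res.comparator.qaly:.3f} QALYs")
print(f"ICER: ${res.icer:,.0f}/QALY")
```

prints

```
DSR+CP: cost $393,227, 3.502 QALYs
PBO+CP: cost $157,937, 2.181 QALYs
ICER: $178,102/QALY
```

Read: over a lifetime horizon the dostarlimab arm accrues 1.32 extra
QALYs at $235,290 extra cost, i.e. $178,102 per QALY gained — more
favorable in the dMMR subgroup and far less favorable in the pMMR
subgroup (run `"dmmr"` / `"pmmr"`), so the value case rests on biomarker
selection. `res.intervention.ledger` holds the full per-cycle audit trail
(occupancy, every cost component, QALYs, discount factors).

The same analyses from the shell:

```sh
psmkit base-case --population dmmr --out dmmr.json
psmkit dsa --population overall --out tornado.csv
psmkit psa --population overall --n 1000 --seed 7
psmkit fit --ipd my_ipd.csv                 # rank all six families by AIC/BIC
psmkit reconstruct --points pts.csv --risk risk.csv
psmkit elicit --estimates panel.csv
```

The tornado's dominant bar is the dostarlimab acquisition cost, followed
by the two health-state utilities — the drug price, not the clinical
parameters, drives the decision.

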