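# Methods

`psmkit` implements a three-state partitioned survival model (PSM) for
cost-utility analysis of a first-line oncology regimen against a
chemotherapy comparator, together with the supporting machinery such an
analysis needs: parametric survival mathematics, pseudo individual-patient-
data (IPD) reconstruction from digitized Kaplan-Meier curves, censored
maximum-likelihood fitting with AIC/BIC selection, deterministic and
probabilistic sensitivity analysis, and structured-expert-elicitation
processing. This note records the model, its assumptions, the defaults and
why they were chosen, and what the synthetic test fixtures do and do not
establish.

## The partitioned survival model

Patients occupy one of three mutually exclusive states: progression-free
disease (PFD), progressive disease (PD), and death. Occupancy is read
directly off two survival curves rather than derived from transition rates:

- PFD(t) = S_PFS(t)
- PD(t) = S_OS(t) − S_PFS(t)
- Death(t) = 1 − S_OS(t)

where S_PFS and S_OS are the progression-free-survival and overall-survival
functions of the arm. Where a fitted S_PFS crosses above S_OS (possible
because the two endpoints are extrapolated independently), PFD is clamped to
S_OS and the violation magnitude is logged.

Occupancy is evaluated on a discrete cycle grid — 21-day cycles over a
16-year horizon (ages 64-80, the cohort's median age to local female life
expectancy), 278 cycles — at **cycle midpoints** (a half-cycle correction).
The evaluation point is configurable (`evaluation="start"`) because
published cycle-based models are frequently silent on this convention and
the difference matters at coarse grids.

New progression in cycle i is pf_{i−1} − pf_i minus the share of that
cycle's deaths attributable to the PFD state, apportioned proportionally to
the previous cycle's occupancy; it is floored at zero.

### Background mortality

Disease-specific OS can be blended with general-population mortality by a
hazard-max rule: over each cycle the all-cause cumulative-hazard increment
is max(ΔH_OS, ΔH_background), so the modelled cohort never outlives the
general population. Background mortality is a user-supplied (age, annual
rate) step table. **The packaged base case ships with zero background
mortality**: the national life-table values behind the original analysis are
not published, and silently substituting another country's table would
change results without provenance. A clearly labelled synthetic table
(`configs/background_mortality_synthetic.csv`) is included for exercising
the blending code.

## Survival distributions

Six families, in the parameterizations standard in survival extrapolation:

| family | parameters | survival function |
|---|---|---|
| exponential | rate r | exp(−rt) |
| Weibull | scale λ, shape k | exp(−(t/λ)^k) |
| Gompertz | shape η, rate b | exp(−(b/η)(e^{ηt}−1)) |
| log-logistic | scale α, shape β | 1/(1+(t/α)^β) |
| log-normal | µ, σ | 1 − Φ((ln t − µ)/σ) |
| generalized gamma | µ, σ, Q | Prentice location/scale/shape form |

Two conventions deserve emphasis. The Gompertz `rate` b is the hazard at
t = 0 (h(t) = b·e^{ηt}); published parameter tables sometimes label it
"scale", which it is not. The generalized gamma uses the (µ, σ, Q) form
with the lognormal recovered in the Q → 0 limit; the implementation
switches to the lognormal expressions below |Q| < 1e−5 to avoid the
indeterminate form. Q = 1 recovers the Weibull, a relation used as a test
oracle.

Every distribution carries an explicit `time_unit` (default months) and can
be converted between units exactly; the engine converts its day-based cycle
grid into each distribution's unit, so a mis-declared unit cannot silently
rescale a curve. The packaged curve parameters are declared in months,
consistent with the medians they imply (e.g. the comparator-arm lognormal
PFS median exp(2.2501) ≈ 9.5 months).

Quantiles are closed-form everywhere except the generalized gamma, which
uses the inverse regularized incomplete gamma function; sampling is by
inverse transform, so one uniform stream drives every family identically.
Hazards where S(t) has underflowed to zero return `inf` (a documented
sentinel), never NaN.

## Costing and QALY accrual

Each arm is a `StrategySpec`. All per-cycle monetary inputs are stated per
21-day **reference** cycle; if the model is evaluated on a different grid
the rates are rescaled, and treatment-window boundaries (end of induction,
the 3-year maintenance cap) are charged pro rata within the boundary cycle,
making totals insensitive to the discretization (verified: 21-day vs 7-day
totals agree to well under 1%).

Per cycle, an arm accrues:

- **drug acquisition** while progression-free: induction regimen (index
  drug, where applicable, plus both chemotherapy backbones) for the first
  6 cycles, then maintenance index drug up to 3 years. Maintenance dosing
  at 1000 mg every 6 weeks delivers the same mg/week as 500 mg every
  3 weeks, so the single per-cycle acquisition cost applies unchanged.
- **routine follow-up** while progression-free. Follow-up is charged in PFD
  only: progressed patients' routine care is carried by the subsequent-
  therapy and best-supportive-care components. (Charging follow-up in both
  alive states was rejected on internal-consistency grounds: at the
  packaged per-cycle price it alone would exceed a comparator arm's total
  published cost.)
- **best supportive care** per PD cycle, for the fraction of progressors
  who do not take active subsequent therapy.
- **subsequent therapy** as a lump charged in the cycle of progression:
  uptake × Σ_options share × per-cycle cost × duration. Durations default
  to the published median PFS of the referenced subsequent-line trials
  (pembrolizumab 13.1 months; lenvatinib + pembrolizumab 7.2 months;
  single-agent doxorubicin 3.8 months). Uptake defaults to 0.60 in the
  comparator arm and 0.40 in the intervention arm (whose progressors
  receive chemotherapy only, reflecting the no-retreatment-with-
  immunotherapy assumption); the trial's actual utilization rates are not
  published, so these are documented assumptions exposed as ordinary
  config values and varied in sensitivity analysis.
- **adverse events**: the eight grade ≥3 events with ≥5% incidence, each an
  expected one-off management cost and one-off disutility charged wholly in
  the first cycle (first-line toxicity).

QALYs accrue as (PFD·u_PFS + PD·u_PD) × cycle length in years, minus the
one-off AE disutility burden in cycle 1. Life-years are undiscounted;
costs and QALYs are discounted at a discrete 3% annual rate evaluated at
the cycle midpoint: PV = Σ x_i (1.03)^{−t_i}.

The ICER is ΔC/ΔQ, reported only when ΔQ ≠ 0, with strict-dominance flags.

## Sensitivity analysis

Every uncertain input lives in one flat registry (name → base, lo, hi, PSA
family, role, source annotation). One-way DSA reruns the full two-arm model
at each parameter's bounds with all others at base and sorts by ICER spread
(tornado order); if a variation drives ΔQ across zero the ICER is unstable
and the row falls back to a net-monetary-benefit spread, flagged. Bounds
follow the inputs: elicited costs use the across-expert IQR, tariffed drug
costs ±30%, probabilities and utilities ±20%.

PSA is second-order Monte Carlo (default 1,000 iterations): all parameters
drawn jointly and independently each iteration — no correlation structure
is asserted because none is reported for the inputs — and the full model
re-evaluated. Distribution construction: gamma and beta by method of
moments with mean = base and sd = (hi − lo)/(2·1.96), i.e. the stated range
is read as an approximate 95% interval (the z multiplier is configurable);
beta-PERT parameters from the (lo, base, hi) triple; disutilities sampled
on the magnitude scale with the sign restored; an infeasible beta variance
is shrunk to the support with a warning. The per-draw decision statistic is
net monetary benefit (NMB = WTP·ΔQ − ΔC) rather than the ICER, which is
sign-ambiguous when ΔQ changes sign; a draw with NMB exactly 0 counts as
not cost-effective. CEACs report P(NMB > 0) over a WTP grid; in the
two-strategy setting the comparator curve is the complement.

## Expert elicitation

Three-point (min, most-likely, max) cost estimates over two Delphi rounds.
Between rounds each statistic is screened independently against Tukey
fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR], values exactly on a fence not
flagged; quartiles use linear interpolation (the numpy default — the
convention is stated because quartile definitions differ across software).
Flagging is report-only; revision is a human act. Final-round estimates are
pooled by equal-weight linear averaging of each statistic (means preserve
the ordering, so the pooled triple is always PERT-valid) and handed to the
beta-PERT parameterization, whose mean (min + 4·mode + max)/6 is the
base-case value.

## Pseudo-IPD reconstruction

`reconstruct_ipd` implements a Guyot-style interval allocation: within each
numbers-at-risk interval, an iteratively adjusted censoring count (spread
uniformly over the interval) and product-limit-ratio event counts are
chosen so the implied at-risk count matches the published risk table
exactly at every interval start. Digitized *times* are treated as exact and
*survival readings* as noisy, so monotonicity repair (running minimum)
touches only the survival axis. Two numerical details matter in practice:

- a fractional-event carry accumulates the rounding error of the per-click
  integer allocation, so reconstructed totals track the cumulative target
  instead of drifting;
- digitized clicks rarely fall exactly on risk-table times, so a virtual
  click is interpolated at each boundary; without it, survival drops that
  straddle a boundary are misattributed as censoring.

Reconstruction reproduces the digitized curve to ≲0.005 at the digitized
times (n = 300, 40-point grid). Between grid points no algorithm can beat
the digitization's own step resolution (~0.04-0.06 at that density); the
everywhere-error falls to ~0.02 at a 120-point grid, and the test suite
checks this refinement behaviour.

## Fitting and selection

`fit_mle` maximizes the right-censored log-likelihood Σ_events ln f(t) +
Σ_censored ln S(t), by quasi-Newton (L-BFGS-B) on transformed scales — log
for positivity-constrained parameters, identity for locations and the
generalized-gamma shape — from five deterministic multi-starts around
moment-based initial values, because the Gompertz and generalized-gamma
surfaces are ridge-prone. Convergence is reported honestly; unconverged
fits are excluded from selection with a warning. Selection ranks by AIC
(2k − 2lnL), ties broken by BIC (k ln n − 2lnL), then by fewer parameters,
and emits fitted-vs-KM overlay data for visual validation. Right censoring
only; no truncation, covariates or stratification (arms are fitted
separately).

## Synthetic data

The generators exist so every pipeline stage is testable without any
external download.

- `simulate_trial_ipd` couples progression and death through a shared
  uniform: P = Q_PFS(U), D = max(P, Q_OS(U)). Death never precedes
  progression, and the OS marginal is exact wherever S_OS ≥ S_PFS
  pointwise (true for all packaged configurations). An additive
  post-progression exponential tail was considered and rejected: for
  near-exponential OS targets the resulting hypoexponential marginal is
  irreducibly ~0.1 away in Kolmogorov-Smirnov distance. If the OS curve is
  materially stochastically smaller than the PFS curve the pair cannot
  define a PSM cohort and an error says so. The coupling is comonotone —
  maximally rank-correlated — which real trials are not; tests based on it
  validate marginal behaviour, not joint dependence.
- `emulate_digitization` reads a KM curve at grid times with additive
  Gaussian noise (violations of monotonicity deliberately left in — repair
  is the consumer's job) and copies the risk table exactly, as a human
  digitizer copies the printed numbers-at-risk row. It does not emulate
  pixel-level scanning artefacts.
- `make_toy_config` is a fully deterministic miniature two-arm model
  (3-year horizon, exponential curves, two adverse events) small enough
  that an independent spreadsheet-style cycle sum reproduces the engine to
  1e−9; it backs the engine-oracle and degenerate-PSA tests.

All generators are seed-deterministic.

## Problem sizes and numerical choices

Tests run at deliberately modest sizes — n = 2000 for parameter recovery,
n = 300 subjects / 40-120 grid points for reconstruction roundtrips,
200-1000 PSA iterations — sizes at which the checked properties are
already sharp. Key tolerances: occupancy conservation 1e−12; hazard-
integral vs −ln S equivalence 1e−4; quantile/survival inversion 1e−6 or
better; engine vs brute-force oracle 1e−9; PSA degenerate-draw equality is
bit-for-bit. Monetary inputs are carried exactly as printed in the config
files and converted once at load.

## Known limitations

- The packaged base case reproduces the *structure* of the original
  analysis and every input it published, but several inputs behind its
  headline table were not published (subsequent-therapy utilization and
  durations, national life-table rates, the half-cycle and time-unit
  conventions). Under the documented defaults the overall-population
  incremental QALY difference lands within the stated reproduction
  tolerance, the tornado's dominant bar (index-drug acquisition cost), the
  cost-and-effect direction in all three populations, and the ICER
  gradient across biomarker subgroups (dMMR < overall < pMMR) all
  reproduce; absolute per-arm totals and hence the absolute ICER level do
  not, and the acceptance suite reports those divergences rather than
  hiding them. Users with access to the unpublished inputs can supply them
  through the ordinary config surface.
- Partitioned survival models have no progression→death causal pathway:
  PD occupancy is a difference of marginals, so interventions on one curve
  do not propagate to the other.
- No treatment-waning, cure-fraction, spline or mixture extrapolations;
  no interval censoring; no EVPI; no parameter correlations in PSA.
- Currency is carried as given (2025 USD in the packaged configs) with no
  inflation or conversion machinery.
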