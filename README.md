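# ckdtraj

Process-mining discovery and multistate Markov modelling of eGFR stage
trajectories, for pharmacoepidemiologists studying chronic kidney
disease (CKD) progression from routine laboratory data.

## The problem

Observational drug-safety studies of CKD usually reduce longitudinal
kidney function to a single endpoint (e.g. "30% eGFR decline").
`ckdtraj` instead keeps the whole trajectory: serum-creatinine
measurements are converted to eGFR (CKD-EPI 2009, no race term),
discretised into KDIGO G stages, and each patient becomes a
time-ordered sequence of stage observations.  Two analyses share that
substrate:

* **Process discovery** builds an annotated directly-follows graph
  ("process indicator"): nodes are stages (plus artificial
  `start`/`end`), edges connect consecutive observations and carry
  absolute counts, relative frequencies and median/IQR sojourn times.
* **Multistate modelling** fits a continuous-time Markov chain over the
  merged stages G1/2 ↔ G3 ↔ G4/5, panel-observed at the measurement
  times, with proportional transition intensities

      q_rs(x) = q_rs(0) · exp(β_rs′ x),

  so `exp(β₁)` is the covariate-adjusted hazard ratio of the exposure
  (e.g. PPI vs H2B new use) for each transition, with 95% Wald CIs.

Cohorts follow the new-user / active-comparator design: entry at the
first-ever dispensation of either drug class inside an enrolment
window, a washout year with no prior use, a baseline eGFR within 183
days before the index date, and eligibility 18+ years with baseline
eGFR in [15, 60).

Because the registry data such studies use cannot be shared, the
package ships a synthetic-cohort generator (`ckdtraj.simulate`) with
known ground truth: Gillespie-simulated latent stage dynamics,
irregular gamma-distributed measurement gaps, administrative
censoring, and registry-shaped CSV output that passes the full
pipeline.

## Worked example

```sh
ckdtraj pipeline --preset table1-defaults --n 2000 --seed 11 --out out/
```

simulates a 2000-patient cohort (≈95% exposed, baseline stages
G3A/G3B/G4), selects the cohort, builds the merged event log, derives
the process indicator (`out/discovery/indicator.dot`, render with
Graphviz) and fits the multistate model, printing:

```
Multistate model fit (proportional transition intensities)
  patients: 2000   observation pairs: 34586
  log-likelihood: -19096.571   converged: True (45 iterations)
  covariates: exposure

  transition       q0/month  HR (exposure)           95% CI
  G1/2 -> G3         0.0990           0.90     (0.66, 1.23)
  G3 -> G1/2         0.0704           0.97     (0.75, 1.25)
  G3 -> G4/5         0.0543           1.58     (1.18, 2.13)
  G4/5 -> G3         0.1154           1.19     (0.86, 1.64)
```

`q0/month` is the baseline (comparator) monthly transition intensity;
each hazard ratio compares exposed vs comparator for that transition.
The generative truth of this preset sets the exposure effect on
progression G3 → G4/5 to HR 1.75 — the estimate 1.58 (1.18, 2.13) is
within sampling noise of it at this cohort size and a 95/5 exposure
split.  The other transitions' true HRs (0.92, 0.95, 1.13) are close
to null.  Every stage writes a `manifest.json` (input checksums,
options, package version); identical inputs and seed give
byte-identical outputs.

Library use mirrors the CLI:

```python
from ckdtraj import simulate, cohort, eventlog, discovery, multistate

cfg = simulate.make_preset("recovery-benchmark", seed=1)
log, covariates, truth = simulate.simulate_panel(cfg)
result = multistate.fit(log, covariates)
print(result.summary())
```

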