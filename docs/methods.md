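# Methods

## Scientific setting

`ckdtraj` analyses chronic-kidney-disease (CKD) progression from
routinely collected serum-creatinine measurements in a
pharmacoepidemiological new-user / active-comparator design: patients
entering at their first dispensation of an exposure drug class (PPI,
proton pump inhibitors) or a clinically interchangeable comparator
(H2B, H2 blockers).  Kidney function is summarised as eGFR via the
CKD-EPI 2009 creatinine equation and discretised into KDIGO G stages;
the analysis object is the per-patient, time-ordered sequence of stage
observations over follow-up.  Two complementary views are computed:

1. **Process discovery** — a descriptive directly-follows graph of the
   stage sequences with frequency and sojourn-time annotations.
2. **Multistate modelling** — a covariate-adjusted continuous-time
   Markov model over the coarsened stage space, yielding per-transition
   exposure hazard ratios.

## Staging

CKD-EPI 2009 without the race coefficient (it is omitted, not merely
defaulted off, because the target registries do not record ethnicity).
KDIGO bands are half-open intervals `[lower, upper)` on the continuous
eGFR scale — `G5 [0,15), G4 [15,30), G3B [30,45), G3A [45,60),
G2 [60,90), G1 [90,∞)` — so boundary values such as 60.0 are assigned
deterministically (60.0 → G2).  Creatinine is consumed in mg/dL; a
documented µmol/L conversion (÷ 88.4) is applied at the I/O boundary
only.  The coarse space merges G1/G2 → "G1/2", G3A/G3B → "G3",
G4/G5 → "G4/5".

## Cohort selection

A new user is a patient whose first-ever dispensation of either class
falls inside the enrolment window (default 2007-01-01..2010-12-31, with
2006 as washout and follow-up to 2011-12-31).  Patients whose earliest
dispensation date carries both classes are excluded as group-ambiguous:
the design does not define the tie, and exclusion is the conservative
choice.  "Less than 6 months before the index date" is realised as a
strict 183-day window; the baseline eGFR is the latest measurement on
or before the index date within that window.  Eligibility — new user,
baseline measurement present, age ≥ 18, baseline eGFR < 60, baseline
eGFR ≥ 15 — is applied sequentially in that fixed order, making the
exclusion tally disjoint and reproducible.

## Event logs

One month = 30.4375 days.  The trajectory starts at the baseline stage
with event time pinned to 0 (even when the baseline measurement
predates the index date by up to 183 days; intermediate measurements
between the baseline draw and the index are not replayed).  Follow-up
events are measurements strictly after the index date up to the
censoring date (earliest of death, emigration, administrative end).
Multiple measurements on one calendar day are averaged on the eGFR
scale before staging — a symmetric rule that guarantees the strictly
increasing event times the panel likelihood requires.  Merging to the
coarse space preserves events one-to-one; consecutive same-stage
observations become self-loops of the process map.

## Process indicators

Nodes are stages plus artificial `start`/`end`; each patient
contributes one start- and one end-edge, so start out-percentages are
the baseline stage distribution.  Edge *relative frequency* on the map
is the edge count over the total out-count of its source node (each
node's out-edges sum to 100%).  The *patient-level* percentage of a
transition — the share of patients experiencing it at least once — is
a separate operation (`transition_summary`), because both conventions
appear in published process maps and conflating them is a recurring
ambiguity.  Sojourn-time medians and quartiles use linear-interpolation
quantiles.  DOT output is deterministic (fixed node order, fixed label
formats), so identical indicators are byte-identical.

## Multistate model

States are the merged stages; the default transition structure is
tridiagonal — `G1/2 ↔ G3 ↔ G4/5` with no direct `G1/2 ↔ G4/5`
intensity.  Observed direct jumps between the extreme stages are
explained by unobserved passage through G3 via the matrix exponential.
Intensities are time-homogeneous and proportional in the covariates,

    q_rs(x) = q_rs(0) · exp(β_rs′ x),

with a common design across transitions and a separate coefficient
vector per transition; the first design column is the exposure
indicator and exp(β₁) its per-transition hazard ratio.  The panel
likelihood is the product over consecutive observation pairs of
`P(Δt; x) = expm(Q(x)·Δt)` entries (states known only at measurement
times; death is censoring, not a state).

**Numerics.**  For each unique covariate row the generator is
eigendecomposed once (batched), giving all `P` entries for that row's
observation gaps in closed form; derivatives of the matrix exponential
are evaluated in the eigenbasis with divided differences
(Kalbfleisch–Lawless), using the confluent limit `t·e^{wt}` when
eigenvalues nearly coincide.  If an eigenvector matrix is
ill-conditioned (condition number > 1e10) the implementation falls
back to `scipy`'s `expm`/`expm_frechet`.  Optimisation is L-BFGS-B on
the mean negative log-likelihood with analytic gradients, gradient
tolerance 1e-8 on that per-observation scale (scale-free, so
convergence behaviour does not depend on cohort size), at most 500
iterations, from a deterministic crude-rate start
(`count(r→s pairs) / months observed starting in r`), β = 0.  Box
bounds `log q ∈ [−20, 5]`, `β ∈ [−10, 10]` keep intensities finite
during line search.  The fit is deterministic given the data.

Transitions never observed as a directly-follows pair are warned
about, their baseline intensity is pinned near zero and their
coefficients fixed at 0; they are flagged `unidentified` and their SEs
reported absent.  Standard errors come from the observed information —
central finite differences of the *analytic* gradient (one
differentiation of an exact quantity, more accurate than differencing
the objective twice) — inverted over the free parameters; Wald 95% CIs
are computed on the log scale, `exp(β₁ ± 1.96·SE)`, with no
multiple-testing adjustment.  Baseline eGFR, when included, enters as
a continuous covariate; age likewise (banded coding is possible by
passing pre-coded columns).

## Synthetic cohorts

The generator emulates the registry data shape: latent stage dynamics
are an exact Gillespie-simulated CTMC with exposure-dependent
intensities; the latent state is observed at irregular times with
gamma-distributed gaps (shape 2; state-independent) up to an
administrative horizon.  Default true monthly intensities,
`q(G1/2→G3)=0.10, q(G3→G1/2)=0.07, q(G3→G4/5)=0.05, q(G4/5→G3)=0.12`,
are plausible for a G3-centred CKD cohort (net downward drift, fast
bounce-back from G4/5 reflecting measurement fluctuation); true
exposure hazard ratios are 0.92, 0.95, 1.75 and 1.13 respectively.

Presets:

* `table1-defaults` — study-scale cohort: n = 12 043, exposure share
  11 486/12 043 ≈ 0.954, baseline full-stage mix 58.2/30.5/11.3
  (exposed) vs 68.6/24.9/6.5 (comparator) over G3A/G3B/G4, denser
  measurements in the exposed group (mean gap 2.0 vs 3.2 months),
  index dates uniform over the enrolment window.  The differential
  observation density reproduces the informative-observation pattern of
  real data but is deliberately *not* modelled in the fit.
* `recovery-benchmark` — validation design: n = 3000, balanced 50/50
  exposure, merged baseline mix 60/30/10, mean gap 2 months for
  everyone, fixed 36-month horizon.  The balanced arms make all
  baseline intensities and effects well identified at moderate n.

Observed values are eGFR drawn uniformly within the band of the latent
stage (with a 0.01 margin below each upper edge so 2-decimal rounding
cannot cross a boundary); an inverse-CKD-EPI helper can back-convert to
creatinine to exercise the staging path.  A single seed fans out to
per-patient substreams, so patient-level draws survive reordering.
The emitted tables satisfy every eligibility criterion by
construction, so the synthetic cohort passes the selection filters
with zero exclusions — a round-trip property the tests assert.

**What the generator does not emulate:** state-dependent measurement
frequency, creatinine assay noise, within-band eGFR autocorrelation,
deaths/emigration (censoring is administrative only), covariate
effects other than exposure, and non-Markov latent dynamics.  Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness to their
violation in real registries.

## Validation studies and problem sizes

The suite validates with: exact oracles (2-state closed-form occupancy
to 1e-10; 3-state matrix exponential vs 1e5 Gillespie paths within 3
binomial SEs); a 50-replicate parameter-recovery study (n = 3000 per
replicate) checking the mean estimated log-HR of every transition is
within ±0.05 of truth; a 200-replicate null study (n = 1000, all true
log-HRs 0) checking 95% Wald CI coverage lies in [90%, 98%]; and a
full-pipeline run of the study-scale preset.  These sizes make the
Monte-Carlo error small relative to the tolerances while keeping a
complete run of the suite on a single CPU in the minutes range.
`scripts/acceptance.py` re-runs the recovery study from scratch with a
caller-supplied seed.

## Known limitations

* Time-homogeneous intensities; no time-varying exposure (use is
  assumed continuous from initiation).
* Death is treated as censoring, not a competing state; if mortality
  is differential by exposure, hazard ratios carry the usual
  independent-censoring caveat.
* Informative observation times (sicker patients measured more often)
  bias panel estimates in real data and are reproducible with the
  simulator's group-specific gaps, but are not corrected in the fit.
* The exclusion tally is sequential; patients failing several criteria
  are counted only at the first.
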