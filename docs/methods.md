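# Methods

This note documents the models, assumptions, defaults and numerical
choices behind `riskscreen`, and what the package's tests do and do not
establish about real screening data.

## The multi-state risk model

Disease is modelled as a continuous-time Markov chain on two-eye
retinopathy grades `R0R0`, `R1R0`, `R1R1` and an absorbing screen-positive
state `SP` (referable retinopathy/maculopathy, ungradable images or other
significant eye disease; once screen-positive a person leaves routine
recall). The default transition structure is "mixed": background
retinopathy may regress (`R0R0 ↔ R1R0`, `R1R0 ↔ R1R1`) and every
observable grade has a direct edge into `SP`, the direct `R0R0 → SP` edge
capturing maculopathy arising without prior background retinopathy. The
structure is an argument everywhere, so sparser or denser graphs can be
swapped in.

Covariates act log-linearly (proportionally) on transition intensities —
the standard link for panel multi-state models — and are centred at
development-sample means, with the centering constants stored in the
fitted model so predictions are portable. Retinopathy history enters as a
binary prior-retinopathy indicator. Covariates are frozen at baseline for
trajectory generation and risk prediction; in a live programme the risk
factors would refresh between visits, but no update model is assumed here
(a config hook exists for supplying updated covariates at refit).

**Fitting.** Screening data are interval-censored panel observations, so
the likelihood of a consecutive pair of visits is the matrix-exponential
transition probability over the elapsed time at the participant's
covariates, and the panel log-likelihood sums these over all pairs.
Optimisation is L-BFGS-B from log-intensity −3 (≈ 0.05/month) and zero
coefficients, gradient tolerance 1e−6, with log-intensities bounded in
[−12, 8]; a transition that is allowed but never directly observed is
pinned at the floor e^−12 with a warning, and non-convergence is reported
in the returned status, never silently. Standard errors come from the
numerically differentiated Hessian at the optimum (central differences,
relative step 1e−4). Matrix exponentials are computed by a batched
eigendecomposition; any matrix whose reconstructed rows fail to sum to
one within 1e−9 (defective or ill-conditioned cases, e.g. equal-rate
chains) falls back to `scipy.linalg.expm`, and probabilities are clipped
to [0, 1] after validation.

**Covariate selection** is forward selection on
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), with k the number of free parameters
and n the number of participants; the full audit table of every model
visited is returned. Forward search is one of several defensible
directions; it was chosen because candidate sets here are small and the
audit table makes the path transparent.

**Allocation.** The engine reports cumulative screen-positive risks over
6, 12 and 24 months (monotone because `SP` is absorbing). One threshold
τ = 0.025 governs all horizons: the longest horizon whose risk is
*strictly* below τ sets the recall interval (24 → low, 12 → medium,
otherwise 6 → high). A risk exactly at the threshold therefore takes the
shorter interval — the conservative reading where the convention is not
fixed; both the threshold and the strictness are arguments.

**Validation.** Discrimination is AUC by rank comparison (ties half),
sensitivity/specificity of `risk ≥ τ`, and a concordance index over all
usable pairs (computed with `lifelines`). Optimism correction follows the
bootstrap recipe (refit on a resample, evaluate on the original, average
the apparent-minus-test difference); the replicate count is an argument
because full refits dominate the cost.

## Synthetic cohorts

No individual-level data ship with the package; the generator emulates a
mature urban screening population:

* Baseline states `R0R0/R1R0/R1R1` with probabilities 0.812/0.124/0.063
  (normalised to sum to one).
* Continuous covariates from families parameterised by median and IQR:
  truncated normal for age (median 63.1, IQR 54.9–70.7, range 14–100),
  systolic BP (130, 122–138, 80–220) and total cholesterol (4.0, 3.4–4.7,
  1–10); log-normal for the right-skewed diabetes duration (7.0,
  4.2–11.0) and HbA1c (51, 44–62 mmol/mol, clipped to 20–160). For a
  normal family sd = IQR/1.349; for a log-normal σ = log(q3/q1)/1.349.
  Families are config-switchable.
* Diabetes type 4.0% type 1 / 88.5% type 2 / 7.5% unknown; eight
  synthetic clinics; a small (<16-years) stratum randomised in blocks of
  two.
* Covariates are sampled independently given the risk structure: the
  high-risk-group correlations (longer duration, higher HbA1c) emerge
  through the generating model's covariate effects on progression rather
  than being hard-coded. The true dependence structure of a screening
  population is richer; tests passing on this generator show the
  machinery is correct, not that the marginals capture any particular
  population.
* True trajectories are simulated exactly (exponential holding times,
  categorical destinations, `SP` absorbing). The default generating model
  uses per-month baseline intensities (0.0045, 0.0040, 0.0030, 0.0025 for
  the grade transitions; 0.0002, 0.0015, 0.0040 into `SP`) chosen so that
  `R0R0` is low-risk, `R1R0` is typically medium (24-month risk just above
  2.5%) and `R1R1` high, with modest positive duration/HbA1c/BP/cholesterol
  effects on progression.
* Attendance at an invitation is Bernoulli with arm × risk-group
  probabilities (control 0.773/0.817/0.857 and individualised
  0.723/0.822/0.851 for high/medium/low); attended visits occur uniformly
  within the 90-day window. Time is in months throughout; the 90-day
  window is 3.0 months.
* Loss to follow-up is a constant hazard, rate −ln(1 − 0.06)/12 per month
  so the annual loss fraction is exactly the planning value of 6%;
  consent withdrawal is a separate small probability (0.6%).
* Utility indices (for the economic analyses) are beta-distributed at
  baseline with most mass near full health (mean 0.82, concentration 10)
  and baseline-correlated Gaussian perturbations (sd 0.06) at follow-ups,
  clipped to the instrument range; worse-than-dead values can be enabled
  for HUI3-like instruments. Tariff/crosswalk valuation machinery is out
  of scope — indices arrive already valued.

## Trial simulation

Randomisation is 1:1 by stratified permuted blocks (clinic × age band;
random blocks of four and six for adults, two for children), so arms are
exactly balanced within every completed block. The control arm is
invited at exactly 12 and 24 months; the individualised arm at the
engine-allocated interval, recomputed at each attended visit from the
observed grade (measurement error is not modelled: the observed grade is
the true grade at the visit time). Non-attenders are re-invited one
interval after the missed invitation; invitation times in the
individualised arm are therefore sums of assigned intervals. Follow-up is
24 months plus the 90-day window, with a further 90 days for the
economics to absorb the compounding scheduling lag.

Screen-positive events from the true path are confirmed as
sight-threatening retinopathy with probability 0.8 (configurable);
unconfirmed cases are re-entered with the truth reset to the
pre-absorption state, since no mechanism for their subsequent course is
available. Independently, attended screens can be screen-positive for
other eye disease at rate 0.035 per attended visit; these false positives
re-enter without interruption. The two defaults jointly give
screen-positive rates near 4–5% per attended episode with roughly a
quarter of individualised-arm positives being retinopathy-related, the
pattern seen in practice. Confirmed cases leave routine recall. Wrong
-interval protocol deviations are injectable at a configured rate (default
0) to exercise the per-protocol/ITT distinction.

Per-protocol excludes consent withdrawals, deviations and participants
whose first follow-up was never resolved; intention-to-treat keeps
everyone but consent withdrawals, counting unresolved attendance as
non-attendance by default (configurable).

## Safety statistics

Wilson score intervals use z = Φ⁻¹(0.975) = 1.959964 (not 1.96 rounded);
rounding to reporting precision happens only at output. The Newcombe
difference interval is the uncorrected square-and-add combination, which
reproduces published overall attendance and low-risk detection bounds to
three decimals from the printed counts; with continuity correction it
does not. (Published subgroup attendance bounds differ from this
computation by ≤ 0.002, suggesting a slightly different subgroup
procedure upstream; the headline rows match exactly.) Verdicts use strict
inequalities at the margins — a CI touching ±5% is not equivalent, a
lower bound exactly at −1.5% is not non-inferior — and both margins and
strictness are arguments.

Multiple imputation draws binary outcomes from a logistic model on
baseline characteristics with coefficients drawn from the approximate
posterior (proper imputation); m defaults to 20. Rubin pooling uses total
variance W + (1 + 1/m)B and the classical degrees of freedom
(m−1)(1 + W/((1+1/m)B))². Deterministic best/worst-case fills are
available as sensitivity analyses.

## Economics

Costs are computed in integer pence (exact at 2 dp): 28.73 GBP per
attended and 12.73 GBP per missed appointment to the health service, plus
9.00 GBP per attendance from the societal perspective. QALYs are
trapezoidal areas under the linearly interpolated utility index, time in
years, truncated at the horizon and extrapolated flat beyond the last
measurement; no discounting over the two-year horizon. Incremental QALYs
optionally adjust for baseline utility; costs regress on the arm
indicator alone (there is no baseline cost). The bootstrap (default 1000
iterations) resamples participants with replacement *within arm*,
preserving the design and ruling out single-arm resamples, and intervals
are bias-corrected percentile (BC, no acceleration term — the minimal
reading of "bias-corrected"; the plain percentile interval is recovered
when the bootstrap distribution is median-centred). Ties at the point
estimate use mid-ranks, and an exactly degenerate bootstrap collapses the
interval to the point. Pooling across imputed sets runs a two-equation
feasible-GLS seemingly unrelated regression (cost and QALY sharing the
arm regressor; hand-rolled since no installed package provides SUR) and
Rubin-pools the arm coefficients.

## Problem sizes in the test suite and acceptance script

Simulation scales are the package's own choices: multi-state parameter
recovery uses 50 replicate panels of 2000 participants × 5 visits;
occupancy-vs-matrix-exponential checks use 15,000 simulated paths per
structure; Newcombe coverage uses 2000 simulated tables per event rate at
n = 200 per arm; bootstrap-CEA coverage uses 200 replicates of 500 per
arm with 1000 bootstrap iterations; the calibrated trial simulation runs
60 replicates (40 in the acceptance script) at n = 4321. All simulations
are seeded and deterministic.

## Known limitations

* The engine here is structurally faithful but fitted to synthetic
  panels; it does not reproduce the numeric coefficients of any deployed
  engine, and printed discrimination figures from live programmes
  (AUCs near 0.9, C-index ≈ 0.69) are context rather than targets.
* No grading error, image-quality/ungradable pathways, treatment after
  confirmed disease, or ethnicity/smoking effects on progression.
* Single invitation per recall cycle; real programmes may re-invite
  within the window.
* Independent covariate sampling (given risk effects) understates real
  covariate correlation; utility synthesis is a shape assumption, not a
  valued tariff.
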