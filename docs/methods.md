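# Methods

## The model

`aptapk` analyses blood concentration–time data of an IV-bolus
fluorescent aptamer probe with a two-compartment population model. Drug
amounts in the central (blood and well-perfused tissue, volume V1) and
peripheral (slower-equilibrating tissue, volume V2) compartments follow
first-order kinetics with elimination clearance CL and distribution
clearance Q. After a bolus dose D into the central compartment the
concentration is the biexponential

    C(t) = A e^(−αt) + B e^(−βt),

where α and β are the roots of x² − (k10+k12+k21)x + k10·k21 = 0 with
k10 = CL/V1, k12 = Q/V1, k21 = Q/V2, and

    A = D(α − k21) / (V1(α − β)),   B = D(k21 − β) / (V1(α − β)),

so A + B = D/V1 = C(0). Disposition half-lives are ln2/α (fast,
distribution) and ln2/β (slow, elimination). Setting Q = 0 collapses the
model to one compartment; the package represents that limit with
β = α and B = 0 by convention, which also covers the (probability-zero
under estimation) repeated-root case.

Between-animal variability enters as a log-normal random effect on
clearance only, CL_i = CL·e^{η_i}, η_i ~ N(0, ω²); reported as a CV via
the exact log-normal identity CV% = 100·√(e^{ω²} − 1) (so 22% CV
corresponds to ω ≈ 0.2174 — the small-variance approximation
CV ≈ 100·ω is deliberately not used). Body weight acts on all four
disposition parameters through fixed allometric exponents: 0.75 for both
clearances, 1 for both volumes, referenced to a 25 g animal
(configurable). Residual error is exponential: observations are
log-transformed and log y is Gaussian around log C(t) with standard
deviation b. Whether a published "exponential error magnitude" is an SD
of log-observations or a CV is ambiguous in general; this package adopts
the SD-of-log reading, which is the standard meaning of an exponential
error model fitted on the log scale (at b ≈ 0.27 the two differ by only
a few percent).

## Estimation

Parameters are estimated by maximum marginal likelihood on log-scale
parameters (guaranteeing positivity): θ = (log CL, log V1, log Q,
log V2, log b, log ω). The per-subject marginal likelihood integrates η
out with a **Laplace approximation**: an inner damped-Newton search
(vectorized across subjects, warm-started between outer iterations,
derivatives by central differences with step 1e-4, convergence at
1e-9) finds the posterior mode η̂_i, and

    ll_i = g_i(η̂_i) − log ω − ½ log(−g_i''(η̂_i)),
    g_i(η) = loglik_i(η) − η²/(2ω²).

A 64-node **adaptive Gauss–Hermite quadrature** route (same mode and
curvature used to center and scale the grid, summed in log space) is
retained as an independent oracle; Laplace agrees with it to well below
0.01 log-likelihood units on this design, and both reduce exactly to the
individual likelihood as ω → 0. Laplace was chosen over stochastic
algorithms (SAEM-type) because it is deterministic, accurate for a
single scalar random effect, and directly checkable against quadrature.

The outer problem is solved with L-BFGS-B under generous log-scale
bounds. Three robustness measures matter in practice:

* **Starting values** come from a naive two-stage pass: per-subject
  log-linear regression of the terminal phase, dose/AUC for clearance,
  and curve stripping of the fast phase for the two-compartment
  structure (the stripped back-extrapolation dose/(A+B) corrects the
  central volume for fast-phase decay already incurred by the first
  post-dose sample); b starts at the empirical SD of the init residuals
  and ω at the between-subject spread of the per-subject clearances.
* **A second start** at generic noise magnitudes (b = 0.3, ω = 0.2) is
  tried when the first solution looks suspicious (no movement from the
  start, optimizer failure, or b > 0.8, i.e. residual noise above 120%
  CV); the better log-likelihood wins. This guards against a degenerate
  basin in which structural misfit is absorbed into the residual error.
* Optimizer failure flags are double-checked with a Nelder-Mead polish
  and a projected-gradient stationarity test, because noisy
  finite-difference line searches near the optimum otherwise produce
  spurious non-convergence reports. Estimates within 1e-4 (log scale) of
  a bound are flagged as boundary estimates — the expected signature of
  an unidentifiable structure (e.g. a two-compartment fit to
  monoexponential data, or ω on no-variability data).

Everything is deterministic given (dataset, init, config).

**Uncertainty.** RSEs come from the observed Fisher information,
numerically differentiated (central second differences, step 1e-4 on the
log scale) at the optimum. Because parameters are estimated in logs,
100·SE(log θ̂) is directly the relative SE of the natural-scale
estimate (delta method). A non-positive-definite information matrix
triggers a warning and missing RSEs for the affected parameters;
boundary estimates get no RSE.

**Model selection** uses a corrected BIC with the hybrid penalty common
in pharmacometric software: −2·loglik + k_R·ln N_subjects +
k_F·ln N_observations, where k_R counts random-effect parameters (ω)
and k_F the fixed-effect and residual parameters. The exact penalty
convention of any given software version is rarely printed, so the
single-sample-size variants are available as configuration. Ties break
toward the simpler model.

**BLOQ handling.** The default policy discards below-LOQ records
("M1"), matching analyses that describe data as "quantifiable up to" a
time. A censored-likelihood option ("M3", adding Φ((log LOQ −
log f)/b) terms for censored records) is available behind a flag.
Pre-dose t = 0 samples are dosing rows (MDV = 1), never observations.

## Diagnostics

Simulation-based diagnostics re-simulate the fitted model under the
original design (same animals, body weights, doses, retained sampling
times), seeded and bit-reproducible.

* **VPC**: observed 5th/50th/95th percentiles per time bin against the
  simulated 90% confidence band of each percentile. Default binning
  groups observations by their nominal sampling times (the design is
  nominal-time); user-supplied edges are supported for irregular data,
  with empty bins merged into a neighbor under a warning.
* **NPDE**: per subject, observed and simulated log-concentration
  vectors are decorrelated with the inverse Cholesky factor of the
  empirical simulated covariance (ridge-regularized if singular, with a
  warning); the observed decorrelated value's midpoint rank
  (k+0.5)/(K+1) among simulations is mapped through the standard-normal
  quantile, avoiding ±∞ and making ties deterministic. Under a correct
  model the NPDE are approximately iid N(0,1); the calibration tests
  check |mean| ≤ 0.1 and |variance − 1| ≤ 0.15 at ~1,000 observations.
* **GOF tables**: per-observation population predictions (η = 0),
  individual predictions (η at the empirical Bayes estimate), and
  weighted residuals (log y − log f)/b.

Under the discard policy, simulated replicate values at retained design
points are used uncensored (rank-based diagnostics need numeric values);
under the censored policy the censored records contribute to the fit but
diagnostics are computed on the quantified rows.

## Synthetic data

The generator emulates the study design: n = 6 mice (point mass 25 g by
default; a Normal(25, 2²) option exercises the allometric path), 40 µg
bolus, sampling at 0 (pre-dose), 15, 30, 60, 90, 120, 240, 480, 1440,
2880 min, per-animal log-normal clearance effects (22% CV), exponential
residual noise (b = 0.27), and LOQ censoring. The default LOQ of
0.015 µg/mL is a generator convention chosen so the median animal's
closed-form profile (≈0.031 µg/mL at 60 min, ≈0.0074 µg/mL at 240 min)
is quantifiable through 60 min and censored by 240 min — the qualitative
censoring pattern of the study; the assay's true quantification limit
and the fluorescence-to-concentration calibration are not published, so
the µg/mL scale is a modeling convention (a linear calibration absorbed
into the dose scale), not a claim about raw instrument units.

The organ-fluorescence generator draws log-normal intensities around
configurable organ-by-group means (n = 4 per sacrifice group, CV 25% by
default). Tumor means default to the published group averages (3273,
850, 690 counts/pixel at 2/24/48 h; 1325 under competition blocking);
the other organs' means are synthetic conventions shaped to the reported
pattern (high hepatic/renal signal at 2 h declining by 24–48 h, low
muscle background, PBS controls at instrument background). Tumor growth
is logistic in the longer caliper dimension with W = 0.7·L and small
per-animal jitter, placed so the median volume passes a 50 mm³
palpability threshold (a generator convention) near day 9 and lands in
the reported 200–500 mm³ window at day 20 for ≳90% of animals; volumes
use the caliper formula V = ½·W²·L.

What passing tests on these cohorts do **not** show: robustness to
model misspecification (real kinetics may include metabolite signal,
nonlinear elimination, or assay drift), to non-nominal sampling times,
or to non-log-normal between-animal variability — the generator draws
from exactly the distributional family the estimator assumes.

## Biodistribution statistics

Each animal is sacrificed at a single timepoint, so there are no
repeated measures across groups; between-timepoint comparisons therefore
use a one-way fixed-effects linear model on log intensity (fluorescence
units are arbitrary, and the log scale makes the contrasts
scale-invariant) with pairwise 2 h-vs-later contrasts, Holm-adjusted.
This is a documented simplification of "mixed generalized linear model"
analyses whose family/link are typically unstated; accordingly only the
direction and attainability of significance under known synthetic effect
sizes is tested, not specific p-values. Near-zero residual variance
falls back to an (exact when feasible) permutation test; identical data
give p = 1. PBS control animals are reported but never pooled into
treated-group statistics, and organs dominated by autofluorescence
(stomach, intestine, gallbladder) are excluded by default. The
competition index is blocked/unblocked mean tumor signal, with percent
reduction 100·(1 − ratio).

## Problem sizes and reproducibility

The shipped experiments use 100-animal cohorts (five replicate seeds)
for parameter recovery, 200-animal cohorts for the variability (CV)
target, 100 six-animal replicates per arm for structure selection, and
~1,000 observations for diagnostic calibration — sizes at which the
checked tolerances (15% fixed effects, 20% residual, 40% CV; ≥80%/≤20%
selection) are comfortably attainable under the generating model. All
randomness flows through explicit integer seeds; generators and
diagnostics are byte-reproducible given (parameters, seed).

## Known limitations

* Random-effect scope is clearance-only by design (matching the reported
  variability structure); other parameters can be freed in configuration
  but are untested beyond smoke level, and correlated random effects are
  out of scope.
* The Laplace approximation is accurate here (scalar random effect,
  9 observations per subject) but would need re-validation against the
  quadrature oracle for sparser designs.
* Single-dose IV bolus only: no infusion, oral absorption, nonlinear
  (Michaelis–Menten) elimination, or three-compartment structures.
* RSEs are asymptotic (observed-information) quantities; no bootstrap.
* The biodistribution model links organ fluorescence to group membership
  only; it does not mechanistically couple probe kinetics to tissue
  uptake.
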