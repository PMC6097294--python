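# Methods

This note documents the models implemented in `asis_kit`, the choices
made where a convention had to be fixed, what the synthetic cohort
generator does and does not emulate, and the problem sizes used by the
test suite and `scripts/acceptance.py`.

## The severity scale and ASIS

Total severity is the sum of 16 ordinal subdomain scores: 8 major domains
with maximum 5 and 8 minor domains with maximum 2, so the scale tops out
at 40 (majors) and 56 (all).  The per-domain major maximum of 5 is the
only integer assignment consistent with both printed maxima (8 × 5 = 40).
Scores are integers; fractional scores are rejected as validation errors.
Hearing is not part of the data model: it cannot be ascertained uniformly
across centres, so "total severity" always means "minus hearing".

ASIS is total severity divided by age at assessment (severity units per
year); it is undefined at age 0 and visits must carry strictly positive
ages.  Any subset of domains can be excluded from the total before the
division (used, e.g., to score an 8-major-domain variant for treated
patients, or to remove a candidate panel from the total).

## ASIS stability

Per patient, ASIS is regressed on time since first visit by ordinary
least squares; using time-since-first rather than absolute age changes
only the intercept, and conditions the design matrix better for short
series.  A patient is *stable* when their slope lies inside the classic
box-plot whiskers [Q1 − 1.5·IQR, Q3 + 1.5·IQR] of the cohort slope
distribution.  Quantiles use linear interpolation between order
statistics throughout the package; this convention is a choice and is
fixed here.  The classification needs at least 4 slopes and is invariant
to patient order.

Kernel density estimates use a Gaussian kernel with Silverman's
bandwidth h = 0.9·min(sd, IQR/1.34)·n^(−1/5); samples with zero spread
are rejected.  Group comparisons report the Wilcoxon–Mann–Whitney test
for location and the Ansari–Bradley test for dispersion, with scipy's
default exact/asymptotic switching for small samples.

## Latent-class mixture regression

Progression subgroups are modelled as a K-component Gaussian mixture of
linear regressions of severity on age: component k has line
a_k + b_k·age, mixture weight π_k, and a residual sd shared across
components (homoscedastic — the simplest model consistent with a fan of
lines; a heteroscedastic variant was deliberately left out of scope).
The fit is EM:

- E-step: responsibilities from the current lines, weights and sd,
  computed in log space with log-sum-exp;
- M-step: per-component weighted least squares and a pooled residual sd.

EM is initialisation-sensitive, so slopes are seeded from jittered
quantiles of the per-point severity/age ratios and the fit is restarted
`n_restarts` times (default 10) from seeded starts, keeping the best
log-likelihood.  The observed-data log-likelihood trace is recorded and
asserted non-decreasing in tests.  Convergence is a log-likelihood change
below `tol` (default 1e-8) within `max_iter` (default 500); otherwise the
best model is returned flagged unconverged.  Components are relabelled by
ascending slope so class labels are canonical.  `zero_intercept=True`
forces lines through the origin, matching the ASIS construction; the
default keeps free intercepts as the general case.  By default the fit
uses one point per patient (the first visit); pooling all visits is a
flag.

Patients are assigned to the class whose line is *vertically* closest to
their observed severity at the chosen visit (first or last); ties break
toward the lower class index.  The category-shift table counts
|label_last − label_first| over patients.

## Subdomain panels and rank aggregation

The subset scan correlates, over one first-visit row per patient, every
1-, 2- and 3-subset of the 8 major domains (8, 28 and 56 subsets) with
the total score — both including the subset's own scores in the total and
after removing them, which guards against the part-whole artefact.
Spearman's rho is the tie-aware rank correlation (average ranks, then
Pearson); constant inputs make it undefined and are reported as NaN in
scan rows (an error for scalar calls).  p-values use the t-approximation.
Minor domains are not scanned combinatorially but may appear in arbitrary
panels via `panel_correlation`.

Questionnaire rankings (1 = most impact) are aggregated by summing ranks
per item across respondents and ordering items by ascending sum.  Tied
sums share the lower position by dense ranking — the published tables do
not state a tie rule, so this is a documented package choice.

## Trial stratification

Eligibility is decided at each patient's first recorded visit.  Age bands
carry a neurological-sign requirement (severity > 0, excluding
pre-symptomatic patients); ASIS bands do not, since a positive lower
ASIS bound already implies signs.  Band endpoints are inclusive on both
sides — the sources write bands as "0.5 to 2" without stating the
convention.  The built-in catalog has nine criteria: age > 12
(substrate-reduction-therapy trial), 2–18 (HSP-amplifier trial), 4–21
(intrathecal cyclodextrin trial as modelled; the registered 2–25 window
and a 12–60 variant are available as separate constants), and ASIS bands
0.5–2, 0.75–2, 1–2, 0.5–2.5, 0.75–2.5, 1–2.5.  Report percentages are
rounded half-up to one decimal.

## Prognosis by MAD

A patient's predicted trajectory is the through-origin line
ASIS_ref · age, with ASIS_ref either the first-visit ASIS or the
unweighted mean of all per-visit ASIS values (first visit included).
Goodness of fit is the *maximum* absolute deviation over the patient's
visits between observed and predicted severity, in severity units; for
the first-visit reference the first visit deviates by zero by
construction.  Groups are summarised by the median and IQR of per-patient
MADs.  Follow-up windows (0–2, 2–4, 4–6 years) partition patients by
total follow-up span with right-closed boundaries (span exactly 2 → the
0–2 window); spans beyond 6 years join the last window with a warning.
Each patient contributes to exactly one window.

## Treatment effect

On-treatment ASIS observations are modelled as
asis = β₀ + β₁·t + b_i + ε with t in years since treatment start, b_i a
patient-level random intercept and β₁ the average annual ASIS change.
The model is statsmodels' MixedLM, REML by default (ML behind a flag),
with a Wald p-value for β₁.  Designs where the patient level is not
identifiable (a single patient, or no repeated measures) degrade to
ordinary regression with the random-intercept variance at the boundary,
flagged `boundary_fit`.  Percent annual change is 100·β₁/β₀ with the
*fitted* baseline as denominator; note that published reports pairing a
−0.06/yr slope with a −10.4 %/yr change imply a baseline near 0.58 while
quoting a baseline median of 0.53 and mean of 0.67 — the denominator
convention is therefore surfaced in the output rather than hidden.

## The synthetic cohort generator

Patient-level severity data of this kind are not published, so the
pipeline ships a generator whose defaults encode the study design it
emulates: 38 patients in 2 centres; six latent progression classes with
rates (0.2, 0.5, 0.9, 1.4, 2.1, 3.0) severity units/year and weights
(0.15, 0.20, 0.25, 0.15, 0.15, 0.10), chosen so first-visit ASIS
quartiles bracket the reported 0.49–1.52 band with a median near 0.96;
2–9 visits per patient over follow-up spans of 0.94–6.36 years; a 47%
seizure fraction; per-visit severity r·age plus Gaussian noise (sd 1.0),
rounded, clamped to 0–56 and made monotone non-decreasing by default
(progressive disease; a flag allows decreases, e.g. a severity drop after
effective seizure medication).

Two structural choices deserve note:

- **Entry age is coupled to the progression rate.**  First-visit ages are
  uniform on [2, min(28, 0.8·56/r)]: fast progressors enter the study
  young, which keeps severities on-scale without saturation and mirrors
  the clinical reality that rapidly progressing patients present early.
- **The seizure group carries a post-onset rate perturbation.**  Seizure
  patients draw an onset age uniform over their follow-up; from onset the
  seizure domain scores > 0 and the patient's rate is perturbed by a
  N(0, 2.0 units/yr) draw.  The sd of 2.0 is derived from the reported
  seizure-group ASIS-slope IQR of (−0.08, 0.19) at typical entry ages
  around 12 years (an ASIS slope of δ/age corresponds to a severity-rate
  kink of δ), and is what makes the seizure group less predictable by a
  constant-rate trajectory.

Totals are split into the 16 subdomain scores by largest-remainder
apportionment with weights proportional to the per-domain maxima,
honouring per-domain caps, a seizures ≥ 1 minimum when a seizure has been
observed and a seizures = 0 cap when it has not.  Ages are rounded to 3
decimals (and simulated ASIS observations to 6) so the CSV round trip is
exact.  Identical config and seed give identical cohorts.

The treatment-series generator draws 10 patients with baseline ASIS
uniform on 0.38–0.80 (centred near the reported baseline), a common
on-treatment slope of −0.06/yr, durations of 2.7–21.16 months, a baseline
visit at t = 0 plus 2–4 on-treatment assessments, and observation noise
sd 0.03.

**What the generator does not emulate:** inter-rater differences between
centres, floor/ceiling effects of individual subdomains, non-linear or
saltatory progression, missing subscores, treatment effects in the main
cohort (≈95% of the real cohort was on substrate-reduction therapy), and
mortality/dropout.  Passing tests therefore demonstrate that the
*pipeline* recovers what the generative model puts in — rate classes,
stability, seizure-group variability, band monotonicity — not that the
clinical findings themselves replicate; the published cohort values serve
only as plausibility references.

## Numerical choices and problem sizes

- Quantiles: linear interpolation; whiskers: 1.5·IQR.
- EM: residual sd floored at 1e-12 (noiseless data collapse to hard
  assignments without overflow thanks to log-space responsibilities).
- Mixture recovery checks use 240 points (40 per class) at residual sd
  1.0 with 10 restarts; recovery tolerance 0.15 units/yr per slope.
- Mixed-model recovery averages 50 seeded 10-patient series; tolerance
  ±0.01 on the −0.06/yr slope.
- Directional cohort checks use 100 seeded replicates of the default
  38-patient cohort; `scripts/acceptance.py` averages 50 replicates.
- Known limitations: with only one point per patient the K = 6 mixture on
  a 38-patient cohort can merge adjacent classes on some seeds (the
  log-likelihood surface is multimodal); restarts mitigate but do not
  eliminate this, which is why recovery guarantees are stated for the
  240-point design, not for single small cohorts.  The Ansari–Bradley
  test assumes equal medians for a clean dispersion interpretation; it is
  reported as-is, as in the source analyses.
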