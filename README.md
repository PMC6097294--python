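# asis-kit

Analysis toolkit for **ASIS** — the *annual severity increment score* — in
longitudinal Niemann-Pick disease type C (NPC) cohorts.

NPC is a rare, progressive neurodegenerative lysosomal storage disease.
Clinical burden is monitored with a composite severity scale summing 16
ordinal neurological subdomains: 8 major domains scored 0–5 (eye movement,
ambulation, memory, speech, swallowing, fine motor skills, cognition,
seizures) and 8 minor domains scored 0–2, for a theoretical maximum of 56
(40 over the majors; hearing is excluded because it cannot be scored
consistently across centres).  Dividing a visit's total severity *S* by
the patient's age *a* gives

```
ASIS = S / a        [severity units per year]
```

an index of the annual rate of disease progression.  If severity accrues
linearly through the origin, S = r·a, then ASIS equals r at every visit
and is constant over time — which makes it a candidate tool for trial
stratification (recruit by progression rate instead of age), prognosis
(predict future severity as ASIS·age) and treatment monitoring.

The package is aimed at biostatisticians and clinical researchers working
with rare-disease severity scales.  It provides, as importable modules
under `asis_kit`:

- `severity` — the 16-domain scale, visit/patient records, validation;
- `metrics` — per-visit ASIS, per-patient ASIS slopes (OLS on time since
  first visit), Tukey-whisker stability classification, quantile
  summaries, Silverman-bandwidth KDEs, Wilcoxon–Mann–Whitney and
  Ansari–Bradley two-sample tests;
- `mixture` — a K-class Gaussian mixture of linear regressions of
  severity on age, fit by EM with seeded restarts, plus nearest-line
  subgroup assignment and category-shift tabulation;
- `subdomains` — exhaustive Spearman scans of 1/2/3-subsets of the major
  domains against the total score (with and without the subset's own
  contribution), panel correlations, questionnaire rank aggregation;
- `stratification` — trial eligibility under age bands (with a
  neurological-sign requirement) versus ASIS bands, with cross-tabulation;
- `prognosis` — through-origin severity prediction from first or mean
  ASIS, scored by per-patient maximum absolute deviation (MAD);
- `treatment` — a random-intercept linear mixed model of on-treatment
  ASIS, reporting the annual slope and percent annual change;
- `simulate` — a seeded synthetic cohort generator (38 patients, 2
  centres, six latent progression classes, ~47% seizure group) so every
  stage is testable without patient-level data;
- `io` / `cli` — CSV readers/writers and the `asis-kit` command line.

The numbered scripts under `analysis/` run the whole pipeline as a
narrative: simulate → ASIS stability → subgroups → subdomain panels →
eligibility → prognosis → treatment effect, writing tables to `results/`.

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_asis_stability.py
python analysis/07_treatment_effect.py
```

prints (seed 1):

```
cohort: 38 patients, 210 visits (seed 1)
  median age at first visit : 11.4 y
  ...
first-visit ASIS: median 0.94, IQR (0.47, 2.04)
stable ASIS: 31/38 patients (82%)
...
fixed slope      : -0.054 ASIS units/yr (Wald p = 3.2e-12)
fitted baseline  : 0.608
annual change    : -8.9% per year
```

Reading: the synthetic cohort's median progression rate is ~0.94 severity
units per year; 82% of patients keep an essentially constant ASIS over
follow-up (their ASIS-vs-time slope falls inside the Tukey whiskers of
the cohort slope distribution); and on the simulated experimental-therapy
series the mixed model recovers a significant ASIS reduction of ~0.05–0.06
units per year, i.e. roughly a 9–10% slowing of progression per year
relative to baseline.

The same computations are available from the shell, e.g.

```sh
asis-kit simulate --seed 1 --out cohort.csv
asis-kit stability --cohort cohort.csv --out slopes.csv
asis-kit stratify --cohort cohort.csv --out eligibility.csv
```

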