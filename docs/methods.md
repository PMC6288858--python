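# Methods

## Scope

`linkbias` studies how probabilistic record-linkage errors propagate into a
time-to-event analysis. Because real HDSS/clinic data of this kind are
confidential, the package pairs the analysis machinery with a synthetic-data
generator whose stated world reproduces the published *structure* of such a
study — cohort composition, identifier completeness, error regime, and effect
size — not any real population.

## The synthetic world

**Registry.** `generate_population` creates `n_people` persons (default
4,000; configurable — the motivating surveillance site covers ~35,000
residents, which is out of budget for exhaustive cross-product scoring in CI)
partitioned into households (Poisson-sized, mean 3.5), grouped under ten-cell
leaders (10 households per leader), nested in 7 villages × 3 sub-villages.
Sub-villages carry rurality and paved-road attributes correlated with their
distance from a fixed care-clinic coordinate; household coordinates are
planar, and distance to the clinic is Euclidean, banded <1 / 1–1.9 / 2–4.9 /
5–11 km. Names come from finite pools (≈60 first names, ≈60 surnames) with
Zipf(1.0) frequencies so distinct people collide on full names at realistic
rates — the raw material of false matches. Every person has a latent third
name that the registry never stores. Residency is a list of non-overlapping
half-open day intervals; ~8% of people have episodes that do not span the
study window and ~5% have two episodes.

**Encounters.** `corrupt_encounter` transcribes a person's true identity onto
a sero-survey, HTC or ANC record. Field presence follows per-source
completeness profiles taken from the observed completeness of matching
identifiers in community-survey vs clinic registers (e.g. third name 13.3%
vs 88.7%; ten-cell-leader names 48.3/48.3% vs 91.5/74.6%; household-member
names 71.5/71.5% vs 11.3/11.3%; names, sex, birth year ≥99.3% everywhere).
Month/day-of-birth completeness is not tabulated anywhere; 0.70 on encounters
and 0.99 in the registry were chosen once as plausible for paper registers.

Two error layers apply to present fields:

* *typos* — one random substitution/transposition/deletion per affected name
  (rate 0.20), and a name-order swap (rate 0.10);
* *identity drift* — the recorded value is a different value entirely: an
  alias name drawn afresh from the pool (personal names 0.45, leader names
  0.55, household-member names 0.45), a shifted birth year (rate 0.65,
  discrete-normal sd 5), a wrong birth month/day (0.40), an out-of-date
  sub-village (0.30), a mis-recorded sex (0.02).

The drift layer exists because typos alone cannot produce a realistic error
regime: a single edit on a 6-character name still clears the 0.85
Jaro–Winkler agreement bar, so a typo-only world yields a false-match rate
under 5% at the minimum threshold. The reference setting reports ~39%, with
true-match scores ranging from strongly negative to strongly positive —
true pairs there frequently disagree outright on identifiers. The drift rates
above were calibrated once against that operating point (false-match rate
0.33–0.45, mean 0.385, across 8 probe seeds of the replicate world) and then
frozen; no acceptance-driven adjustment was made afterwards.

**Cohort and outcomes.** `simulate_cohort` samples a diagnosed cohort
(default 405; 263 sero-survey : 142 clinic, clinic split 126 HTC : 16 ANC)
from eligible resident adults using importance weights that reproduce the
modality-conditional distributions of sex, age group, rurality, paved road
and distance band observed in the reference cohort. Time from diagnosis to
care registration is exponential with hazard
`λ0 · exp(β_mod·1[clinic] + Σ covariate effects)`; the baseline
`λ0 = 0.0019/day` makes ~16% of sero-survey diagnoses register within the
90-day horizon, matching the reference registration proportion, and the
default `β_mod = ln 5` matches its reported effect size. Covariate log-HRs
default to modest values (|β| ≤ 0.2). Deaths occur at 2×10⁻⁴/day.
Crucially, *every* registry person gets an outcome history: undiagnosed
people carry a 3% probability of a background CTC registration date. This is
what a falsely linked encounter inherits, and it is the concrete mechanism of
attenuation. Deliberately ineligible encounters (under-15, repeat testers,
reported non-residents; 5% of the cohort each) are emitted so eligibility
filtering is exercised. All dates are integer days from an arbitrary epoch.

## Linkage engine

Nine fields are scored: three name sets (personal, ten-cell-leader,
household-member; order-free, best Jaro–Winkler over cross pairs ≥ 0.85 ⇒
agree) and six exact fields (sex, birth year/month/day, village,
sub-village). Weights are Fellegi–Sunter log-likelihood ratios in base 2
(configurable; base affects scale only). Missing on either side contributes
nothing. Defaults: m = 0.9 for names and dates, 0.95 for sex and geography;
u is estimated empirically as the per-field agreement rate among 2,000
randomly paired records (clipped to (0.001, min(0.6, m − 0.05))), with an
optional EM refinement over binary agreement patterns. The m/u values of the
original software are unpublished; empirical u with configured m is standard
practice absent training labels.

Best-candidate selection takes, per encounter, the registry record with the
highest score; ties are broken by fewest disagreeing fields, then lowest
person id, and are reported. Optional blocking restricts candidates to
sex+village agreement. Thresholds are the 0/25/50/75th nearest-rank
percentiles (`ceil(p/100·n)`-th order statistic; 0 ⇒ minimum) of the score
distribution among gold true pairs, applied inclusively (score ≥ cutoff).
Because the gold person is always among the candidates, every best candidate
scores at least its own true pair, so the minimum threshold provably retains
all best candidates.

## Evaluation and outcome analysis

Confusion counts obey `tp + fn = n_gold`; sensitivity = tp/n_gold,
PPV = tp/(tp+fp), false-match rate = 1 − PPV. Balance tables compare true vs
false and true vs missed matches level-by-level with standardised differences
(pooled-variance form; anchors 0.2/0.5/0.8). Missed matches retain their gold
person's attributes; true and false matches carry the linked person's —
mirroring what an analyst of the linked file observes. The contingency
utility uses Pearson chi-square without continuity correction, switching to
Fisher's exact test for 2×2 tables with any expected cell below 5 (the
reference analysis used both without stating its rule).

Cox fits use lifelines' `CoxPHFitter` (Efron tie handling — day-granular
times tie heavily; Efron is the least-biased standard choice). Categorical
adjusters enter as indicator contrasts against reference levels (sero-survey,
15–29, female, rural, no paved road, <1 km). The adjuster set follows the
fuller five-covariate specification (age group, sex, rurality, paved road,
distance band) rather than the four-covariate variant that also circulates;
it is an argument of `fit_cox`. Same-day registrations are set to 0.5 days; a
linked person who registered *before* the encounter's diagnosis (possible
only for false matches) is analysed as an immediate registration rather than
dropped, so the analytic n tracks the linked dataset. The 95% CI multiplier
is fixed at 1.96. The precision summary regresses the exposure SE on the
missed-match count across the four thresholds by ordinary least squares
(R², with the t-test p on 2 df); since the regressor behind the published
R² is not stated, threshold index and PPV variants are also reported, with
missed count primary.

## What a green test establishes — and what it does not

The generator reproduces: finite-pool name ambiguity, per-source identifier
completeness, a high-error regime calibrated to a published false-match rate,
a proportional-hazards outcome with administrative censoring, and
modality-covariate confounding via weighted cohort sampling. It does **not**
model real name distributions or phonetics, migration dynamics, survey round
timing, duplicate registry records, or within-household correlation of
identifier errors. Passing tests therefore establish that the *mechanisms*
(attenuation by false matches, precision loss by missed matches, the
threshold trade-off) behave as theory predicts in a faithful stand-in world —
not that any specific published coefficient is recovered, which would require
the confidential source data.

## Numerical choices and degenerate inputs

* Weight arithmetic in float64; score ties compared at 1e-9 absolute.
* Empty name lists, blank strings and NA all count as missing.
* An all-missing comparison scores 0 (neither evidence for nor against).
* PPV of an empty linked dataset is NaN with a warning, never an exception.
* Unfittable threshold models (no events in a modality arm, separation,
  non-convergence) are reported as unfittable rows; the experiment continues.
* Zero-variance standardised differences are NaN, labelled blank.
* Percentile cutoffs are asserted nondecreasing; inclusive comparison keeps
  dataset size monotone in the cutoff.
* Per-replicate seeds derive from the master seed via
  `SeedSequence(entropy=seed, spawn_key=(replicate,))`, keeping every derived
  seed below 2³¹.

## Known limitations

* Exhaustive cross-product scoring is O(encounters × registry); the default
  world keeps this around 1.6M pairs (~1 s). Use blocking or smaller
  registries for larger experiments.
* The EM refinement is a plain two-class conditional-independence mixture; it
  is provided as an optional pass, not used by default.
* The replicate world (800 persons, 160 diagnoses) trades Monte-Carlo noise
  for runtime; its high thresholds occasionally yield unfittable models,
  which the replicate summaries handle as missing.
* No correction methods (multiple imputation for unlinked records,
  weight-informed priors) are implemented; the package quantifies the biases,
  it does not remove them.
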