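# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `dateshift`.

## Data model

A dataset is a pair of tables. Patients: `patient_id`, `sex` (M/F),
`birth_date`, optional `death_date`. Stays: `stay_id`, `patient_id`,
`admission_date`, `discharge_date`, `hospital_id`, `icd10_codes`
(';'-separated). All dates are integer **day indices** (day 0 =
2017-08-01); CSV serialisation renders ISO-8601 calendar dates with empty
fields for missing values. Day resolution is the finest grain any attribute
carries, so integer arithmetic is exact throughout. Raw datasets must
satisfy per-patient chronology (birth ≤ admissions, discharges ≤ death);
pseudonymised datasets are exempt, because independent stay shifts can
legitimately invert event order — only `discharge ≥ admission` (length of
stay ≥ 0) is universal.

## Pseudonymisation schemes

Offsets are integers drawn uniformly on closed intervals (15 values for
Δt = 7). Each entity's offset is a pure function of `(seed, entity id)`:
a counter-based hash (splitmix64 of the seed, a CRC-32 of the id and a
role tag) yields one latent uniform `u ∈ [0, 1)`, and the offset is
`floor(u·(2Δ+1)) − Δ` — exactly uniform on {−Δ, …, +Δ}. Two consequences
are deliberate:

* adding or removing patients never changes another patient's draw
  (per-patient streams);
* sweeping the amplitude re-uses the same latent uniforms (**common random
  numbers**), so uniqueness measured along an amplitude grid is a paired
  comparison: each candidate's offset grows continuously with Δ, making the
  per-pair compatibility — and hence the aggregate uniqueness — monotone
  in the evaluated amplitude up to integer rounding. Grid sweeps exploit
  this by passing one shared seed to every cell.

Death dates are treated as event dates: shifted by the patient's shared δt
under the base and birth schemes, independently under the stay scheme.
Applying a scheme to an already-pseudonymised dataset raises — composition
of shifts is never meaningful here and usually indicates a pipeline bug.

## Attack model

The attacker knows a subset of {sex, birth_date, stay_dates, hospitals,
death_date} with the target's **true** values, plus the scheme and its
amplitudes. Compatibility is an exact feasibility question: does a legal
offset assignment map the known true values onto the candidate?

* **base/birth**: all stay dates pin a single shared offset (candidate and
  true stays are sorted and paired; any valid assignment is the sorted
  one because the offset is shared). The death date must agree with the
  same offset; the birth date must agree exactly (base) or within
  ±Δt_birth of it (birth). Attributes whose dates are unknown contribute
  interval constraints that are intersected.
* **stay**: a perfect bipartite matching must pair every true stay with a
  candidate stay of equal length of stay, equal hospital (if known) and
  admission offset within ±Δt (Kuhn's augmenting-path algorithm; stay
  counts are small). Birth and death are range checks.
* When death_date is not known, candidate death values are ignored
  entirely; when it is, presence/absence must agree first.
* Hospital knowledge defaults to per-stay (multiset / matched-pair)
  equality; a set-level mode (`hospitals_as_set=True`) is available since
  "hospitals visited" can also be read as a set.

An independent brute-force oracle enumerates every integer offset (and
every stay pairing) for amplitudes ≤ 200 days; the test suite requires
exact agreement with the range matcher on fuzzed instances.

**Scale.** k-anonymity queries use lossless blocking: candidates are
bucketed on attributes every scheme preserves exactly — sex, death
presence, stay count, the multiset of lengths of stay and (when known)
hospitals — and pre-filtered on the earliest admission, whose shift is
bounded by Δt under every scheme. Uniqueness on large sets is estimated on
a seeded sample of targets (search remains exhaustive); exact mode is the
default when no sample size is given.

k-suppression removes records with k < k_min and recomputes k on the
survivors until a fixed point, reporting the removed fraction.

## Synthetic generator

The generator emulates the marginal structure of a large multi-hospital
warehouse; all parameters live in `SyntheticConfig` and are YAML-round-
trippable. Defaults (chosen once, from the published marginal summaries of
such warehouses):

* window 2435 days (≈ Aug 2017–Apr 2024), 38 hospitals with volumes
  ∝ rank^−0.7 and 0.8 home-site affinity per patient;
* sex ~ Bernoulli(0.46 male); 10% of patients receive a death date placed
  an Exp(180 d) delay after their last discharge;
* age at first stay from a paediatric + adult mixture — weight 0.252 on a
  Gamma(1.3, 3.0) child component (clipped at 17.5 y) and a truncated
  normal (μ = 7.15, σ = 68.78 on [18, 105]) adult bulk — calibrated so the
  median is ≈ 39.7 y with IQR ≈ [16, 66];
* stays per patient: zero-truncated negative binomial (r = 0.6, μ = 0.9;
  mean ≈ 2.1) sampled by inverse CDF above the zero mass; length of stay:
  discretised log-normal (μ = 0.9, σ = 1.0);
* admissions uniform over the window; the birth date is anchored to the
  earliest admission so the age target applies exactly to "age at first
  stay".

Injected cohorts (independent RNG streams derived from the master seed, so
injections never perturb the background draw):

* **epidemics** — yearly waves with wrapped-normal day-of-year around a
  peak week: bronchiolitis (J21.0, week 49, paediatric Gamma ages, median
  < 2 y) and influenza (J10.1, week 5, elderly Gamma ages, mean ≈ 66 y);
  250 expected cases/year per 5000 background patients;
* **pancreatic cancer** (C25.0) — treatment categories with probabilities
  surgery 0.25 / chemotherapy 0.45 / best supportive care 0.30, stored as
  marker codes on the index stay; exponential survival with median
  720/330/120 days; deaths beyond the window are censored; Poisson
  follow-up stays (3/8/1 expected per category) make pathways clusterable;
* **bariatric surgery** (K95.0) — index stays with a true 30-day
  readmission probability of 0.07 and Exp(10 d) delays truncated to
  [1, 60].

What the generator does **not** emulate: clinically coherent ICD-10
co-occurrence (codes are cohort markers), within-patient correlation of
stay timing beyond site affinity, secular trends, data-quality artefacts
(duplicate records, coding errors), and the sheer scale of a real
warehouse (~2 M patients). Passing tests therefore demonstrate the
*mechanics and ordering* of privacy/utility effects, not the absolute
risk figures of any real dataset — real-data uniqueness at a given
amplitude will differ, chiefly with dataset size and attribute richness.

## Studies and the unreliability indicator

* Ages are `(admission − birth)/365.25` years. Re-hospitalisation windows
  are closed: 90 days for the characterisation study, 30 for bariatric
  (day +30 counts, +31 does not), measured discharge → next same-patient
  admission, per discharge.
* Epidemic series are 7-day bins from the window start; admissions shifted
  outside the window drop out. The indicator is KL(original ‖
  pseudonymised) in nats after adding ε = 0.5 per bin and normalising
  (ε keeps the divergence finite on empty bins; the value is reported as a
  divergence, not a proportion).
* Survival: time zero is the index (earliest C25) admission, event =
  death. With window filtering **on** (default), diagnoses shifted outside
  the window are excluded and deaths shifted past it censored — this is
  the realistic release pipeline, where inclusion criteria are applied to
  the delivered dates. With filtering **off**, censoring is at the
  patient's last observed contact, so every duration is a difference of
  per-patient dates; this mode exists so that interval-preserving schemes
  can be shown to leave the entire analysis bit-identical. Cox fits use
  statsmodels' proportional-hazards regression with Breslow ties
  (covariates: age at diagnosis, sex, treatment vs best supportive care);
  durations are floored at 0.5 d for the fit; Kaplan–Meier via lifelines.
  Non-convergence is flagged on the result, not raised.
* Care pathways: each patient's profile is a count matrix over
  (hospital × 90-day period since first cancer stay, 8 periods), flattened,
  with age/100 × (total count) appended — birth information enters as age,
  never as an absolute date, which is what makes the base scheme exactly
  invariant. Distances are chi-squared between row profiles (Euclidean on
  profiles scaled by inverse square-root column masses, zero-mass columns
  dropped). Clustering is PAM k-medoids (greedy BUILD, best-improvement
  SWAP), fully deterministic, k = 4 by default. Six descriptors per
  cluster: size, median inter-stay gap, median stay duration, median stay
  count, median follow-up, median age.
* Unreliability: mean relative deviation |v′ − v| / |v| over the study's
  key statistics (0 when both sides are 0 or both undefined; an exact zero
  original with a nonzero pseudonymised value is reported as infinite and
  flagged rather than averaged). Epidemics use the KL divergence instead;
  care pathways average the descriptor deviations over clusters matched
  greedily by minimal descriptor disagreement.
* Studies sort their working frames by patient id before any
  floating-point reduction, so results on a base-shifted dataset are
  bit-identical to the original, not merely equal to rounding.

## Experiment orchestration and problem sizes

`run_experiment` executes a (scheme × Δt × study × scenario) grid on one
dataset: per cell it pseudonymises, recomputes all six studies against the
originals, builds each study's cohort (ICD-10-prefix criteria, evaluated
on the dataset's own — possibly shifted — dates) and evaluates uniqueness
for the random-target (search = total dataset) and target-in-cohort
(search = cohort) scenarios on a shared seeded target sample. Default
problem sizes — 5000 background patients, 300–500 sampled targets per
cell, 2000 patients for the two-parameter birth sweep — were chosen so a
full grid completes in minutes on a single core while leaving the
qualitative orderings stable across seeds; all sizes are parameters.

## Known limitations

* The random-target scenario adopts the standard assumption that an
  attacker can infer total-dataset uniqueness from the accessed subset;
  this inference is assumed, not simulated.
* Only singling-out is modelled; linkage and attribute-inference attacks,
  and richer attacker knowledge (labs, comorbidities), are out of scope —
  reported uniqueness is a lower bound in that sense.
* Seasonality-preserving shift schemes (e.g. shifts constrained to
  multiples of a year) are not implemented.
* The pathway featurisation and the cohort inclusion criteria are
  configurable stand-ins: real studies would use richer, protocol-specific
  definitions.
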