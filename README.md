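# dateshift

**Quantifying what date-shifting pseudonymisation buys — and costs — on
longitudinal hospital records.**

Clinical data warehouses release hospitalisation records (sex, birth and
death dates, admission/discharge dates, hospitals, ICD-10 codes) for
secondary research after *pseudonymisation* (here: random date shifting) and
*minimisation* (restricting the delivered cohort). Both reduce
re-identification risk; both can distort the studies the data were released
for. `dateshift` is a library for measuring that trade-off end to end on a
synthetic data warehouse, aimed at privacy researchers and the governance
teams who must pick a scheme and an amplitude.

## The model

Three date-shifting schemes, in increasing order of how much per-patient
temporal coherence they destroy (offsets are integers drawn uniformly on
closed intervals, one independent stream per patient):

| scheme | what shifts | what survives |
|---|---|---|
| **base** | every date of a patient by one δt ∈ [−Δt, +Δt] | all intra-patient intervals: age, gaps, time-to-death |
| **birth** | base, plus birth by an extra δt_birth ∈ [−Δt_birth, +Δt_birth] | intervals among stays/death; age perturbed ≤ Δt_birth |
| **stay** | birth, death and each stay by independent δt | each length of stay; order and gaps may break |

The attacker holds the **true** values of some quasi-identifiers of a target
(sex, birth date, stay dates, hospitals, death date) and knows the scheme
and its amplitudes (Kerckhoffs' principle). A pseudonymised record is
*compatible* with the target if some legal offset assignment maps the true
values exactly onto it; the target's k-anonymity is the number of compatible
records in the searched set, *uniqueness* the fraction of targets with
k = 1, and

```
P(success) = P(access) × P(unique | cohort),   P(access) = n_cohort / n_total
```

with P(access) = 1 when the attacker knows the target is in the cohort.
On the utility side, six archetypal studies (hospitalisation
characterisation, bronchiolitis and flu surveillance, 30-day bariatric
readmission, pancreatic-cancer survival with Kaplan–Meier + Cox, and
care-pathway k-medoids clustering) are re-run on pseudonymised data; an
*unreliability indicator* reports the mean relative deviation of each
study's key statistics (KL divergence of the weekly series for epidemics).

## Worked example

```python
from dateshift import (SyntheticConfig, generate_population, uniqueness_grid)

ds = generate_population(SyntheticConfig(n_patients=3000, seed=3))
grid = uniqueness_grid(ds, ("base", "birth", "stay"), (0, 7, 30, 100, 1000),
                       seed=5, target_sample=400)
print(grid.pivot(index="delta_t", columns="scheme", values="uniqueness"))
```

prints

```
scheme   base   birth    stay
delta_t
0         1.0  1.0000  1.0000
7         1.0  1.0000  1.0000
30        1.0  0.9950  0.9975
100       1.0  0.9950  0.9950
1000      1.0  0.9575  0.9600
```

Every record is unique to a fully informed attacker without protection.
The base scheme barely helps at any amplitude — the shared offset is pinned
by the stay dates, so the birth date must still match to the day — while
the birth and stay schemes, which decouple the timelines, start hiding
records once the amplitude is large. The utility mirror image
(`examples/study_reliability.py`):

```
scheme  delta_t  characterisation  bronchiolitis    flu  bariatric  survival  pathways
  base     1000            0.0000         1.1903 1.2916        0.0    1.1583    0.0000
 birth     1000            0.0002         1.1903 1.2916        0.0    1.0676    0.0016
  stay     1000            0.1706         1.1219 1.2830        1.0    4.0954    4.7456
  base        7            0.0000         0.0492 0.0462        0.0    0.0092    0.0000
```

base shifting is free for every interval-based statistic at any amplitude,
but already a 100-day shift flattens epidemic seasonality, and stay-level
shifting destroys readmission rates, survival curves and pathway clusters.

Each script in `examples/` demonstrates one capability: dataset generation,
scheme verification, attack simulation (with knowledge ablation and
k-suppression), study reliability, and the full trade-off report with
figures.

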