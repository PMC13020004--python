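"""Synthetic hospitalisation-record generator.

Emulates the statistical structure of a large multi-hospital clinical
data warehouse: ~46% male patients, ~10% with a recorded death, median
age at first stay ~39.7 years (IQR ~16-66), heavy-tailed stays-per-patient
and length-of-stay distributions, 38 hospitals with very unequal volumes
and per-patient site affinity. Epidemic waves (bronchiolitis, influenza),
a cancer survival cohort with treatment categories and follow-up stays,
and a surgical cohort with 30-day readmissions are injected on top of the
background population.

Everything is reproducible from a single master seed; the population,
each epidemic and each cohort injection consume independent derived
streams, so adding an injection never perturbs the background draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .core import DAYS_PER_YEAR, EHRDataset

# stream labels: (seed, _STREAMS[name]) seeds an independent Generator
_STREAMS = {"population": 0, "epidemic": 1, "survival": 2, "readmission": 3}


def _rng(seed: int, purpose: str, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[purpose], int(salt)]))


@dataclass
class EpidemicConfig:
    """Yearly-periodic wave of admissions carrying a fixed ICD-10 code.

    ``peak_week`` is the week of the epidemic year (0-51) around which
    admissions concentrate with spread ``sd_weeks``; ``annual_cases`` is
    the expected count per simulated year. The age profile is a gamma
    distribution (paediatric by default, matching bronchiolitis).
    """

    name: str = "bronchiolitis"
    code: str = "J21.0"
    annual_cases: int = 250
    peak_week: int = 49
    sd_weeks: float = 3.0
    age_gamma_shape: float = 1.5
    age_gamma_scale: float = 0.4
    los_lognorm_mu: float = 0.7
    los_lognorm_sigma: float = 0.7
    seed_salt: int = 0


def influenza_config(annual_cases: int = 250) -> EpidemicConfig:
    """Influenza preset: late-winter peak, elderly-skewed age profile."""
    return EpidemicConfig(
        name="flu",
        code="J10.1",
        annual_cases=annual_cases,
        peak_week=5,
        sd_weeks=3.0,
        age_gamma_shape=12.0,  # mean 66 y, sd ~19 y
        age_gamma_scale=5.5,
        seed_salt=1,
    )


#: treatment-category marker codes stored on the index diagnosis stay
TREATMENT_CODES = {
    "surgery": "TRT_SURGERY",
    "chemotherapy": "TRT_CHEMO",
    "bsc": "TRT_BSC",
}


@dataclass
class CancerConfig:
    """Incident cancer cohort with per-treatment exponential survival.

    Each case gets an index diagnosis stay carrying ``code`` plus a
    treatment marker code, an exponential survival time whose median
    depends on the treatment category, and a number of follow-up stays
    (also carrying ``code``) spread over the follow-up period — these
    make care pathways non-trivial to cluster. Deaths beyond the study
    window are censored (no death date recorded).
    """

    n_cases: int = 600
    code: str = "C25.0"
    treatment_probs: dict = field(
        default_factory=lambda: {"surgery": 0.25, "chemotherapy": 0.45, "bsc": 0.30}
    )
    median_survival_days: dict = field(
        default_factory=lambda: {"surgery": 720.0, "chemotherapy": 330.0, "bsc": 120.0}
    )
    followup_stays_mean: dict = field(
        default_factory=lambda: {"surgery": 3.0, "chemotherapy": 8.0, "bsc": 1.0}
    )
    age_normal_mu: float = 68.0
    age_normal_sigma: float = 10.0
    seed_salt: int = 0


@dataclass
class ReadmissionConfig:
    """Surgical cohort with a known true 30-day readmission probability."""

    n_index: int = 800
    marker_code: str = "K95.0"
    p_readmit: float = 0.07
    delay_exp_scale: float = 10.0  # days; truncated to [1, 60]
    age_normal_mu: float = 45.0
    age_normal_sigma: float = 11.0
    seed_salt: int = 0


@dataclass
class SyntheticConfig:
    """Parameters of the background population generator.

    Defaults emulate the marginal structure reported for a 38-hospital
    warehouse covering Aug 2017 - Apr 2024 (2435 days): Bernoulli(0.46)
    male, 10% deceased, age at first stay from a paediatric + adult
    mixture with median ~39.7 y, zero-truncated negative-binomial stays
    per patient (mean ~2.1), discretised log-normal length of stay and
    power-law hospital volumes with 0.8 home-site affinity.
    """

    n_patients: int = 5000
    n_hospitals: int = 38
    window_days: int = 2435
    p_male: float = 0.46
    p_death: float = 0.10
    # age-at-first-stay mixture: child gamma + adult truncated normal
    age_mixture: dict = field(
        default_factory=lambda: {
            "w_child": 0.252,
            "child_gamma_shape": 1.3,
            "child_gamma_scale": 3.0,
            "child_max": 17.5,
            "adult_mu": 7.15,
            "adult_sigma": 68.78,
            "adult_min": 18.0,
            "adult_max": 105.0,
        }
    )
    # zero-truncated negative binomial: r dispersion, mu untruncated mean
    stays_per_patient: dict = field(default_factory=lambda: {"r": 0.6, "mu": 0.9})
    # discretised log-normal length of stay
    los_distribution: dict = field(default_factory=lambda: {"mu": 0.9, "sigma": 1.0})
    hospital_zipf_exponent: float = 0.7
    home_affinity: float = 0.8
    death_delay_scale: float = 180.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_hospitals < 1:
            raise ValueError("n_hospitals must be >= 1")
        if self.window_days < 1:
            raise ValueError("window must be non-empty")
        for p in (self.p_male, self.p_death, self.home_affinity):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def hospital_weights(self) -> np.ndarray:
        w = np.arange(1, self.n_hospitals + 1, dtype=float) ** (-self.hospital_zipf_exponent)
        return w / w.sum()

    # -- YAML round trip -------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


# -- helpers -------------------------------------------------------------


def _sample_ages(rng: np.random.Generator, mix: dict, n: int) -> np.ndarray:
    child = np.clip(
        rng.gamma(mix["child_gamma_shape"], mix["child_gamma_scale"], n), 0, mix["child_max"]
    )
    a = (mix["adult_min"] - mix["adult_mu"]) / mix["adult_sigma"]
    b = (mix["adult_max"] - mix["adult_mu"]) / mix["adult_sigma"]
    adult = stats.truncnorm.rvs(
        a, b, loc=mix["adult_mu"], scale=mix["adult_sigma"], size=n, random_state=rng
    )
    return np.where(rng.random(n) < mix["w_child"], child, adult)


def _sample_zt_negbinom(rng: np.random.Generator, r: float, mu: float, n: int) -> np.ndarray:
    """Zero-truncated negative binomial via inverse-CDF above the zero mass."""
    p = r / (r + mu)
    p0 = stats.nbinom.pmf(0, r, p)
    u = p0 + rng.random(n) * (1.0 - p0)
    return stats.nbinom.ppf(u, r, p).astype(int)


def _sample_los(rng: np.random.Generator, los: dict, n: int) -> np.ndarray:
    return np.round(rng.lognormal(los["mu"], los["sigma"], n)).astype(int)


# -- main generator ------------------------------------------------------


def generate_population(config: SyntheticConfig) -> EHRDataset:
    """Draw the background population described by *config*.

    Admissions are placed uniformly over the study window; the patient's
    birth date is anchored so that the age at the *earliest* admission
    follows the configured mixture; deaths (fraction ``p_death``) occur
    an exponential delay after the last discharge.
    """
    config.validate()
    rng = _rng(config.seed, "population")
    n = config.n_patients

    sex = np.where(rng.random(n) < config.p_male, "M", "F")
    ages = _sample_ages(rng, config.age_mixture, n)
    n_stays = _sample_zt_negbinom(
        rng, config.stays_per_patient["r"], config.stays_per_patient["mu"], n
    )
    weights = config.hospital_weights()
    home = rng.choice(config.n_hospitals, size=n, p=weights) + 1

    total = int(n_stays.sum())
    owner = np.repeat(np.arange(n), n_stays)
    admission = rng.integers(0, config.window_days + 1, size=total)
    los = _sample_los(rng, config.los_distribution, total)
    away = rng.random(total) >= config.home_affinity
    hospital = np.where(
        away, rng.choice(config.n_hospitals, size=total, p=weights) + 1, home[owner]
    )

    first_adm = np.full(n, np.iinfo(np.int64).max)
    np.minimum.at(first_adm, owner, admission)
    birth = first_adm - np.round(ages * DAYS_PER_YEAR).astype(int)

    discharge = admission + los
    last_dis = np.zeros(n, dtype=int)
    np.maximum.at(last_dis, owner, discharge)
    dies = rng.random(n) < config.p_death
    delay = np.round(rng.exponential(config.death_delay_scale, n)).astype(int)
    death = np.where(dies, (last_dis + delay).astype(float), np.nan)

    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:07d}" for i in range(n)],
            "sex": sex,
            "birth_date": birth,
            "death_date": death,
        }
    )
    stays = pd.DataFrame(
        {
            "stay_id": [f"S{i:08d}" for i in range(total)],
            "patient_id": patients["patient_id"].to_numpy()[owner],
            "admission_date": admission.astype(int),
            "discharge_date": discharge.astype(int),
            "hospital_id": hospital.astype(int),
            "icd10_codes": "",
        }
    )
    ds = EHRDataset(patients, stays, (0, config.window_days), provenance="raw")
    ds.validate()
    return ds


def _append(dataset: EHRDataset, patients: pd.DataFrame, stays: pd.DataFrame) -> EHRDataset:
    return EHRDataset(
        pd.concat([dataset.patients, patients], ignore_index=True),
        pd.concat([dataset.stays, stays], ignore_index=True),
        dataset.study_window,
        dataset.provenance,
    )


def inject_epidemic(
    dataset: EHRDataset, epidemic: EpidemicConfig, config: SyntheticConfig
) -> EHRDataset:
    """Add a yearly-periodic wave of coded admissions to *dataset*.

    Admission days-of-year are drawn from a wrapped normal around
    ``peak_week``; cases are new patients whose age follows the
    epidemic's gamma profile. With ``annual_cases == 0`` the dataset is
    returned unchanged (a copy).
    """
    if not epidemic.code:
        raise ValueError("epidemic config must name an ICD-10 code")
    if epidemic.annual_cases == 0:
        return dataset.copy()
    rng = _rng(config.seed, "epidemic", epidemic.seed_salt)
    start, end = dataset.study_window
    n_years = int(np.ceil((end - start) / 365.0))
    weights = config.hospital_weights()

    rows_p, rows_s = [], []
    idx = 0
    for year in range(n_years):
        n_cases = rng.poisson(epidemic.annual_cases)
        day_of_year = np.mod(
            epidemic.peak_week * 7 + 3 + np.round(rng.normal(0, epidemic.sd_weeks * 7, n_cases)),
            365,
        ).astype(int)
        adm = start + year * 365 + day_of_year
        ages = rng.gamma(epidemic.age_gamma_shape, epidemic.age_gamma_scale, n_cases)
        los = np.round(
            rng.lognormal(epidemic.los_lognorm_mu, epidemic.los_lognorm_sigma, n_cases)
        ).astype(int)
        hosp = rng.choice(config.n_hospitals, size=n_cases, p=weights) + 1
        sex = np.where(rng.random(n_cases) < 0.5, "M", "F")
        for i in range(n_cases):
            if not (start <= adm[i] <= end):
                continue
            pid = f"{epidemic.name[:2].upper()}{epidemic.seed_salt}_{idx:06d}"
            rows_p.append(
                (pid, sex[i], int(adm[i] - round(ages[i] * DAYS_PER_YEAR)), np.nan)
            )
            rows_s.append(
                (
                    f"S{epidemic.name[:2].upper()}{epidemic.seed_salt}_{idx:07d}",
                    pid,
                    int(adm[i]),
                    int(adm[i] + los[i]),
                    int(hosp[i]),
                    epidemic.code,
                )
            )
            idx += 1

    patients = pd.DataFrame(rows_p, columns=["patient_id", "sex", "birth_date", "death_date"])
    stays = pd.DataFrame(
        rows_s,
        columns=[
            "stay_id",
            "patient_id",
            "admission_date",
            "discharge_date",
            "hospital_id",
            "icd10_codes",
        ],
    )
    return _append(dataset, patients, stays)


def inject_survival_cohort(
    dataset: EHRDataset, cancer: CancerConfig, config: SyntheticConfig
) -> EHRDataset:
    """Add an incident cancer cohort with treatment-dependent survival."""
    probs = cancer.treatment_probs
    if abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ValueError("treatment probabilities must sum to 1")
    if cancer.n_cases == 0:
        return dataset.copy()
    rng = _rng(config.seed, "survival", cancer.seed_salt)
    start, end = dataset.study_window
    weights = config.hospital_weights()
    categories = list(probs)
    cat_idx = rng.choice(len(categories), size=cancer.n_cases, p=[probs[c] for c in categories])

    rows_p, rows_s = [], []
    sid = 0
    for i in range(cancer.n_cases):
        cat = categories[cat_idx[i]]
        pid = f"CA{cancer.seed_salt}_{i:06d}"
        index_adm = int(rng.integers(start, end + 1))
        age = float(
            np.clip(rng.normal(cancer.age_normal_mu, cancer.age_normal_sigma), 25, 100)
        )
        birth = index_adm - int(round(age * DAYS_PER_YEAR))
        sex = "M" if rng.random() < 0.5 else "F"
        hosp = int(rng.choice(config.n_hospitals, p=weights) + 1)
        median = cancer.median_survival_days[cat]
        if median <= 0 or np.isinf(median):
            surv = np.inf
        else:
            surv = rng.exponential(median / np.log(2))
        death_day = index_adm + int(round(surv)) if np.isfinite(surv) else None
        censored = death_day is None or death_day > end
        death = np.nan if censored else float(death_day)
        followup_end = min(end, death_day) if death_day is not None else end

        index_los = int(np.round(rng.lognormal(1.5, 0.5)))
        rows_p.append((pid, sex, birth, death))
        rows_s.append(
            (
                f"SCA{cancer.seed_salt}_{sid:07d}",
                pid,
                index_adm,
                min(index_adm + index_los, int(followup_end)) if not censored else index_adm + index_los,
                hosp,
                f"{cancer.code};{TREATMENT_CODES[cat]}",
            )
        )
        sid += 1
        n_follow = rng.poisson(cancer.followup_stays_mean[cat])
        horizon = followup_end - index_adm
        if horizon > 1:
            offsets = np.sort(rng.integers(1, horizon + 1, size=n_follow))
            for off in offsets:
                adm = index_adm + int(off)
                los = int(np.round(rng.lognormal(0.8, 0.6)))
                dis = min(adm + los, int(followup_end)) if not censored else adm + los
                rows_s.append(
                    (f"SCA{cancer.seed_salt}_{sid:07d}", pid, adm, max(dis, adm), hosp, cancer.code)
                )
                sid += 1

    patients = pd.DataFrame(rows_p, columns=["patient_id", "sex", "birth_date", "death_date"])
    stays = pd.DataFrame(
        rows_s,
        columns=[
            "stay_id",
            "patient_id",
            "admission_date",
            "discharge_date",
            "hospital_id",
            "icd10_codes",
        ],
    )
    return _append(dataset, patients, stays)


def inject_readmission_cohort(
    dataset: EHRDataset, proc: ReadmissionConfig, config: SyntheticConfig
) -> EHRDataset:
    """Add index surgical stays with Bernoulli(p) 30-day readmissions."""
    if not 0.0 <= proc.p_readmit <= 1.0:
        raise ValueError("p_readmit must lie in [0, 1]")
    if proc.n_index == 0:
        return dataset.copy()
    rng = _rng(config.seed, "readmission", proc.seed_salt)
    start, end = dataset.study_window
    weights = config.hospital_weights()

    rows_p, rows_s = [], []
    sid = 0
    for i in range(proc.n_index):
        pid = f"BA{proc.seed_salt}_{i:06d}"
        adm = int(rng.integers(start, max(start + 1, end - 90)))
        age = float(np.clip(rng.normal(proc.age_normal_mu, proc.age_normal_sigma), 18, 75))
        birth = adm - int(round(age * DAYS_PER_YEAR))
        sex = "M" if rng.random() < 0.30 else "F"  # bariatric cohorts skew female
        hosp = int(rng.choice(config.n_hospitals, p=weights) + 1)
        los = int(np.round(rng.lognormal(1.2, 0.4)))
        rows_p.append((pid, sex, birth, np.nan))
        rows_s.append(
            (f"SBA{proc.seed_salt}_{sid:07d}", pid, adm, adm + los, hosp, proc.marker_code)
        )
        sid += 1
        if rng.random() < proc.p_readmit:
            delay = int(np.clip(np.round(rng.exponential(proc.delay_exp_scale)), 1, 60))
            radm = adm + los + delay
            rlos = int(np.round(rng.lognormal(0.8, 0.5)))
            rows_s.append((f"SBA{proc.seed_salt}_{sid:07d}", pid, radm, radm + rlos, hosp, ""))
            sid += 1

    patients = pd.DataFrame(rows_p, columns=["patient_id", "sex", "birth_date", "death_date"])
    stays = pd.DataFrame(
        rows_s,
        columns=[
            "stay_id",
            "patient_id",
            "admission_date",
            "discharge_date",
            "hospital_id",
            "icd10_codes",
        ],
    )
    return _append(dataset, patients, stays)


def generate_full_dataset(
    config: SyntheticConfig,
    epidemics: list[EpidemicConfig] | None = None,
    cancer: CancerConfig | None = None,
    readmission: ReadmissionConfig | None = None,
) -> EHRDataset:
    """Background population plus the standard study cohorts.

    With no arguments beyond *config*, injects the default bronchiolitis
    and influenza waves, the cancer survival cohort and the surgical
    readmission cohort, all scaled relative to ``config.n_patients``.
    """
    scale = config.n_patients / 5000.0
    if epidemics is None:
        epidemics = [
            EpidemicConfig(annual_cases=max(1, int(250 * scale))),
            influenza_config(annual_cases=max(1, int(250 * scale))),
        ]
    if cancer is None:
        cancer = CancerConfig(n_cases=max(4, int(600 * scale)))
    if readmission is None:
        readmission = ReadmissionConfig(n_index=max(4, int(800 * scale)))
    ds = generate_population(config)
    for epi in epidemics:
        ds = inject_epidemic(ds, epi, config)
    ds = inject_survival_cohort(ds, cancer, config)
    ds = inject_readmission_cohort(ds, readmission, config)
    ds.validate()
    return ds


def summarise_dataset(dataset: EHRDataset) -> dict:
    """Marginal summary: counts, sex/death fractions, age / LOS / volume quantiles."""
    if dataset.n_patients == 0 or dataset.n_stays == 0:
        raise ValueError("cannot summarise an empty dataset")
    first = dataset.first_admissions()
    los = dataset.stays["discharge_date"] - dataset.stays["admission_date"]
    per_patient = dataset.stays.groupby("patient_id").size()
    age_q = first["age_years"].quantile([0.25, 0.5, 0.75])
    return {
        "n_patients": int(dataset.n_patients),
        "n_stays": int(dataset.n_stays),
        "male_fraction": float((dataset.patients["sex"] == "M").mean()),
        "death_fraction": float(dataset.patients["death_date"].notna().mean()),
        "median_age_first_stay": float(age_q.loc[0.5]),
        "age_iqr": (float(age_q.loc[0.25]), float(age_q.loc[0.75])),
        "los_quantiles": {
            q: float(los.quantile(q)) for q in (0.25, 0.5, 0.75, 0.95)
        },
        "stays_per_patient_quantiles": {
            q: float(per_patient.quantile(q)) for q in (0.5, 0.75, 0.95)
        },
        "stays_per_hospital": dataset.stays["hospital_id"].value_counts().to_dict(),
    }
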