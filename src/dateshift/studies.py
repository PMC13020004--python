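"""Archetypal EHR epidemiological studies and the unreliability indicator.

Six study archetypes are implemented: characterisation of all
hospitalisations, two seasonal-epidemic surveillance studies
(weekly admission counts), 30-day readmission after surgery,
survival of an incident cancer cohort (Kaplan-Meier + Cox), and
care-pathway clustering (chi-squared distance + PAM k-medoids).

Each study returns a :class:`StudyResult`; running the same study on the
original and on a pseudonymised dataset and comparing with
:func:`unreliability` yields a scalar deviation score — the mean
relative deviation of the study's key statistics, or the
Kullback-Leibler divergence of the weekly series for the epidemic
studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.special import rel_entr
from statsmodels.duration.hazard_regression import PHReg

from .core import DAYS_PER_YEAR, EHRDataset
from .synthetic import TREATMENT_CODES

EPIDEMIC_PREFIX = "epidemic:"


@dataclass
class StudyResult:
    """Named statistics of one study on one dataset.

    ``series`` is the weekly admission-count vector for epidemic
    studies; ``curve`` the Kaplan-Meier step function; ``memberships``
    and ``descriptors`` the clustering output for care pathways.
    """

    study: str
    statistics: dict
    series: np.ndarray | None = None
    week_origin: int | None = None
    curve: pd.DataFrame | None = None
    memberships: pd.DataFrame | None = None
    descriptors: pd.DataFrame | None = None
    flags: list = field(default_factory=list)


@dataclass
class UnreliabilityScore:
    """Scalar deviation between original and pseudonymised results.

    For non-epidemic studies the value is the mean of the per-statistic
    relative deviations and reads as a proportion of the original
    result; 0 means the pseudonymised study reproduced the original
    exactly.
    """

    value: float
    components: dict
    flags: list = field(default_factory=list)


# -- helper views --------------------------------------------------------


def _codes_match(codes: pd.Series, prefix: str) -> pd.Series:
    return codes.fillna("").map(
        lambda s: any(c.startswith(prefix) for c in s.split(";") if c)
    )


def _sorted_stays(dataset: EHRDataset) -> pd.DataFrame:
    return dataset.stays.sort_values(
        ["patient_id", "admission_date", "stay_id"], kind="stable"
    )


# -- study 1: characterisation of all hospitalisations -------------------


def study_hosp_characterisation(dataset: EHRDataset) -> StudyResult:
    """Mean/sd age at first admission and 3-month re-hospitalisation rate.

    The re-hospitalisation rate is measured per discharge: the fraction
    of discharges followed by a same-patient admission within 90 days
    (closed bound).
    """
    if dataset.n_stays == 0:
        raise ValueError("dataset has no stays")
    first = dataset.first_admissions().sort_values("patient_id")
    stays = _sorted_stays(dataset)
    next_adm = stays.groupby("patient_id")["admission_date"].shift(-1)
    rehosp = (next_adm - stays["discharge_date"]) <= 90
    return StudyResult(
        study="hosp_characterisation",
        statistics={
            "mean_age_first_admission": float(first["age_years"].mean()),
            "sd_age_first_admission": float(first["age_years"].std(ddof=1)),
            "rehosp_3m_rate": float(rehosp.fillna(False).mean()),
        },
    )


# -- studies 2 & 3: seasonal epidemics -----------------------------------


def study_epidemic(
    dataset: EHRDataset, icd_prefix: str, week_origin: int | None = None
) -> StudyResult:
    """Weekly admission counts and mean age for one coded epidemic.

    Weeks are consecutive 7-day bins from ``week_origin`` (defaults to
    the study-window start); admissions shifted outside the window fall
    out of the histogram.
    """
    start, end = dataset.study_window
    if week_origin is None:
        week_origin = start
    sel = dataset.stays[_codes_match(dataset.stays["icd10_codes"], icd_prefix)]
    n_weeks = int(np.ceil((end - week_origin + 1) / 7))
    adm = sel["admission_date"].to_numpy()
    in_window = (adm >= week_origin) & (adm <= end)
    weeks = (adm[in_window] - week_origin) // 7
    series = np.bincount(weeks.astype(int), minlength=n_weeks)[:n_weeks]

    birth = sel["patient_id"].map(
        dict(zip(dataset.patients["patient_id"], dataset.patients["birth_date"]))
    )
    ages = (sel["admission_date"] - birth) / DAYS_PER_YEAR
    return StudyResult(
        study=f"{EPIDEMIC_PREFIX}{icd_prefix}",
        statistics={
            "mean_age_admission": float(ages.mean()) if len(ages) else float("nan"),
            "n_admissions": int(len(sel)),
        },
        series=series,
        week_origin=week_origin,
    )


def kl_divergence(
    p_series: np.ndarray, q_series: np.ndarray, epsilon: float = 0.5
) -> float:
    """KL(P || Q) in nats between two weekly count series.

    Both series are smoothed by adding *epsilon* to every bin and
    normalised; P is the original series, Q the pseudonymised one.
    """
    p = np.asarray(p_series, dtype=float)
    q = np.asarray(q_series, dtype=float)
    if p.shape != q.shape:
        raise ValueError("series lengths differ")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("series must be non-negative")
    p = p + epsilon
    q = q + epsilon
    if p.sum() == 0 or q.sum() == 0:
        raise ValueError("series must not be all zero")
    return float(rel_entr(p / p.sum(), q / q.sum()).sum())


# -- study 4: readmission after surgery ----------------------------------


def study_bariatric(dataset: EHRDataset, marker_prefix: str = "K95") -> StudyResult:
    """30-day readmission rate after marker-coded index stays.

    A readmission is any same-patient admission strictly after the index
    discharge and at most 30 days later (day +30 counts, +31 does not).
    """
    index = dataset.stays[_codes_match(dataset.stays["icd10_codes"], marker_prefix)]
    if index.empty:
        raise ValueError("no index stays carry the marker code")
    adm_by_pid: dict[str, np.ndarray] = {
        pid: np.sort(g["admission_date"].to_numpy())
        for pid, g in dataset.stays.groupby("patient_id")
    }
    readmitted = 0
    for pid, dis in zip(index["patient_id"], index["discharge_date"]):
        adms = adm_by_pid[pid]
        lo = np.searchsorted(adms, dis, side="right")
        hi = np.searchsorted(adms, dis + 30, side="right")
        if hi > lo:
            readmitted += 1
    return StudyResult(
        study="bariatric",
        statistics={"readmit_30d_rate": readmitted / len(index)},
    )


# -- study 5: cancer survival --------------------------------------------


def _survival_frame(
    dataset: EHRDataset,
    code_prefix: str,
    window: tuple[int, int],
    window_filter: bool,
) -> pd.DataFrame:
    stays = dataset.stays[_codes_match(dataset.stays["icd10_codes"], code_prefix)]
    index = (
        stays.sort_values(["admission_date", "stay_id"], kind="stable")
        .groupby("patient_id", sort=False)
        .first()
        .reset_index()
    )
    df = index.merge(dataset.patients, on="patient_id")
    if window_filter:
        df = df[df["admission_date"].between(*window)]
    start, end = window
    death = df["death_date"]
    event = death.notna()
    if window_filter:
        # absolute administrative censoring at the window end
        event &= death <= end
        censor_time = end - df["admission_date"]
    else:
        # censor at the patient's last observed contact so that all
        # durations are differences of per-patient dates
        last_contact = df["patient_id"].map(
            dataset.stays.groupby("patient_id")["discharge_date"].max()
        )
        censor_time = last_contact - df["admission_date"]
    duration = np.where(event, death - df["admission_date"], censor_time)
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "duration": np.maximum(duration, 0.0),
            "event": event.astype(int).to_numpy(),
            "age_dx": (df["admission_date"] - df["birth_date"]) / DAYS_PER_YEAR,
            "sex_male": (df["sex"] == "M").astype(int).to_numpy(),
        }
    )
    for cat, code in TREATMENT_CODES.items():
        out[f"treat_{cat}"] = (
            df["icd10_codes"].fillna("").str.contains(code, regex=False).astype(int).to_numpy()
        )
    # canonical row order: keeps floating-point reductions identical when
    # only the absolute (shifted) dates differ between datasets
    return out.sort_values("patient_id").reset_index(drop=True)


def study_survival(
    dataset: EHRDataset,
    code_prefix: str = "C25",
    window: tuple[int, int] | None = None,
    window_filter: bool = True,
) -> StudyResult:
    """Kaplan-Meier curve and Cox model for the incident cancer cohort.

    Time zero is the index diagnosis admission; the event is death,
    censored at the window end. The Cox model includes sex, age at
    diagnosis and treatment category (reference: exclusive best
    supportive care), with Breslow tie handling. With ``window_filter``
    on, patients whose (possibly shifted) diagnosis falls outside the
    window are excluded and deaths shifted beyond it count as censored.
    """
    if window is None:
        window = dataset.study_window
    df = _survival_frame(dataset, code_prefix, window, window_filter)
    if df.empty:
        raise ValueError("no subjects in the survival cohort")

    kmf = KaplanMeierFitter()
    kmf.fit(df["duration"], event_observed=df["event"])
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    surv_365 = float(kmf.predict(365.0))

    stats = {
        "n_subjects": int(len(df)),
        "n_events": int(df["event"].sum()),
        "km_surv_365": surv_365,
    }
    flags = []
    covars = ["age_dx", "sex_male", "treat_surgery", "treat_chemotherapy"]
    try:
        model = PHReg(
            np.maximum(df["duration"].to_numpy(), 0.5),
            df[covars].to_numpy(dtype=float),
            status=df["event"].to_numpy(),
            ties="breslow",
        )
        res = model.fit(disp=False)
        for name, coef in zip(covars, res.params):
            stats[f"cox_{name}"] = float(coef)
    except Exception as exc:  # noqa: BLE001 - non-convergence is a flagged result
        flags.append(f"cox_fit_failed: {exc}")
    return StudyResult(study="pancreatic_survival", statistics=stats, curve=curve, flags=flags)


# -- study 6: care pathways ----------------------------------------------


def _pam_kmedoids(D: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """PAM (BUILD + SWAP) k-medoids on a precomputed distance matrix.

    Fully deterministic: BUILD greedily seeds the medoids, SWAP takes
    the best improving (medoid, candidate) exchange until none exists.
    Returns the sorted medoid indices.
    """
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=0)))]
    while len(medoids) < k:
        nearest = D[:, medoids].min(axis=1)
        gains = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    for _ in range(max_iter):
        nearest = D[:, medoids].min(axis=1)
        total = nearest.sum()
        best_delta, best_swap = 1e-9, None
        for mi in range(len(medoids)):
            others = medoids[:mi] + medoids[mi + 1 :]
            d_others = D[:, others].min(axis=1) if others else np.full(n, np.inf)
            # all candidate replacements at once: n x n is fine at study scale
            new_totals = np.minimum(d_others[:, None], D).sum(axis=0)
            new_totals[medoids] = np.inf
            h = int(np.argmin(new_totals))
            delta = total - new_totals[h]
            if delta > best_delta:
                best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    return np.array(sorted(medoids))


def _chi2_distances(X: np.ndarray) -> np.ndarray:
    """Chi-squared distances between row profiles (correspondence form)."""
    X = np.asarray(X, dtype=float)
    col_mass = X.sum(axis=0)
    keep = col_mass > 0
    X = X[:, keep]
    col_mass = col_mass[keep] / X.sum()
    profiles = X / X.sum(axis=1, keepdims=True)
    Y = profiles / np.sqrt(col_mass)
    sq = ((Y[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)
    return np.sqrt(np.maximum(sq, 0.0))


#: the six per-cluster descriptors reported for care-pathway clusters
PATHWAY_DESCRIPTORS = (
    "n_patients",
    "median_interstay_days",
    "median_stay_duration",
    "median_n_stays",
    "median_followup_days",
    "median_age_admission",
)


def study_care_pathways(
    dataset: EHRDataset,
    code_prefix: str = "C25",
    k_clusters: int = 4,
    seed: int = 0,
    n_periods: int = 8,
    period_days: int = 90,
) -> StudyResult:
    """Cluster cancer patients' care pathways and describe each cluster.

    Each patient's pathway profile is a count vector over (hospital x
    90-day period since the first cancer stay, 8 periods), with an
    age-at-first-stay feature appended scaled to the counts' total so
    birth information enters as age, not as an absolute date. Pairwise
    chi-squared distances feed a deterministic PAM k-medoids; each
    cluster is described by six healthcare-utilisation descriptors.

    *seed* is part of the interface for forward compatibility with
    stochastic initialisation; the PAM used here is deterministic.
    """
    del seed  # deterministic PAM; see docstring
    marked = dataset.stays[_codes_match(dataset.stays["icd10_codes"], code_prefix)]
    anchor = (
        marked.sort_values(["admission_date", "stay_id"], kind="stable")
        .groupby("patient_id", sort=False)["admission_date"]
        .first()
    )
    pids = sorted(anchor.index)
    if len(pids) < k_clusters:
        raise ValueError("fewer patients than clusters")
    birth = dict(zip(dataset.patients["patient_id"], dataset.patients["birth_date"]))
    hospitals = sorted(dataset.stays["hospital_id"].unique())
    h_index = {h: i for i, h in enumerate(hospitals)}
    n_h = len(hospitals)

    stays_by_pid = {
        pid: g for pid, g in dataset.stays.groupby("patient_id") if pid in anchor.index
    }
    X = np.zeros((len(pids), n_h * n_periods + 1))
    per_patient_rows = []
    for r, pid in enumerate(pids):
        a0 = anchor[pid]
        g = stays_by_pid[pid]
        rel = g["admission_date"].to_numpy() - a0
        in_h = (rel >= 0) & (rel < n_periods * period_days)
        sel = g[in_h]
        for adm, dis, hosp in zip(
            sel["admission_date"], sel["discharge_date"], sel["hospital_id"]
        ):
            X[r, h_index[hosp] * n_periods + (adm - a0) // period_days] += 1
        total = max(X[r, :-1].sum(), 1.0)
        age = (a0 - birth[pid]) / DAYS_PER_YEAR
        X[r, -1] = age / 100.0 * total

        sel_sorted = sel.sort_values(["admission_date", "stay_id"], kind="stable")
        adms = sel_sorted["admission_date"].to_numpy()
        diss = sel_sorted["discharge_date"].to_numpy()
        gaps = adms[1:] - diss[:-1] if len(adms) > 1 else np.array([])
        per_patient_rows.append(
            {
                "patient_id": pid,
                "n_stays": len(sel_sorted),
                "median_gap": float(np.median(gaps)) if len(gaps) else np.nan,
                "median_los": float(np.median(diss - adms)) if len(adms) else np.nan,
                "followup": float(diss.max() - adms.min()) if len(adms) else 0.0,
                "age": age,
            }
        )

    D = _chi2_distances(X)
    medoids = _pam_kmedoids(D, k_clusters)
    labels = np.argmin(D[:, medoids], axis=1)
    per_patient = pd.DataFrame(per_patient_rows)
    per_patient["cluster"] = labels

    def _median(series: pd.Series) -> float:
        values = series.dropna()
        return float(values.median()) if len(values) else float("nan")

    rows = []
    for c in range(k_clusters):
        grp = per_patient[per_patient["cluster"] == c]
        rows.append(
            {
                "cluster": c,
                "n_patients": int(len(grp)),
                "median_interstay_days": _median(grp["median_gap"]),
                "median_stay_duration": _median(grp["median_los"]),
                "median_n_stays": float(grp["n_stays"].median()),
                "median_followup_days": float(grp["followup"].median()),
                "median_age_admission": float(grp["age"].median()),
            }
        )
    descriptors = pd.DataFrame(rows).set_index("cluster")
    return StudyResult(
        study="care_pathways",
        statistics={"n_clusters": k_clusters, "n_patients": len(pids)},
        memberships=per_patient[["patient_id", "cluster"]],
        descriptors=descriptors,
    )


# -- the unreliability indicator -----------------------------------------


def _relative_deviation(orig: float, pseudo: float) -> float:
    if np.isnan(orig) or np.isnan(pseudo):
        # undefined on both sides (e.g. sd of a single subject) is no deviation
        return 0.0 if np.isnan(orig) and np.isnan(pseudo) else float("inf")
    if orig == pseudo:
        return 0.0
    if orig == 0:
        return float("inf")
    return abs(pseudo - orig) / abs(orig)


def _match_clusters(
    orig: pd.DataFrame, pseudo: pd.DataFrame
) -> list[tuple[int, int, float]]:
    """Greedy cluster pairing by minimal mean descriptor deviation."""
    cost = {}
    for i in orig.index:
        for j in pseudo.index:
            devs = [
                _relative_deviation(float(orig.loc[i, c]), float(pseudo.loc[j, c]))
                for c in PATHWAY_DESCRIPTORS
                if not (np.isnan(orig.loc[i, c]) and np.isnan(pseudo.loc[j, c]))
            ]
            finite = [v for v in devs if np.isfinite(v)]
            cost[(i, j)] = np.mean(finite) if finite else float("inf")
    pairs = []
    used_i, used_j = set(), set()
    for (i, j), c in sorted(cost.items(), key=lambda kv: (kv[1], kv[0])):
        if i not in used_i and j not in used_j:
            pairs.append((i, j, c))
            used_i.add(i)
            used_j.add(j)
    return pairs


def unreliability(
    original: StudyResult, pseudo: StudyResult, kl_epsilon: float = 0.5
) -> UnreliabilityScore:
    """Deviation of the pseudonymised study's results from the original.

    Epidemic studies: KL divergence of the weekly series. Care
    pathways: mean relative deviation of the six descriptors over
    greedily matched clusters. All other studies: mean relative
    deviation of the key scalar statistics.
    """
    if original.study != pseudo.study:
        raise ValueError("study types differ")
    flags: list[str] = []

    if original.study.startswith(EPIDEMIC_PREFIX):
        kl = kl_divergence(original.series, pseudo.series, epsilon=kl_epsilon)
        return UnreliabilityScore(value=kl, components={"kl_divergence": kl})

    if original.study == "care_pathways":
        components: dict[str, float] = {}
        devs = []
        for i, j, _ in _match_clusters(original.descriptors, pseudo.descriptors):
            for c in PATHWAY_DESCRIPTORS:
                a, b = float(original.descriptors.loc[i, c]), float(pseudo.descriptors.loc[j, c])
                if np.isnan(a) and np.isnan(b):
                    continue
                dev = _relative_deviation(a, b)
                components[f"cluster{i}->{j}:{c}"] = dev
                if np.isinf(dev):
                    flags.append(f"original zero with nonzero pseudo: cluster{i}:{c}")
                else:
                    devs.append(dev)
        value = float(np.mean(devs)) if devs else 0.0
        return UnreliabilityScore(value=value, components=components, flags=flags)

    keys = [
        k
        for k in original.statistics
        if k in pseudo.statistics and isinstance(original.statistics[k], (int, float))
    ]
    components = {}
    devs = []
    for k in keys:
        dev = _relative_deviation(float(original.statistics[k]), float(pseudo.statistics[k]))
        components[k] = dev
        if np.isinf(dev):
            flags.append(f"original zero with nonzero pseudo: {k}")
        else:
            devs.append(dev)
    value = float(np.mean(devs)) if devs else 0.0
    return UnreliabilityScore(value=value, components=components, flags=flags)
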