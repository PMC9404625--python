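"""Synthetic ICU cohort generator for continuous-infusion piperacillin TDM.

Emulates the covariate structure of the two study sites (a Belgian surgical
ICU, "GUH", and a Dutch external cohort, "UMCG"): demographics and labs are
drawn from distributions matched to the published medians and interquartile
ranges (log-normal for skewed labs, normal for anthropometrics), creatinine
clearance is coupled to age/weight/sex/serum-creatinine through a
Cockcroft-Gault-shaped dependence, dosing follows each site's
renal-function-banded protocol, and "true" concentrations come from the
two-compartment PopPK model with log-normal inter-individual variability
plus a combined proportional + additive residual error.  Missingness can be
injected at the per-feature rates observed in the original data, and the
published imputation rules and patient-level train/test split are
reproduced — so the full predict -> quantify -> calibrate -> classify
pipeline is testable without the restricted hospital data.

What the generator deliberately does **not** emulate: within-day covariate
dynamics, renal replacement therapy / ECMO patients (excluded from the
studies), correlated lab panels beyond the renal axis, or non-steady-state
sampling.  A green test on this data establishes pipeline correctness and
statistical behaviour under the stated model, not clinical performance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import clinical, poppk
from .poppk import TypicalValues

__all__ = [
    "PatientProfile",
    "NoiseModel",
    "generate_cohort",
    "simulate_records",
    "inject_missingness",
    "impute",
    "split_patients",
    "heteroscedastic_regression_data",
    "DEFAULT_MISSING_RATES",
    "RECORD_COLUMNS",
]

logger = logging.getLogger(__name__)

# named substreams fanned out from the single user seed
_STREAMS = {"cohort": 0, "records": 1, "iiv": 2, "residual": 3, "missingness": 4, "split": 5, "hetero": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[stream])))


# ---------------------------------------------------------------------------
# covariate targets: (median, q1, q3, family) per site
# ---------------------------------------------------------------------------

_GUH_TARGETS = {
    "age": (64.0, 53.0, 74.0, "normal"),
    "height": (170.0, 165.0, 178.0, "normal"),
    "weight": (75.0, 64.2, 85.0, "normal"),
    "scr": (0.69, 0.51, 1.04, "lognormal"),
    "albumin": (23.0, 20.0, 26.0, "normal"),
    "platelets": (281.0, 174.0, 414.0, "lognormal"),
    "lactate": (10.9, 8.5, 14.3, "lognormal"),
    "wbc": (12.6, 9.9, 16.9, "lognormal"),
    "bilirubin": (0.60, 0.40, 1.10, "lognormal"),
    "fluid_balance": (421.9, -359.7, 1399.3, "normal"),
    "sofa": (5.0, 3.0, 8.0, "lognormal"),
    # below: not tabulated in the source cohorts; realistic ICU choices
    "temperature": (37.0, 36.6, 37.6, "normal"),
    "urine_creatinine": (45.0, 25.0, 80.0, "lognormal"),
    "hemoglobin": (10.5, 9.5, 11.8, "normal"),
    "rbc": (3.6, 3.2, 4.1, "normal"),
}

_UMCG_TARGETS = {
    **_GUH_TARGETS,
    "age": (60.0, 54.0, 66.0, "normal"),
    "height": (175.0, 172.0, 178.0, "normal"),
    "weight": (77.0, 70.0, 90.0, "normal"),
    "scr": (0.76, 0.52, 1.33, "lognormal"),
    "albumin": (22.5, 19.0, 26.0, "normal"),
    "platelets": (160.0, 123.5, 199.2, "lognormal"),
    "lactate": (12.0, 9.0, 18.0, "lognormal"),
    "wbc": (11.7, 8.5, 19.5, "lognormal"),
    "bilirubin": (0.99, 0.36, 2.70, "lognormal"),
    "fluid_balance": (816.5, -210.0, 2328.2, "normal"),
    "sofa": (12.0, 9.0, 14.0, "lognormal"),
}

_SITE_TARGETS = {"GUH": _GUH_TARGETS, "UMCG": _UMCG_TARGETS}
_MALE_FRACTION = {"GUH": 0.649, "UMCG": 0.87}
_CLCR_TARGET_MEDIAN = {"GUH": 107.5, "UMCG": 96.9}
#: extra log-normal dispersion of CLcr on top of the Cockcroft-Gault coupling
_CLCR_EXTRA_LOG_SD = 0.25

# physiologic clipping ranges
_CLIPS = {
    "age": (18.0, 100.0),
    "height": (140.0, 210.0),
    "weight": (30.0, 250.0),
    "scr": (0.1, 15.0),
    "albumin": (5.0, 55.0),
    "platelets": (5.0, 1500.0),
    "lactate": (1.0, 200.0),
    "wbc": (0.5, 80.0),
    "bilirubin": (0.05, 40.0),
    "fluid_balance": (-8000.0, 12000.0),
    "sofa": (0.0, 24.0),
    "temperature": (33.0, 42.0),
    "urine_creatinine": (2.0, 400.0),
    "hemoglobin": (4.0, 20.0),
    "rbc": (1.5, 7.0),
    "clcr": (1.0, 300.0),
}

_IQR_TO_SD = 2.0 * 0.6744897501960817  # q3 - q1 in standard-normal units

#: Per-feature missingness rates (fraction of records), derived from the
#: published per-feature missing counts out of N = 752 records.
DEFAULT_MISSING_RATES = {
    "albumin": 13 / 752,
    "bilirubin": 19 / 752,
    "clcr": 100 / 752,
    "height": 6 / 752,
    "hemoglobin": 7 / 752,
    "lactate": 5 / 752,
    "platelets": 7 / 752,
    "scr": 14 / 752,
    "sofa": 32 / 752,
    "temperature": 107 / 752,
    "urine_creatinine": 39 / 752,
    "wbc": 8 / 752,
}

#: features with < 5% missing get previous/next-value fill during imputation
_LOW_MISSING = [
    "albumin", "bilirubin", "height", "hemoglobin", "lactate",
    "platelets", "scr", "sofa", "wbc",
]

RECORD_COLUMNS = [
    "patient_id", "sample_time_h", "site", "age", "sex", "race", "height",
    "weight", "admission_category", "scr", "clcr", "albumin", "bilirubin",
    "lactate", "platelets", "wbc", "rbc", "hemoglobin", "sofa",
    "fluid_balance", "temperature", "urine_creatinine", "dose_per_hour",
    "cumulative_dose", "hours_since_start", "previous_concentration",
    "hours_to_previous", "true_concentration", "observed_concentration",
]


@dataclass
class PatientProfile:
    """Baseline covariates of one virtual ICU patient."""

    patient_id: int
    site: str
    age: float
    sex: str
    race: str
    height: float
    weight: float
    admission_category: str
    scr: float
    clcr: float
    albumin: float
    bilirubin: float
    lactate: float
    platelets: float
    wbc: float
    rbc: float
    hemoglobin: float
    sofa: float
    fluid_balance: float
    temperature: float
    urine_creatinine: float


@dataclass(frozen=True)
class NoiseModel:
    """Dispersion of the concentration-generating process.

    iiv_cv: log-normal coefficient of variation per PK parameter (the keys
    are cl, v, vp, q).  residual_proportional_cv and residual_additive_sd
    form a combined residual-error model
    ``observed = true*(1 + eps_p) + eps_a`` floored at 0.1 mg/L.
    """

    iiv_cv: dict = field(
        default_factory=lambda: {"cl": 0.30, "v": 0.25, "vp": 0.25, "q": 0.25}
    )
    residual_proportional_cv: float = 0.15
    residual_additive_sd: float = 2.0

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(iiv_cv={"cl": 0.0, "v": 0.0, "vp": 0.0, "q": 0.0},
                   residual_proportional_cv=0.0, residual_additive_sd=0.0)


def _draw(rng, median, q1, q3, family, n):
    if family == "normal":
        sd = (q3 - q1) / _IQR_TO_SD
        return rng.normal(median, sd, size=n)
    if family == "lognormal":
        log_sd = math.log(q3 / q1) / _IQR_TO_SD
        return np.exp(rng.normal(math.log(median), log_sd, size=n))
    raise ValueError(family)


def generate_cohort(n: int, seed: int, site: str = "GUH") -> list[PatientProfile]:
    """Draw ``n`` virtual patients with site-matched covariate distributions.

    Creatinine clearance is not drawn independently: it is the Cockcroft-Gault
    estimate of each patient's age/weight/sex/creatinine, rescaled so the
    cohort median matches the site's published median, times a log-normal
    physiologic/measurement factor.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    site = site.upper()
    if site not in _SITE_TARGETS:
        raise ValueError(f"unknown site {site!r}")
    targets = _SITE_TARGETS[site]
    rng = _rng(seed, "cohort")

    cols = {}
    for name, (median, q1, q3, family) in targets.items():
        vals = _draw(rng, median, q1, q3, family, n)
        lo, hi = _CLIPS[name]
        cols[name] = np.clip(vals, lo, hi)
    cols["sofa"] = np.round(cols["sofa"])

    male = rng.random(n) < _MALE_FRACTION[site]
    sex = np.where(male, "male", "female")
    race = np.where(rng.random(n) < 0.05, "black", "white")
    adm_probs = {"GUH": (0.418, 0.479, 0.103), "UMCG": (0.267, 0.533, 0.2)}[site]
    admission = rng.choice(
        ["medical", "surgical", "trauma"], size=n, p=np.array(adm_probs) / sum(adm_probs)
    )

    # CLcr: CG-shaped coupling rescaled to the site median
    med_age, med_w = targets["age"][0], targets["weight"][0]
    cg_ref = clinical.estimate_gfr("cockcroft_gault", med_age, med_w, "male", "white", targets["scr"][0])
    cg = np.array(
        [
            clinical.estimate_gfr("cockcroft_gault", a, w, s, r, c)
            for a, w, s, r, c in zip(cols["age"], cols["weight"], sex, race, cols["scr"])
        ]
    )
    clcr = _CLCR_TARGET_MEDIAN[site] * (cg / cg_ref) * np.exp(
        rng.normal(0.0, _CLCR_EXTRA_LOG_SD, size=n)
    )
    cols["clcr"] = np.clip(clcr, *_CLIPS["clcr"])

    profiles = []
    for i in range(n):
        profiles.append(
            PatientProfile(
                patient_id=i,
                site=site,
                sex=str(sex[i]),
                race=str(race[i]),
                admission_category=str(admission[i]),
                **{k: float(cols[k][i]) for k in targets},
                clcr=float(cols["clcr"][i]),
            )
        )
    return profiles


def _individual_params(tv: TypicalValues, profile: PatientProfile, noise: NoiseModel, rng):
    base = poppk.individual_parameters(tv, profile.clcr, profile.weight)
    factors = {}
    for name in ("cl", "v", "vp", "q"):
        cv = noise.iiv_cv.get(name, 0.0)
        if cv > 0:
            sd = math.sqrt(math.log(1.0 + cv * cv))
            factors[name] = math.exp(rng.normal(0.0, sd))
        else:
            factors[name] = 1.0
    return poppk.PKParameters(
        cl=base.cl * factors["cl"],
        v=base.v * factors["v"],
        vp=base.vp * factors["vp"],
        q=base.q * factors["q"],
        km=base.km,
        vmax=base.vmax,
    )


def simulate_records(
    cohort: list[PatientProfile],
    tv: TypicalValues | None = None,
    noise: NoiseModel | None = None,
    n_days: int = 3,
    seed: int = 0,
    method: str = "steady_state",
) -> pd.DataFrame:
    """Simulate daily-sampled TDM records for a cohort.

    Each patient receives the site's loading + continuous regimen, is sampled
    every 24 h (the 6 a.m. steady-state draw), and contributes between 1 and
    ``n_days`` records (uniform).  "True" concentrations come either from the
    steady-state mass balance of the infusion rate active at the sample time
    (``method="steady_state"``, the default — samples are steady-state
    material by design) or from the full ODE simulation (``method="ode"``).
    Observations add the residual-error model, floored at 0.1 mg/L.
    """
    if tv is None:
        tv = TypicalValues()
    if noise is None:
        noise = NoiseModel()
    if method not in {"steady_state", "ode"}:
        raise ValueError(f"unknown method {method!r}")
    rng_rec = _rng(seed, "records")
    rng_iiv = _rng(seed, "iiv")
    rng_res = _rng(seed, "residual")

    rows = []
    for profile in cohort:
        params = _individual_params(tv, profile, noise, rng_iiv)
        regimen = clinical.site_dosing(profile.site, profile.clcr)
        n_records = int(rng_rec.integers(1, n_days + 1))
        sample_times = 24.0 * np.arange(1, n_records + 1)

        if method == "ode":
            try:
                series = poppk.simulate(params, regimen.events, sample_times)
            except RuntimeError as err:
                raise RuntimeError(f"patient {profile.patient_id}: {err}") from err
            true_conc = series.central_conc
        else:
            true_conc = np.array(
                [
                    poppk.steady_state_concentration(params, regimen.rate_at(t))
                    for t in sample_times
                ]
            )

        eps_p = rng_res.normal(0.0, noise.residual_proportional_cv, size=n_records) \
            if noise.residual_proportional_cv > 0 else np.zeros(n_records)
        eps_a = rng_res.normal(0.0, noise.residual_additive_sd, size=n_records) \
            if noise.residual_additive_sd > 0 else np.zeros(n_records)
        observed = true_conc * (1.0 + eps_p) + eps_a
        if noise.residual_proportional_cv > 0 or noise.residual_additive_sd > 0:
            observed = np.maximum(observed, 0.1)

        prev_conc, prev_dt = 0.0, 0.0
        for k, t in enumerate(sample_times):
            rate = regimen.rate_at(t)
            cumulative = clinical.LOADING_DOSE_MG + sum(
                e.rate * max(0.0, min(t, e.end) - e.start) for e in regimen.continuous
            )
            rows.append(
                {
                    "patient_id": profile.patient_id,
                    "sample_time_h": t,
                    "site": profile.site,
                    "age": profile.age,
                    "sex": profile.sex,
                    "race": profile.race,
                    "height": profile.height,
                    "weight": profile.weight,
                    "admission_category": profile.admission_category,
                    "scr": profile.scr,
                    "clcr": profile.clcr,
                    "albumin": profile.albumin,
                    "bilirubin": profile.bilirubin,
                    "lactate": profile.lactate,
                    "platelets": profile.platelets,
                    "wbc": profile.wbc,
                    "rbc": profile.rbc,
                    "hemoglobin": profile.hemoglobin,
                    "sofa": profile.sofa,
                    "fluid_balance": profile.fluid_balance,
                    "temperature": profile.temperature,
                    "urine_creatinine": profile.urine_creatinine,
                    "dose_per_hour": rate,
                    "cumulative_dose": cumulative,
                    "hours_since_start": t,
                    "previous_concentration": prev_conc,
                    "hours_to_previous": prev_dt,
                    "true_concentration": float(true_conc[k]),
                    "observed_concentration": float(observed[k]),
                }
            )
            prev_conc, prev_dt = float(observed[k]), 24.0
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def inject_missingness(
    records: pd.DataFrame, rates: dict | None = None, seed: int = 0
) -> pd.DataFrame:
    """Delete feature values completely at random at per-feature rates.

    Default rates mirror the per-feature missing counts observed in the
    original 752-record dataset.
    """
    if rates is None:
        rates = DEFAULT_MISSING_RATES
    unknown = set(rates) - set(records.columns)
    if unknown:
        raise KeyError(f"unknown feature(s) in missingness rates: {sorted(unknown)}")
    bad = {k: v for k, v in rates.items() if not (0 <= v <= 1)}
    if bad:
        raise ValueError(f"rates must lie in [0, 1]: {bad}")
    out = records.copy()
    rng = _rng(seed, "missingness")
    for feature, rate in rates.items():
        if rate <= 0:
            continue
        mask = rng.random(len(out)) < rate
        out.loc[mask, feature] = np.nan
    return out


def impute(records: pd.DataFrame, strategy: str = "sentinel") -> pd.DataFrame:
    """Apply the study's imputation rules; drop rows that stay incomplete.

    - features with < 5% missing: previous/next-value fill within a patient
      (records ordered by sample time);
    - missing CLcr: the weighted (CG + 2*MDRD)/3 estimate from
      age/weight/sex/race/serum creatinine;
    - urine creatinine and temperature: column mean (``strategy="mean"``) or
      the -999 sentinel (``strategy="sentinel"``, tree-model convention);
    - any record still incomplete is dropped; the count is logged and stored
      in ``result.attrs["n_dropped"]``.
    """
    if strategy not in {"sentinel", "mean"}:
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    out = records.sort_values(["patient_id", "sample_time_h"]).copy()

    low = [c for c in _LOW_MISSING if c in out.columns]
    out[low] = out.groupby("patient_id")[low].transform(lambda g: g.ffill().bfill())

    if "clcr" in out.columns:
        need = out["clcr"].isna()
        for idx in out.index[need]:
            row = out.loc[idx]
            if np.isnan(row.get("scr", np.nan)) or np.isnan(row.get("weight", np.nan)):
                continue
            cg = clinical.estimate_gfr(
                "cockcroft_gault", row["age"], row["weight"], row["sex"], row["race"], row["scr"]
            )
            mdrd = clinical.estimate_gfr(
                "mdrd", row["age"], row["weight"], row["sex"], row["race"], row["scr"]
            )
            out.loc[idx, "clcr"] = clinical.weighted_clcr(cg, mdrd)

    for col in ("urine_creatinine", "temperature"):
        if col in out.columns:
            if strategy == "mean":
                out[col] = out[col].fillna(out[col].mean())
            else:
                out[col] = out[col].fillna(-999.0)

    numeric = out.select_dtypes(include=[np.number]).columns
    complete = out[numeric].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("impute: dropped %d record(s) that remained incomplete", n_dropped)
    out = out.loc[complete].reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    return out


def split_patients(
    records: pd.DataFrame,
    test_fraction: float = 0.25,
    min_records: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Patient-level split into train and the two evaluation views.

    ``ceil(test_fraction * n_eligible)`` patients with at least
    ``min_records`` records become the test set, chosen stratified by their
    record count; everyone else (including patients with fewer records)
    trains.  The *a priori* view zeroes the previous-concentration link on
    every test record; the *a posteriori* view keeps only test records that
    have a real previous concentration (each patient's first record drops).
    """
    counts = records.groupby("patient_id").size()
    eligible = counts.index[counts >= min_records].to_numpy()
    if eligible.size == 0:
        raise ValueError(f"no patients with >= {min_records} records to draw a test set from")
    n_test = math.ceil(test_fraction * eligible.size)
    rng = _rng(seed, "split")

    # stratified by record count: shuffle within strata, then interleave
    order = []
    strata = {}
    for pid in rng.permutation(eligible):
        strata.setdefault(counts[pid], []).append(pid)
    pools = [strata[k] for k in sorted(strata)]
    while any(pools):
        for pool in pools:
            if pool:
                order.append(pool.pop())
    test_ids = set(order[:n_test])

    is_test = records["patient_id"].isin(test_ids)
    train = records.loc[~is_test].reset_index(drop=True)
    test = records.loc[is_test].sort_values(["patient_id", "sample_time_h"])

    test_a_priori = test.copy().reset_index(drop=True)
    test_a_priori["previous_concentration"] = 0.0
    test_a_priori["hours_to_previous"] = 0.0

    first = test.groupby("patient_id")["sample_time_h"].transform("min")
    test_a_posteriori = test.loc[test["sample_time_h"] > first].reset_index(drop=True)
    return train, test_a_priori, test_a_posteriori


def heteroscedastic_regression_data(n: int = 5000, seed: int = 0, sigma_range: float = 4.0) -> pd.DataFrame:
    """Concentration-like regression data with feature-driven noise scale.

    y = 60 + 80*x1 + 10*x2 + N(0, sigma(x2)^2) with sigma rising linearly
    from 5 to ``5*sigma_range`` mg/L in x2 — the benchmark for checking that
    a heteroscedastic model's predicted sigma tracks the true noise scale.
    """
    rng = _rng(seed, "hetero")
    x1 = rng.uniform(0.0, 1.0, n)
    x2 = rng.uniform(0.0, 1.0, n)
    mu = 60.0 + 80.0 * x1 + 10.0 * x2
    sigma = 5.0 * (1.0 + (sigma_range - 1.0) * x2)
    y = mu + rng.normal(0.0, sigma)
    return pd.DataFrame(
        {"x1": x1, "x2": x2, "observed_concentration": y, "true_mu": mu, "true_sigma": sigma}
    )
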