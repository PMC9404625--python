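"""Renal-function estimation, site dosing rules, therapeutic thresholds and
target-attainment classification for continuous-infusion piperacillin.

Therapeutic window.  Efficacy targets are defined on the *unbound*
concentration: at least four times the MIC (worst-case Pseudomonas
aeruginosa breakpoint of 16 mg/L by default), with an unbound toxicity
bound of 112 mg/L.  Measured concentrations are total plasma, so both
targets are divided by the unbound fraction (1 - protein binding); at the
default 30% binding this gives 91.43 and 160 mg/L total plasma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .poppk import DosingEvent
from .quantile_uq import GaussianPrediction, coverage_between

__all__ = [
    "CATEGORIES",
    "TherapeuticRange",
    "DosingRegimen",
    "estimate_gfr",
    "weighted_clcr",
    "site_dosing",
    "therapeutic_thresholds",
    "classify_concentration",
    "category_probabilities",
    "classification_report",
]

CATEGORIES = ("subtherapeutic", "therapeutic", "supratherapeutic")

#: Unbound toxicity bound for piperacillin (mg/L).
UNBOUND_TOXICITY = 112.0
#: Default protein binding fraction.
DEFAULT_BINDING = 0.30
#: Default MIC (mg/L): upper susceptibility limit of P. aeruginosa.
DEFAULT_MIC = 16.0

LOADING_DOSE_MG = 4000.0
LOADING_DURATION_H = 0.5


@dataclass(frozen=True)
class TherapeuticRange:
    """Total-plasma therapeutic window [lower, upper) in mg/L."""

    lower: float
    upper: float
    mic: float
    binding_fraction: float

    def __post_init__(self):
        if not (self.lower < self.upper):
            raise ValueError("lower threshold must be below upper threshold")


@dataclass(frozen=True)
class DosingRegimen:
    """Loading bolus plus continuous infusion events (piperacillin component)."""

    loading: DosingEvent
    continuous: tuple
    site: str

    @property
    def events(self) -> list[DosingEvent]:
        return [self.loading, *self.continuous]

    def rate_at(self, t: float) -> float:
        """Continuous-infusion rate (mg/h) active at time t, loading excluded."""
        return sum(e.rate for e in self.continuous if e.start <= t < e.end)


def estimate_gfr(
    method: str,
    age: float,
    weight: float,
    sex: str,
    race: str,
    scr: float,
) -> float:
    """Estimate renal function (mL/min or mL/min/1.73m2 depending on formula).

    Methods: ``cockcroft_gault`` (actual body weight), ``mdrd`` (4-variable,
    IDMS-traceable 175 coefficient), ``ckd_epi`` (2009 equation).

    Parameters
    ----------
    age : years; weight : kg; scr : serum creatinine mg/dL.
    sex : "male"/"female" (or "m"/"f"); race : "black" triggers the MDRD /
        CKD-EPI race coefficient, anything else does not.
    """
    if age <= 0 or weight <= 0 or scr <= 0:
        raise ValueError("age, weight and serum creatinine must be positive")
    female = str(sex).lower().startswith("f")
    black = str(race).lower() == "black"
    if method == "cockcroft_gault":
        out = (140.0 - age) * weight / (72.0 * scr)
        return out * 0.85 if female else out
    if method == "mdrd":
        out = 175.0 * scr**-1.154 * age**-0.203
        if female:
            out *= 0.742
        if black:
            out *= 1.212
        return out
    if method == "ckd_epi":
        kappa = 0.7 if female else 0.9
        alpha = -0.329 if female else -0.411
        out = (
            141.0
            * min(scr / kappa, 1.0) ** alpha
            * max(scr / kappa, 1.0) ** -1.209
            * 0.993**age
        )
        if female:
            out *= 1.018
        if black:
            out *= 1.159
        return out
    raise ValueError(f"unknown GFR method: {method!r}")


def weighted_clcr(cg: float, mdrd: float) -> float:
    """Weighted eGFR combination (CG + 2*MDRD) / 3 used to fill missing CLcr."""
    if cg < 0 or mdrd < 0:
        raise ValueError("inputs must be nonnegative")
    return (cg + 2.0 * mdrd) / 3.0


def site_dosing(site: str, clcr: float, hours_since_start: float = 0.0) -> DosingRegimen:
    """Piperacillin dosing regimen for a site given renal function.

    Both sites load 4000 mg over 0.5 h.  Continuous rates (piperacillin
    component of the piperacillin/tazobactam product):

    GUH:   CLcr < 15 -> 8 g/24 h (333.33 mg/h); 15-29 -> 12 g/24 h (500);
           >= 30 -> 16 g/24 h (666.67).
    UMCG:  CLcr < 20 -> 8 g/24 h; 20-39 -> 8 g/24 h for the first 24 h then
           12 g/24 h; >= 40 -> 12 g/24 h.

    ``hours_since_start`` only matters for the UMCG 20-39 band.
    """
    if clcr < 0:
        raise ValueError(f"clcr must be >= 0, got {clcr}")
    loading = DosingEvent(start=0.0, duration=LOADING_DURATION_H, rate=LOADING_DOSE_MG / LOADING_DURATION_H)
    horizon = 1e6  # open-ended continuous infusion
    site_u = site.upper()
    if site_u == "GUH":
        if clcr < 15:
            rate = 8000.0 / 24.0
        elif clcr < 30:
            rate = 12000.0 / 24.0
        else:
            rate = 16000.0 / 24.0
        continuous = (DosingEvent(LOADING_DURATION_H, horizon, rate),)
    elif site_u == "UMCG":
        if clcr < 20:
            continuous = (DosingEvent(LOADING_DURATION_H, horizon, 8000.0 / 24.0),)
        elif clcr < 40:
            continuous = (
                DosingEvent(LOADING_DURATION_H, 24.0 - LOADING_DURATION_H, 8000.0 / 24.0),
                DosingEvent(24.0, horizon, 12000.0 / 24.0),
            )
        else:
            continuous = (DosingEvent(LOADING_DURATION_H, horizon, 12000.0 / 24.0),)
    else:
        raise ValueError(f"unknown site: {site!r} (expected GUH or UMCG)")
    return DosingRegimen(loading=loading, continuous=continuous, site=site_u)


def therapeutic_thresholds(
    mic: float = DEFAULT_MIC,
    binding_fraction: float = DEFAULT_BINDING,
    unbound_toxicity: float = UNBOUND_TOXICITY,
) -> TherapeuticRange:
    """Total-plasma thresholds from unbound targets and protein binding.

    lower = 4*MIC / (1 - binding);  upper = unbound_toxicity / (1 - binding).
    """
    if not (0 <= binding_fraction < 1):
        raise ValueError(f"binding fraction must lie in [0, 1), got {binding_fraction}")
    unbound = 1.0 - binding_fraction
    return TherapeuticRange(
        lower=4.0 * mic / unbound,
        upper=unbound_toxicity / unbound,
        mic=mic,
        binding_fraction=binding_fraction,
    )


def classify_concentration(c: float, range_: TherapeuticRange) -> str:
    """Target-attainment category: [0, lower) sub, [lower, upper) ther, [upper, inf) supra."""
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    if c < range_.lower:
        return "subtherapeutic"
    if c < range_.upper:
        return "therapeutic"
    return "supratherapeutic"


def category_probabilities(
    dist: GaussianPrediction, range_: TherapeuticRange
) -> tuple[float, float, float]:
    """Probability mass of the predictive distribution in each category.

    The three pieces partition the line, so they sum to 1 exactly.
    """
    p_sub = coverage_between(dist, -np.inf, range_.lower)
    p_ther = coverage_between(dist, range_.lower, range_.upper)
    p_sup = coverage_between(dist, range_.upper, np.inf)
    total = p_sub + p_ther + p_sup
    return p_sub / total, p_ther / total, p_sup / total


def classification_report(true_cats, pred_cats) -> pd.DataFrame:
    """One-vs-rest precision, specificity, sensitivity and F1 per category.

    Returns a DataFrame indexed by category with a ``support`` column (class
    count in the truth).  A class absent from the truth gets NaN sensitivity
    with a warning; a class never predicted gets NaN precision.
    """
    true_cats = np.asarray(true_cats, dtype=object)
    pred_cats = np.asarray(pred_cats, dtype=object)
    if true_cats.shape != pred_cats.shape:
        raise ValueError("true and predicted category vectors differ in length")
    rows = {}
    for cat in CATEGORIES:
        t = true_cats == cat
        p = pred_cats == cat
        tp = int(np.sum(t & p))
        fp = int(np.sum(~t & p))
        fn = int(np.sum(t & ~p))
        tn = int(np.sum(~t & ~p))
        if t.sum() == 0:
            warnings.warn(f"class {cat!r} absent from the truth; sensitivity undefined")
        sens = tp / (tp + fn) if (tp + fn) else float("nan")
        prec = tp / (tp + fp) if (tp + fp) else float("nan")
        spec = tn / (tn + fp) if (tn + fp) else float("nan")
        if np.isnan(prec) or np.isnan(sens):
            f1 = float("nan")
        else:
            f1 = 2 * prec * sens / (prec + sens) if (prec + sens) > 0 else 0.0
        rows[cat] = {
            "precision": prec,
            "specificity": spec,
            "sensitivity": sens,
            "f1": f1,
            "support": int(t.sum()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
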