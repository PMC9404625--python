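"""Calibration and sharpness metrics for Gaussian predictive distributions.

A well-calibrated predictive distribution has empirical interval coverage
matching the nominal coverage at *every* level, not just one.  The
(Absolute) Distribution Coverage Error sweeps the nominal coverage p over a
grid of S+1 levels, measures the empirical coverage C(p) of the centered
intervals, and averages the (absolute) gap:

    DCE  = (2/S) * sum_{i=0..S} (C(i/S) - i/S)
    ADCE = (2/S) * sum_{i=0..S} |C(i/S) - i/S|

Positive DCE means the model is conservative (intervals wider than needed);
negative DCE means overconfident.  ADCE bounds |DCE|.  With the inclusive
endpoints i = 0 and i = S the attainable extreme is (S+1)/S, marginally above
1.  Sharpness is the mean (and spread) of the predicted standard deviations:
at equal calibration, smaller is better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quantile_uq import gaussian_quantile

__all__ = [
    "CalibrationCurve",
    "CalibrationReport",
    "picp",
    "coverage_fn",
    "calibration_errors",
    "sharpness",
    "calibration_report",
    "plot_calibration",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Empirical coverage C at each nominal level i/S, i = 0..S."""

    levels: np.ndarray
    empirical: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"level": self.levels, "empirical_coverage": self.empirical})


@dataclass(frozen=True)
class CalibrationReport:
    """ADCE/DCE, sharpness and the full calibration curve for one model."""

    adce: float
    dce: float
    sharpness_mean: float
    sharpness_std: float
    curve: CalibrationCurve


def _as_1d(*arrays):
    out = [np.atleast_1d(np.asarray(a, dtype=float)) for a in arrays]
    n = {a.shape[0] for a in out}
    if len(n) != 1:
        raise ValueError(f"length mismatch: {[a.shape[0] for a in out]}")
    return out


def picp(y, y_lower, y_upper) -> float:
    """Prediction-interval coverage probability with inclusive bounds.

    Fraction of observations with ``y_lower <= y <= y_upper``.
    """
    y, y_lower, y_upper = _as_1d(y, y_lower, y_upper)
    if y.size == 0:
        raise ValueError("picp requires at least one observation")
    return float(np.mean((y_lower <= y) & (y <= y_upper)))


def coverage_fn(y, p: float, mus, sigmas) -> float:
    """Empirical coverage C of the centered Gaussian intervals at level ``p``.

    ``p = 1`` gives infinite bounds (coverage 1) for any positive sigma; a
    degenerate ``sigma = 0`` keeps the interval zero-width at every level,
    including ``p = 1`` (the limit of the interval as sigma -> 0).
    """
    if not (0 <= p <= 1):
        raise ValueError(f"coverage p must lie in [0, 1], got {p}")
    y, mus, sigmas = _as_1d(y, mus, sigmas)
    if np.any(sigmas < 0):
        raise ValueError("sigmas must be nonnegative")
    if p == 1.0:
        # bounds are mu -+ inf*sigma: infinite when sigma > 0, mu when sigma == 0
        lo = np.where(sigmas > 0, -np.inf, mus)
        hi = np.where(sigmas > 0, np.inf, mus)
        return picp(y, lo, hi)
    with np.errstate(invalid="ignore"):
        lo = gaussian_quantile((1 - p) / 2, mus, sigmas)
        hi = gaussian_quantile((1 + p) / 2, mus, sigmas)
    return picp(y, np.atleast_1d(lo), np.atleast_1d(hi))


def calibration_errors(y, mus, sigmas, S: int = 1000):
    """DCE, ADCE and the calibration curve over the level grid i/S, i = 0..S.

    Vectorised over levels: each observation's standardised absolute residual
    ``|y - mu| / sigma`` falls inside the centered interval at level p iff it
    is <= the half-width ``sqrt(2)*erfinv(p)``, so coverage at all S+1 levels
    reduces to one sorted pass.
    """
    if S < 2:
        raise ValueError(f"S must be >= 2, got {S}")
    y, mus, sigmas = _as_1d(y, mus, sigmas)
    if np.any(sigmas < 0):
        raise ValueError("sigmas must be nonnegative")
    levels = np.arange(S + 1) / S
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(y - mus) / sigmas  # inf where sigma == 0 and y != mu
    z = np.where((sigmas == 0) & (y == mus), 0.0, z)
    # half-width of the standardised interval at level p; erfinv(1) = inf
    half_widths = np.sqrt(2.0) * _erfinv(levels)
    # coverage at level p: fraction of z <= sqrt(2)*erfinv(p) (inclusive)
    z_sorted = np.sort(z)
    empirical = np.searchsorted(z_sorted, half_widths, side="right") / z.size
    # sigma == 0 at p == 1 stays zero-width: z = inf never counted; z finite
    # (exact hits) counted — consistent with the limit convention above.
    if np.any(sigmas == 0):
        empirical[-1] = float(np.mean(np.isfinite(z)))
    gaps = empirical - levels
    dce = float(2.0 / S * np.sum(gaps))
    adce = float(2.0 / S * np.sum(np.abs(gaps)))
    return dce, adce, CalibrationCurve(levels=levels, empirical=empirical)


def _erfinv(p):
    from scipy import special

    return special.erfinv(p)


def sharpness(sigmas) -> tuple[float, float]:
    """Mean and population standard deviation of the predicted sigmas (mg/L).

    A near-zero std identifies a homoscedastic model.
    """
    sigmas = np.atleast_1d(np.asarray(sigmas, dtype=float))
    if sigmas.size == 0:
        raise ValueError("sharpness requires at least one sigma")
    if np.any(sigmas <= 0):
        raise ValueError("sigmas must be positive")
    return float(np.mean(sigmas)), float(np.std(sigmas))


def calibration_report(y, mus, sigmas, S: int = 1000) -> CalibrationReport:
    """Full calibration + sharpness summary for one model on one test set."""
    dce, adce, curve = calibration_errors(y, mus, sigmas, S=S)
    sh_mean, sh_std = sharpness(sigmas)
    return CalibrationReport(
        adce=adce, dce=dce, sharpness_mean=sh_mean, sharpness_std=sh_std, curve=curve
    )


def plot_calibration(curves: dict, path=None, ax=None):
    """Specified-vs-actual coverage plot with the identity diagonal.

    Parameters
    ----------
    curves : dict[str, CalibrationCurve]
        Label -> curve.
    path : optional
        If given, the figure is saved there.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="perfect calibration")
    for label, curve in curves.items():
        ax.plot(curve.levels, curve.empirical, lw=1.5, label=label)
    ax.set_xlabel("Specified coverage p")
    ax.set_ylabel("Actual coverage C")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower right", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
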