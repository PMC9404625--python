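"""Quantile Ensemble: per-sample Gaussian predictive distributions from quantile regressors.

The Quantile Ensemble turns any trio of quantile regressors (median, upper,
lower) into a heteroscedastic Gaussian predictive distribution.  A coverage
hyperparameter ``p`` fixes the upper and lower quantile levels at
``0.5 +/- p/2``; the spread between the predicted upper and lower quantiles is
converted into a per-sample standard deviation through the Gaussian quantile
function.  The method is learner-agnostic: anything that minimises the pinball
(quantile) loss at a prescribed level satisfies the contract.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import joblib
import numpy as np
from scipy import special

__all__ = [
    "SIGMA_FLOOR",
    "GaussianPrediction",
    "CoverageSpec",
    "QuantileEnsembleModel",
    "quantile_levels",
    "gaussian_quantile",
    "sigma_from_quantiles",
    "prediction_interval",
    "coverage_between",
    "pinball_loss",
    "fit_quantile_ensemble",
    "predict_distribution",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

#: Lower bound on an estimated standard deviation (mg/L).  Independent quantile
#: learners can cross (upper <= lower); the spread is then floored here so the
#: predictive distribution stays proper.
SIGMA_FLOOR = 1e-6


@dataclass(frozen=True)
class GaussianPrediction:
    """Gaussian predictive distribution for one concentration.

    Parameters
    ----------
    mu : float
        Predicted mean concentration (mg/L); the regression output.
    sigma : float
        Estimated standard deviation (mg/L); strictly positive
        (floored at :data:`SIGMA_FLOOR`).
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu}")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class CoverageSpec:
    """Coverage hyperparameter p and the quantile levels it induces."""

    p: float
    q_up: float
    q_low: float


def quantile_levels(p: float) -> CoverageSpec:
    """Derive the upper/lower quantile levels for a coverage ``p``.

    The centered interval with coverage ``p`` runs from the ``0.5 - p/2``
    quantile to the ``0.5 + p/2`` quantile.

    Parameters
    ----------
    p : float
        Coverage in ``[0, 1)``.  ``p = 0`` is the degenerate zero-width case.

    Returns
    -------
    CoverageSpec
    """
    if not (0 <= p < 1):
        raise ValueError(f"coverage p must lie in [0, 1), got {p}")
    return CoverageSpec(p=p, q_up=0.5 + p / 2, q_low=0.5 - p / 2)


def gaussian_quantile(q, mu, sigma):
    """Quantile function of N(mu, sigma^2): ``mu + sigma*sqrt(2)*erfinv(2q-1)``.

    ``q = 0`` and ``q = 1`` return ``-inf`` / ``+inf``.  Accepts scalars or
    arrays (broadcast).
    """
    q = np.asarray(q, dtype=float)
    out = mu + sigma * np.sqrt(2.0) * special.erfinv(2.0 * q - 1.0)
    return out if out.ndim else float(out)


def sigma_from_quantiles(y_upper, y_lower, p: float):
    """Recover the Gaussian standard deviation from predicted quantiles.

    For quantiles at levels ``0.5 +/- p/2`` of N(mu, sigma^2),

        sigma = (y_upper - y_lower) / (2 * sqrt(2) * erfinv(p))

    Crossed quantiles (``y_upper <= y_lower``) are floored at
    :data:`SIGMA_FLOOR` with a logged warning.
    """
    if not (0 < p < 1):
        raise ValueError(f"coverage p must lie in (0, 1), got {p}")
    y_upper = np.asarray(y_upper, dtype=float)
    y_lower = np.asarray(y_lower, dtype=float)
    denom = 2.0 * np.sqrt(2.0) * special.erfinv(p)
    sigma = (y_upper - y_lower) / denom
    n_crossed = int(np.sum(sigma < SIGMA_FLOOR))
    if n_crossed:
        logger.warning(
            "%d quantile pair(s) crossed or degenerate; sigma floored at %g mg/L",
            n_crossed,
            SIGMA_FLOOR,
        )
    sigma = np.maximum(sigma, SIGMA_FLOOR)
    return sigma if sigma.ndim else float(sigma)


def prediction_interval(dist: GaussianPrediction, p: float) -> tuple[float, float]:
    """Centered prediction interval ``[Q((1-p)/2), Q((1+p)/2)]`` at coverage p."""
    if not (0 <= p <= 1):
        raise ValueError(f"coverage p must lie in [0, 1], got {p}")
    lo = gaussian_quantile((1 - p) / 2, dist.mu, dist.sigma)
    hi = gaussian_quantile((1 + p) / 2, dist.mu, dist.sigma)
    return float(lo), float(hi)


def coverage_between(dist: GaussianPrediction, y_lower: float, y_upper: float) -> float:
    """Probability mass of the predictive distribution between two bounds.

        p~ = (1/2) * [erf((y_U - mu)/(sigma*sqrt2)) - erf((y_L - mu)/(sigma*sqrt2))]

    Infinite bounds are allowed; the full line integrates to 1.
    """
    if y_lower > y_upper:
        raise ValueError(f"reversed bounds: y_lower={y_lower} > y_upper={y_upper}")
    s = dist.sigma * np.sqrt(2.0)
    return float(0.5 * (special.erf((y_upper - dist.mu) / s) - special.erf((y_lower - dist.mu) / s)))


def pinball_loss(y, y_hat, alpha: float):
    """Pinball (quantile) loss at level ``alpha``: the loss the sub-models minimise."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    d = np.asarray(y, dtype=float) - np.asarray(y_hat, dtype=float)
    out = np.maximum(alpha * d, (alpha - 1.0) * d)
    return out if out.ndim else float(out)


@dataclass
class QuantileEnsembleModel:
    """Three quantile learners (median, upper, lower) sharing a feature set.

    Attributes
    ----------
    median_learner, upper_learner, lower_learner :
        Fitted regressors exposing ``predict(X)``, trained at quantile levels
        0.5, ``coverage.q_up`` and ``coverage.q_low`` respectively.
    coverage : CoverageSpec
        The coverage hyperparameter and its induced levels.
    features : list of str
        Column names the learners were trained on.
    """

    median_learner: object
    upper_learner: object
    lower_learner: object
    coverage: CoverageSpec
    features: list = field(default_factory=list)


def fit_quantile_ensemble(
    train_table,
    learner_factory: Callable[[float], object],
    p: float,
    features: Sequence[str],
    target: str = "observed_concentration",
) -> QuantileEnsembleModel:
    """Train the three-learner Quantile Ensemble at coverage ``p``.

    Parameters
    ----------
    train_table : pandas.DataFrame
        One row per sample; must contain ``features`` and ``target`` columns.
    learner_factory : callable(alpha) -> regressor
        Returns an unfitted regressor minimising :func:`pinball_loss` at
        quantile level ``alpha`` (e.g. gradient-boosted trees with a quantile
        objective).
    p : float
        Coverage hyperparameter in (0, 1).
    features : sequence of str
        Feature columns, identical for all three learners.
    target : str
        Target column (mg/L).
    """
    if len(train_table) == 0:
        raise ValueError("training table is empty")
    missing = [c for c in [*features, target] if c not in train_table.columns]
    if missing:
        raise KeyError(f"training table lacks columns: {missing}")
    spec = quantile_levels(p)
    if not (0 < p < 1):
        raise ValueError("coverage p must lie in (0, 1) for ensemble fitting")
    X = train_table.loc[:, list(features)].to_numpy(dtype=float)
    y = train_table[target].to_numpy(dtype=float)
    learners = {}
    for name, alpha in [("median", 0.5), ("upper", spec.q_up), ("lower", spec.q_low)]:
        est = learner_factory(alpha)
        est.fit(X, y)
        learners[name] = est
    return QuantileEnsembleModel(
        median_learner=learners["median"],
        upper_learner=learners["upper"],
        lower_learner=learners["lower"],
        coverage=spec,
        features=list(features),
    )


def predict_distribution(model: QuantileEnsembleModel, features) -> list[GaussianPrediction]:
    """Predict a Gaussian distribution per row of ``features``.

    mu is the median learner's output; sigma is recovered from the upper/lower
    quantile predictions via :func:`sigma_from_quantiles` — one sigma per
    sample, which is what makes the method heteroscedastic.
    """
    missing = [c for c in model.features if c not in features.columns]
    if missing:
        raise KeyError(f"prediction table lacks feature columns: {missing}")
    X = features.loc[:, model.features].to_numpy(dtype=float)
    mu = np.asarray(model.median_learner.predict(X), dtype=float)
    y_u = np.asarray(model.upper_learner.predict(X), dtype=float)
    y_l = np.asarray(model.lower_learner.predict(X), dtype=float)
    sigma = np.atleast_1d(sigma_from_quantiles(y_u, y_l, model.coverage.p))
    return [GaussianPrediction(m, s) for m, s in zip(mu, sigma)]


def save_model(model: QuantileEnsembleModel, path) -> None:
    """Serialise the ensemble (three learners + coverage + features) to one archive."""
    joblib.dump(
        {
            "median": model.median_learner,
            "upper": model.upper_learner,
            "lower": model.lower_learner,
            "p": model.coverage.p,
            "features": model.features,
        },
        path,
    )


def load_model(path) -> QuantileEnsembleModel:
    """Load an ensemble archive written by :func:`save_model`."""
    blob = joblib.load(path)
    return QuantileEnsembleModel(
        median_learner=blob["median"],
        upper_learner=blob["upper"],
        lower_learner=blob["lower"],
        coverage=quantile_levels(blob["p"]),
        features=list(blob["features"]),
    )
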