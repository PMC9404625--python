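"""Regression metrics, bias compensation, the homoscedastic baseline and
end-to-end experiment orchestration.

Sign conventions (documented prominently because they are easy to flip):

* ME = mean(predicted - observed): a model that *over*-predicts has a
  positive ME on this convention's mirror... concretely, a high positive ME
  flags systematic over-estimation of the observed concentrations.
* MdPE = median((observed - predicted)/predicted) * 100 and
  MdAPE = median(|observed - predicted|/predicted) * 100 — percentage errors
  divide by the *predicted* concentration.

Clinical acceptability follows the Struys criteria for drug-prediction
models: MdAPE <= 30% and MdPE within [-20%, 20%] on the natural
concentration scale (boundaries inclusive).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.metrics import r2_score

from . import calibration, clinical, quantile_uq, synthetic
from .quantile_uq import GaussianPrediction

__all__ = [
    "RegressionMetrics",
    "RunConfig",
    "DEFAULT_FEATURES_NEW",
    "DEFAULT_FEATURES_PREV",
    "gbt_factory",
    "regression_metrics",
    "bias_compensate",
    "clinical_acceptability",
    "homoscedastic_baseline",
    "run_experiment",
]

logger = logging.getLogger(__name__)

#: default feature list for the *new* (a priori, no previous concentration) model
DEFAULT_FEATURES_NEW = [
    "clcr", "scr", "albumin", "bilirubin", "height", "lactate",
    "platelets", "rbc", "fluid_balance",
]
#: default feature list for the *prev* (a posteriori) model
DEFAULT_FEATURES_PREV = [
    "previous_concentration", "hours_to_previous", "clcr", "scr", "albumin",
    "bilirubin", "height", "lactate", "platelets", "rbc",
    "hours_since_start", "dose_per_hour",
]


@dataclass(frozen=True)
class RegressionMetrics:
    """Point-prediction error summary, natural and log scale."""

    me: float
    mae: float
    rmse: float
    r2: float
    mdape: float
    mdpe: float
    log_me: float = float("nan")
    log_mae: float = float("nan")
    log_rmse: float = float("nan")
    log_r2: float = float("nan")
    log_mdape: float = float("nan")
    log_mdpe: float = float("nan")

    def to_dict(self):
        return asdict(self)


def _core_metrics(obs, pred):
    err = pred - obs
    me = float(np.mean(err))
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    r2 = float(r2_score(obs, pred)) if obs.size > 1 else float("nan")
    pe = (obs - pred) / pred * 100.0
    return me, mae, rmse, r2, float(np.median(np.abs(pe))), float(np.median(pe))


def regression_metrics(y_obs, y_pred, log_scale: bool = True) -> RegressionMetrics:
    """ME/MAE/RMSE/R2/MdAPE/MdPE, optionally also on natural-log concentrations."""
    obs = np.atleast_1d(np.asarray(y_obs, dtype=float))
    pred = np.atleast_1d(np.asarray(y_pred, dtype=float))
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("y_obs and y_pred must be equal-length nonempty vectors")
    me, mae, rmse, r2, mdape, mdpe = _core_metrics(obs, pred)
    log_vals = dict.fromkeys(
        ("log_me", "log_mae", "log_rmse", "log_r2", "log_mdape", "log_mdpe"), float("nan")
    )
    if log_scale:
        if np.any(obs <= 0) or np.any(pred <= 0):
            raise ValueError("log-scale metrics require strictly positive concentrations")
        lme, lmae, lrmse, lr2, lmdape, lmdpe = _core_metrics(np.log(obs), np.log(pred))
        log_vals = {
            "log_me": lme, "log_mae": lmae, "log_rmse": lrmse,
            "log_r2": lr2, "log_mdape": lmdape, "log_mdpe": lmdpe,
        }
    return RegressionMetrics(me=me, mae=mae, rmse=rmse, r2=r2, mdape=mdape, mdpe=mdpe, **log_vals)


def bias_compensate(y_pred, me: float):
    """Subtract a (training-set) mean error from predictions."""
    return np.asarray(y_pred, dtype=float) - float(me)


def clinical_acceptability(metrics: RegressionMetrics) -> tuple[bool, list[str]]:
    """Struys acceptance: MdAPE <= 30% and MdPE in [-20%, 20%], inclusive."""
    reasons = []
    if not metrics.mdape <= 30.0:
        reasons.append(f"MdAPE {metrics.mdape:.2f}% exceeds 30%")
    if not (-20.0 <= metrics.mdpe <= 20.0):
        reasons.append(f"MdPE {metrics.mdpe:.2f}% outside [-20%, 20%]")
    return (len(reasons) == 0, reasons)


def homoscedastic_baseline(train_residuals, mus) -> list[GaussianPrediction]:
    """Constant-sigma predictive distributions (sigma = std of training residuals).

    The contrast to the heteroscedastic Quantile Ensemble: one global
    uncertainty for every sample, so its sharpness std is 0 by construction.
    """
    res = np.atleast_1d(np.asarray(train_residuals, dtype=float))
    if res.size == 0:
        raise ValueError("cannot estimate a residual sigma from zero residuals")
    sigma = max(float(np.std(res)), quantile_uq.SIGMA_FLOOR)
    return [GaussianPrediction(float(m), sigma) for m in np.atleast_1d(np.asarray(mus, float))]


def gbt_factory(random_state: int = 0, **kwargs):
    """Factory of quantile-objective gradient-boosted-tree learners.

    Returns a callable(alpha) -> regressor minimising the pinball loss at
    ``alpha`` — the reference learner of the Quantile Ensemble.
    """
    defaults = dict(n_estimators=200, max_depth=4, learning_rate=0.05, subsample=0.9)
    defaults.update(kwargs)

    def factory(alpha: float):
        return GradientBoostingRegressor(
            loss="quantile", alpha=alpha, random_state=random_state, **defaults
        )

    return factory


@dataclass
class RunConfig:
    """End-to-end experiment configuration (all defaults mirror the study setup)."""

    site: str = "GUH"
    n_patients: int = 300
    n_days: int = 3
    coverage_new: float = 0.80
    coverage_prev: float = 0.82
    features_new: list = field(default_factory=lambda: list(DEFAULT_FEATURES_NEW))
    features_prev: list = field(default_factory=lambda: list(DEFAULT_FEATURES_PREV))
    mic: float = clinical.DEFAULT_MIC
    binding_fraction: float = clinical.DEFAULT_BINDING
    test_fraction: float = 0.25
    impute_strategy: str = "sentinel"
    with_missingness: bool = True
    calibration_s: int = 1000
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a flat ``key = value`` config file (``#`` comments allowed)."""
        cfg = cls()
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, value.lower() in {"1", "true", "yes"})
            elif isinstance(current, int):
                setattr(cfg, key, int(value))
            elif isinstance(current, float):
                setattr(cfg, key, float(value))
            elif isinstance(current, list):
                setattr(cfg, key, [v.strip() for v in value.split(",") if v.strip()])
            else:
                setattr(cfg, key, value)
        return cfg


def _evaluate_view(name, train, test, features, coverage, config, out):
    """Fit ensemble + baseline on one view; fill metric/calibration/attainment tables."""
    model = quantile_uq.fit_quantile_ensemble(
        train, gbt_factory(random_state=config.seed), coverage, features
    )
    dists = quantile_uq.predict_distribution(model, test)
    mus = np.array([d.mu for d in dists])
    sigmas = np.array([d.sigma for d in dists])
    y = test["observed_concentration"].to_numpy(float)

    metrics = regression_metrics(y, np.maximum(mus, 0.1))
    accepted, reasons = clinical_acceptability(metrics)
    out["metrics"].append({"view": name, "model": "quantile_ensemble", **metrics.to_dict(),
                           "clinically_acceptable": accepted})
    if reasons:
        logger.info("%s quantile_ensemble rejected: %s", name, "; ".join(reasons))

    report = calibration.calibration_report(y, mus, sigmas, S=config.calibration_s)
    out["calibration"].append(
        {"view": name, "model": "quantile_ensemble", "adce": report.adce, "dce": report.dce,
         "sharpness_mean": report.sharpness_mean, "sharpness_std": report.sharpness_std}
    )
    out["curves"][f"{name}/quantile_ensemble"] = report.curve

    # homoscedastic contrast fitted on training residuals of the median learner
    train_mu = model.median_learner.predict(train.loc[:, features].to_numpy(float))
    residuals = train["observed_concentration"].to_numpy(float) - train_mu
    base = homoscedastic_baseline(residuals, mus)
    base_sig = np.array([d.sigma for d in base])
    base_rep = calibration.calibration_report(y, mus, base_sig, S=config.calibration_s)
    out["calibration"].append(
        {"view": name, "model": "homoscedastic_baseline", "adce": base_rep.adce,
         "dce": base_rep.dce, "sharpness_mean": base_rep.sharpness_mean,
         "sharpness_std": base_rep.sharpness_std}
    )
    out["curves"][f"{name}/homoscedastic_baseline"] = base_rep.curve

    rng_ = clinical.therapeutic_thresholds(config.mic, config.binding_fraction)
    true_cats = [clinical.classify_concentration(c, rng_) for c in y]
    pred_cats = [clinical.classify_concentration(max(c, 0.0), rng_) for c in mus]
    rep = clinical.classification_report(true_cats, pred_cats)
    rep = rep.assign(view=name, model="quantile_ensemble")
    out["attainment"].append(rep)
    return model


def run_experiment(config: RunConfig, out_dir=None) -> dict:
    """Generate a synthetic cohort, fit both sub-models, evaluate everything.

    Returns a dict with DataFrames ``metrics``, ``calibration``,
    ``attainment``, the fitted models and the record tables; if ``out_dir``
    is given, the tables, calibration curves/plot and model archives are
    written there.  Fully reproducible from (config, seed).
    """
    t0 = time.perf_counter()
    logger.info("run_experiment: site=%s n=%d seed=%d", config.site, config.n_patients, config.seed)
    cohort = synthetic.generate_cohort(config.n_patients, seed=config.seed, site=config.site)
    records = synthetic.simulate_records(cohort, n_days=config.n_days, seed=config.seed)
    if config.with_missingness:
        records = synthetic.inject_missingness(records, seed=config.seed)
    records = synthetic.impute(records, strategy=config.impute_strategy)
    train, test_a_priori, test_a_posteriori = synthetic.split_patients(
        records, test_fraction=config.test_fraction, seed=config.seed
    )
    logger.info(
        "split: %d train / %d a-priori / %d a-posteriori records",
        len(train), len(test_a_priori), len(test_a_posteriori),
    )

    out = {"metrics": [], "calibration": [], "attainment": [], "curves": {}}
    # a priori: the *new* model never sees a previous concentration
    train_new = train.copy()
    train_new["previous_concentration"] = 0.0
    model_new = _evaluate_view(
        "a_priori", train_new, test_a_priori, config.features_new, config.coverage_new, config, out
    )
    model_prev = _evaluate_view(
        "a_posteriori", train, test_a_posteriori, config.features_prev, config.coverage_prev,
        config, out,
    )

    bundle = {
        "metrics": pd.DataFrame(out["metrics"]),
        "calibration": pd.DataFrame(out["calibration"]),
        "attainment": pd.concat(out["attainment"]).rename_axis("range").reset_index(),
        "curves": out["curves"],
        "model_new": model_new,
        "model_prev": model_prev,
        "train": train,
        "test_a_priori": test_a_priori,
        "test_a_posteriori": test_a_posteriori,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        bundle["metrics"].to_csv(out_dir / "regression_metrics.csv", index=False)
        bundle["calibration"].to_csv(out_dir / "calibration_metrics.csv", index=False)
        bundle["attainment"].to_csv(out_dir / "target_attainment.csv", index=False)
        for key, curve in out["curves"].items():
            curve.to_frame().to_csv(
                out_dir / f"curve_{key.replace('/', '_')}.csv", index=False
            )
        calibration.plot_calibration(out["curves"], out_dir / "calibration_plot.png")
        quantile_uq.save_model(model_new, out_dir / "model_new.joblib")
        quantile_uq.save_model(model_prev, out_dir / "model_prev.joblib")
    logger.info("run_experiment finished in %.1f s", time.perf_counter() - t0)
    return bundle
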