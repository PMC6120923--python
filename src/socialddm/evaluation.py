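"""Out-of-sample prediction and model comparison.

Fitted DDMs (biased or unbiased) are turned into per-game selfish-choice
probabilities by forward simulation; logistic baselines regress the
selfish-choice indicator on DicDiff and ReceDiff (optionally RT).  Model
quality on held-out games is summarized by the summed absolute error
between predicted and empirical per-game probabilities and by Cramer's
lambda, the mean predicted P(selfish) on selfish-chosen trials minus
that on pro-social-chosen trials (1 = perfect, 0 = chance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ddm import DDMParams, FitResult, attach_game_columns, drift_rates
from .simulate import simulate_wiener

__all__ = [
    "LogitFit",
    "PredictionResult",
    "predict_choice_probs",
    "fit_logit",
    "predict_logit_probs",
    "absolute_error_sum",
    "cramers_lambda",
    "split_half_prediction",
]


@dataclass
class LogitFit:
    coefficients: np.ndarray  # intercept, DicDiff, ReceDiff[, RT]
    include_rt: bool
    loglik: float
    n_obs: int
    separated: bool = False

    def __post_init__(self) -> None:
        expected = 4 if self.include_rt else 3
        if len(self.coefficients) != expected:
            raise ValueError("coefficient count does not match include_rt")


@dataclass
class PredictionResult:
    predicted: pd.Series     # per-game P(selfish)
    empirical: pd.Series     # per-game empirical fraction
    abs_error: pd.Series
    summed_ae: float
    lam: float | None = None


def predict_choice_probs(fit: FitResult | DDMParams, games: pd.DataFrame,
                         n_sims: int = 5000, seed: int = 0, *,
                         dt: float = 0.002, bridge: bool = True) -> pd.Series:
    """Monte-Carlo per-game P(selfish) under fitted DDM parameters.

    Simulates ``n_sims`` diffusion trials per game (all games in one
    vectorized batch); reproducible for a fixed seed.
    """
    params = fit.params if isinstance(fit, FitResult) else fit
    v = drift_rates(params, games)
    rng = np.random.default_rng(seed)
    n_g = len(games)
    res = simulate_wiener(n_g * n_sims, np.repeat(v, n_sims), params.a,
                          params.z, sigma=params.sigma, dt=dt, szr=params.szr,
                          rng=rng, bridge=bridge)
    choice = res.choice_selfish.copy()
    unresolved = ~res.resolved
    if unresolved.any():
        choice[unresolved] = res.evidence[unresolved] > params.a / 2
    p = choice.reshape(n_g, n_sims).mean(axis=1)
    return pd.Series(p, index=pd.Index(games["game_id"].to_numpy(), name="game_id"),
                     name="p_selfish")


def fit_logit(trials: pd.DataFrame, games: pd.DataFrame | None = None,
              include_rt: bool = False) -> LogitFit:
    """Logistic regression of the selfish indicator on DicDiff, ReceDiff
    (and RT when ``include_rt``); perfect separation is flagged and the
    coefficients are left at the optimizer's bounded solution."""
    df = trials if "dic_diff" in trials.columns else attach_game_columns(trials, games)
    y = (df["choice"] == "selfish").astype(float).to_numpy()
    if y.min() == y.max():
        warnings.warn("one-class data: logistic fit is separated")
    cols = [np.ones(len(df)), df["dic_diff"].to_numpy(float),
            df["rece_diff"].to_numpy(float)]
    if include_rt:
        cols.append(df["rt"].to_numpy(float))
    X = np.column_stack(cols)
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            coefs = res.params
            llf = float(res.llf)
            if not res.mle_retvals.get("converged", True) or np.abs(coefs).max() > 20:
                separated = True
        except Exception:
            # perfect separation: fall back to a ridge-stabilized fit
            separated = True
            res = sm.Logit(y, X).fit_regularized(alpha=1e-4, disp=0)
            coefs = np.asarray(res.params)
            llf = float(sm.Logit(y, X).loglike(coefs))
    if y.min() == y.max():
        separated = True
    return LogitFit(coefficients=np.asarray(coefs), include_rt=include_rt,
                    loglik=llf, n_obs=len(df), separated=separated)


def predict_logit_probs(fit: LogitFit, frame: pd.DataFrame) -> np.ndarray:
    """Per-row predicted P(selfish); ``frame`` needs dic_diff/rece_diff
    (and rt when the fit includes it — prediction conditional on RT)."""
    cols = [np.ones(len(frame)), frame["dic_diff"].to_numpy(float),
            frame["rece_diff"].to_numpy(float)]
    if fit.include_rt:
        cols.append(frame["rt"].to_numpy(float))
    x = np.column_stack(cols) @ fit.coefficients
    return 1.0 / (1.0 + np.exp(-x))


def absolute_error_sum(predicted: pd.Series, trials: pd.DataFrame,
                       games: pd.DataFrame | None = None) -> tuple[pd.Series, float]:
    """Per-game absolute error |predicted - empirical| and its sum.

    The empirical probability is the fraction of selfish choices across
    all (held-out) trials of the game, equal trial weight.
    """
    df = trials
    emp = (df.assign(selfish=(df["choice"] == "selfish").astype(float))
             .groupby("game_id")["selfish"].mean())
    missing = [g for g in predicted.index if g not in emp.index]
    if missing:
        raise ValueError(f"games without held-out trials: {missing}")
    emp = emp.reindex(predicted.index)
    ae = (predicted - emp).abs()
    return ae, float(ae.sum())


def cramers_lambda(predicted_per_trial, choices) -> float:
    """Cramer's lambda: mean predicted P(selfish) over trials where the
    selfish option was chosen minus the mean over pro-social trials."""
    p = np.asarray(predicted_per_trial, dtype=float)
    sel = np.asarray(choices) == "selfish"
    if sel.all() or not sel.any():
        raise ValueError("need at least one selfish and one pro-social choice")
    return float(p[sel].mean() - p[~sel].mean())


def split_half_prediction(fit_result: FitResult, held_out_trials: pd.DataFrame,
                          held_out_games: pd.DataFrame, *, n_sims: int = 5000,
                          seed: int = 0, dt: float = 0.002) -> PredictionResult:
    """Evaluate a DDM fit (estimated on one half of the games) on the
    other half: per-game AE plus Cramer's lambda over pooled trials."""
    pred = predict_choice_probs(fit_result, held_out_games, n_sims=n_sims,
                                seed=seed, dt=dt)
    ae, total = absolute_error_sum(pred, held_out_trials)
    per_trial = pred.reindex(held_out_trials["game_id"]).to_numpy()
    lam = cramers_lambda(per_trial, held_out_trials["choice"].to_numpy())
    emp = (held_out_trials.assign(selfish=(held_out_trials["choice"] == "selfish")
                                  .astype(float))
           .groupby("game_id")["selfish"].mean().reindex(pred.index))
    return PredictionResult(predicted=pred, empirical=emp, abs_error=ae,
                            summed_ae=total, lam=lam)
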