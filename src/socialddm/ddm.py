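"""Drift-diffusion model parameters, likelihoods and fits.

Two fitting routes are provided, mirroring how biased DDMs are fit in
practice:

* :func:`fit_individual` — per-subject maximum likelihood on the Wiener
  first-passage density, with the drift rate a linear function of the
  game's payoff differences, ``v = d_c + d_d * DicDiff + d_r * ReceDiff``.
  The biased variant frees the relative starting point ``z`` (6
  parameters); the unbiased variant fixes ``z = 0.5`` (5 parameters).
* :func:`fit_group_ks` — group-level fit of pooled trials that estimates
  one drift rate per (DicDiff, ReceDiff) design cell plus common
  ``(z, a, t0, szr)`` by minimizing the count-weighted sum of
  Kolmogorov-Smirnov distances between empirical and model signed-RT
  distributions (pro-social responses mapped to negative times).

The diffusion coefficient is fixed at 1 evidence unit per sqrt(second)
throughout; under this convention fitted thresholds land around 3-4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, minimize

from .wfpt import _f1, _gauss_legendre_nodes, analytic_choice_prob

__all__ = [
    "DDMParams",
    "FitResult",
    "drift_rate",
    "drift_rates",
    "attach_game_columns",
    "loglik_trials",
    "fit_individual",
    "fit_group_ks",
    "bic",
    "jackknife_se",
]

LIK_FLOOR = 1e-10
DRIFT_BOUNDS = (-5.0, 5.0)


@dataclass
class DDMParams:
    """Parameters of a (possibly biased) Wiener diffusion process.

    The drift specification is either coefficient form (``drift_coefs =
    (d_c, d_d, d_r)``) or cell form (``cell_drifts`` keyed by
    ``(DicDiff, ReceDiff)``).
    """

    a: float
    z: float = 0.5
    t0: float = 0.0
    szr: float = 0.0
    sigma: float = 1.0
    drift_coefs: tuple[float, float, float] | None = None
    cell_drifts: dict[tuple[int, int], float] | None = None

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("threshold separation a must be positive")
        if not 0 < self.z < 1:
            raise ValueError("relative starting point z must be in (0, 1)")
        if self.t0 < 0:
            raise ValueError("non-decision time must be non-negative")
        if self.szr < 0 or (self.szr > 0 and self.szr >= 2 * min(self.z, 1 - self.z)):
            raise ValueError("szr must satisfy 0 <= szr < 2*min(z, 1-z)")
        if self.drift_coefs is None and self.cell_drifts is None:
            raise ValueError("provide drift_coefs or cell_drifts")


@dataclass
class FitResult:
    params: DDMParams
    objective: float
    n_obs: int
    k_params: int
    converged: bool
    n_starts_used: int = 1
    bic: float | None = None
    extra: dict = field(default_factory=dict)


def drift_rate(params: DDMParams, game) -> float:
    """Drift rate (evidence/s) for one game; positive = toward selfish."""
    if isinstance(game, tuple):
        dic, rece = game
    else:
        try:
            dic, rece = game.dic_diff, game.rece_diff
        except AttributeError:
            dic, rece = game["dic_diff"], game["rece_diff"]
    if params.drift_coefs is not None:
        dc, dd, dr = params.drift_coefs
        return float(dc + dd * dic + dr * rece)
    key = (int(dic), int(rece))
    if key not in params.cell_drifts:
        raise KeyError(f"no drift estimated for design cell {key}")
    return float(params.cell_drifts[key])


def drift_rates(params: DDMParams, frame: pd.DataFrame) -> np.ndarray:
    """Vectorized :func:`drift_rate` over a frame with dic_diff/rece_diff."""
    dic = frame["dic_diff"].to_numpy(float)
    rece = frame["rece_diff"].to_numpy(float)
    if params.drift_coefs is not None:
        dc, dd, dr = params.drift_coefs
        return dc + dd * dic + dr * rece
    out = np.empty(len(frame))
    for i, key in enumerate(zip(dic.astype(int), rece.astype(int))):
        if key not in params.cell_drifts:
            raise KeyError(f"no drift estimated for design cell {key}")
        out[i] = params.cell_drifts[key]
    return out


def attach_game_columns(trials: pd.DataFrame, games: pd.DataFrame) -> pd.DataFrame:
    """Merge per-trial rows with their game's payoff-difference columns."""
    cols = ["game_id", "condition", "dic_diff", "rece_diff"]
    merged = trials.merge(games[cols], on=["game_id", "condition"],
                          how="left", validate="many_to_one")
    if merged["dic_diff"].isna().any():
        missing = merged.loc[merged["dic_diff"].isna(),
                             ["game_id", "condition"]].drop_duplicates()
        raise KeyError(f"trials reference unknown games:\n{missing}")
    return merged


def _density_vectors(tau, v, a, z, selfish, szr=0.0, sigma=1.0, eps=1e-7):
    """Defective FPT density for a vector of trials with per-trial drift
    ``v`` and response indicator ``selfish``; decision times ``tau``."""
    v = np.where(selfish, -v, v) / sigma
    a = a / sigma
    zz = np.where(selfish, 1.0 - z, z)
    if szr == 0.0:
        nodes = np.array([0.0])
        wts = np.array([1.0])
    else:
        x, w = np.polynomial.legendre.leggauss(11)
        nodes, wts = 0.5 * szr * x, w / 2.0
    tau_pos = np.maximum(tau, 1e-12)
    dens = np.zeros_like(tau_pos)
    for off, wt in zip(nodes, wts):
        zo = np.clip(zz + np.where(selfish, -off, off), 1e-6, 1 - 1e-6)
        dens = dens + wt * np.exp(-v * a * zo - v**2 * tau_pos / 2.0) \
            * _f1(tau_pos / a**2, zo, eps) / a**2
    return np.where(tau > 0, dens, 0.0)


def loglik_trials(params: DDMParams, trials: pd.DataFrame,
                  games: pd.DataFrame | None = None,
                  floor: float = LIK_FLOOR) -> float:
    """Summed log Wiener first-passage density over trials.

    Densities are floored at ``floor`` so outlier RTs (e.g. faster than
    ``t0``) keep the objective finite.
    """
    df = trials if "dic_diff" in trials.columns else attach_game_columns(trials, games)
    v = drift_rates(params, df)
    tau = df["rt"].to_numpy(float) - params.t0
    selfish = df["choice"].to_numpy() == "selfish"
    dens = _density_vectors(tau, v, params.a, params.z, selfish,
                            szr=params.szr, sigma=params.sigma)
    return float(np.sum(np.log(np.maximum(dens, floor))))


def bic(loglik: float, n: int, k: int) -> float:
    """Bayesian information criterion, ``ln(n) * k - 2 * loglik``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(np.log(n) * k - 2.0 * loglik)


# ---------------------------------------------------------------------------
# individual-level maximum likelihood


def fit_individual(trials: pd.DataFrame, games: pd.DataFrame | None = None,
                   biased: bool = True, *, n_starts: int = 5, seed: int = 0,
                   maxfev: int = 2000) -> FitResult:
    """Fit the (un)biased DDM to one subject's trials by MLE.

    Free parameters: ``z`` (biased only), ``a``, ``t0`` and the three
    drift coefficients.  Derivative-free Nelder-Mead from ``n_starts``
    seeded starting points within documented bounds.
    """
    df = trials if "dic_diff" in trials.columns else attach_game_columns(trials, games)
    if len(df) < 50:
        warnings.warn(f"only {len(df)} trials; DDM fits below 50 trials are fragile")
    rt = df["rt"].to_numpy(float)
    selfish = df["choice"].to_numpy() == "selfish"
    dic = df["dic_diff"].to_numpy(float)
    rece = df["rece_diff"].to_numpy(float)
    min_rt = float(rt.min())

    t0_hi = max(min_rt - 0.01, 0.02)
    t0_lo = min(0.05, 0.5 * t0_hi)
    lo = [0.02, 0.3, t0_lo, DRIFT_BOUNDS[0], DRIFT_BOUNDS[0], DRIFT_BOUNDS[0]]
    hi = [0.98, 8.0, t0_hi, DRIFT_BOUNDS[1], DRIFT_BOUNDS[1], DRIFT_BOUNDS[1]]
    if not biased:
        lo, hi = lo[1:], hi[1:]

    def unpack(theta):
        if biased:
            z, a, t0, dc, dd, dr = theta
        else:
            a, t0, dc, dd, dr = theta
            z = 0.5
        return z, a, t0, dc, dd, dr

    def nll(theta):
        z, a, t0, dc, dd, dr = unpack(theta)
        v = dc + dd * dic + dr * rece
        dens = _density_vectors(rt - t0, v, a, z, selfish)
        return -float(np.sum(np.log(np.maximum(dens, LIK_FLOOR))))

    rng = np.random.default_rng(seed)
    heuristic = [0.5, 3.0, min(0.7 * min_rt, t0_hi), 0.0, 0.1, -0.02]
    if not biased:
        heuristic = heuristic[1:]
    starts = [np.array(heuristic)]
    lo_a, hi_a = np.array(lo), np.array(hi)
    for _ in range(n_starts - 1):
        u = rng.random(len(lo))
        starts.append(lo_a + (0.1 + 0.8 * u) * (hi_a - lo_a))

    best = None
    for x0 in starts:
        res = minimize(nll, x0, method="Nelder-Mead",
                       bounds=Bounds(lo_a, hi_a),
                       options={"maxfev": maxfev, "fatol": 1e-2, "xatol": 1e-3})
        if best is None or res.fun < best.fun:
            best = res

    z, a, t0, dc, dd, dr = unpack(best.x)
    params = DDMParams(a=a, z=z, t0=t0, drift_coefs=(dc, dd, dr))
    k = 6 if biased else 5
    ll = -best.fun
    return FitResult(params=params, objective=ll, n_obs=len(df), k_params=k,
                     converged=bool(best.success), n_starts_used=len(starts),
                     bic=bic(ll, len(df), k))


# ---------------------------------------------------------------------------
# group-level Kolmogorov-Smirnov fit with per-cell drifts


def _cell_arrays(df: pd.DataFrame):
    cells, signed = [], []
    for key, sub in df.groupby(["dic_diff", "rece_diff"], sort=True):
        s = np.where(sub["choice"].to_numpy() == "selfish", 1.0, -1.0) \
            * sub["rt"].to_numpy(float)
        cells.append((int(key[0]), int(key[1])))
        signed.append(np.sort(s))
    return cells, signed


class _GroupObjective:
    """Count-weighted summed KS distance, with per-cell drifts profiled
    out by a vectorized grid-refinement search at every outer step.

    The drift-independent part of the Wiener density (the standardized
    first-passage series over the start-variability quadrature nodes) is
    tabulated once per outer parameter vector and reused across all
    drift candidates.
    """

    def __init__(self, cells, signed, grid_dt, t_max, drift_bounds):
        self.cells = cells
        self.signed = signed
        self.counts = np.array([len(s) for s in signed], dtype=float)
        self.grid_dt = grid_dt
        self.t_max = t_max
        self.drift_bounds = drift_bounds

    def _prepare(self, z, a, t0, szr):
        tau_grid = np.arange(self.grid_dt, max(self.t_max - t0, 5 * self.grid_dt),
                             self.grid_dt)
        if szr > 0:
            nodes, wts = _gauss_legendre_nodes(z, szr)
        else:
            nodes, wts = np.array([z]), np.array([1.0])
        w = tau_grid / a**2
        A_lo = np.stack([_f1(w, zk, 1e-7) for zk in nodes])          # (K, T)
        A_up = np.stack([_f1(w, 1.0 - zk, 1e-7) for zk in nodes])    # (K, T)
        return {"tau_grid": tau_grid, "nodes": nodes, "wts": wts,
                "A_lo": A_lo, "A_up": A_up, "a": a, "t0": t0}

    def _per_cell_ks(self, prep, drifts):
        """KS distance per cell for one drift candidate per cell."""
        a = prep["a"]
        t0 = prep["t0"]
        tau_grid = prep["tau_grid"]
        nodes, wts = prep["nodes"], prep["wts"]
        v = np.asarray(drifts)[:, None]                               # (C, 1)
        damp = np.exp(-(v**2) * tau_grid[None, :] / 2.0)              # (C, T)
        wl = wts[None, :] * np.exp(-v * a * nodes[None, :])           # (C, K)
        wu = wts[None, :] * np.exp(v * a * (1.0 - nodes[None, :]))    # (C, K)
        dens_lo = (wl @ prep["A_lo"]) * damp / a**2
        dens_up = (wu @ prep["A_up"]) * damp / a**2
        dtau = self.grid_dt
        F_lo = np.concatenate(
            [np.zeros((len(v), 1)),
             np.cumsum((dens_lo[:, 1:] + dens_lo[:, :-1]) / 2, axis=1) * dtau], axis=1)
        F_up = np.concatenate(
            [np.zeros((len(v), 1)),
             np.cumsum((dens_up[:, 1:] + dens_up[:, :-1]) / 2, axis=1) * dtau], axis=1)
        p_pro = (wts[None, :] * (1.0 - analytic_choice_prob(
            v, a, nodes[None, :]))).sum(axis=1)

        out = np.empty(len(self.cells))
        for i, s in enumerate(self.signed):
            tau = np.abs(s) - t0
            neg = s < 0
            F = np.empty_like(s)
            F[neg] = p_pro[i] - np.interp(tau[neg], tau_grid, F_lo[i])
            F[~neg] = p_pro[i] + np.interp(tau[~neg], tau_grid, F_up[i])
            n = len(s)
            steps = np.arange(n + 1) / n
            out[i] = max(np.max(np.abs(F - steps[1:])), np.max(np.abs(F - steps[:-1])))
        return out

    def best_drifts(self, z, a, t0, szr):
        """Profile the per-cell drifts: coarse grid then successive
        refinements, all cells searched simultaneously."""
        prep = self._prepare(z, a, t0, szr)
        n_c = len(self.cells)
        lo = np.full(n_c, self.drift_bounds[0])
        hi = np.full(n_c, self.drift_bounds[1])
        best_v = np.zeros(n_c)
        best_val = np.full(n_c, np.inf)
        for n_pts in (13, 7, 7, 7):
            grid = np.linspace(0.0, 1.0, n_pts)
            vals = np.empty((n_pts, n_c))
            for j, g in enumerate(grid):
                vals[j] = self._per_cell_ks(prep, lo + g * (hi - lo))
            j_best = np.argmin(vals, axis=0)
            v_here = lo + grid[j_best] * (hi - lo)
            val_here = vals[j_best, np.arange(n_c)]
            improve = val_here < best_val
            best_v = np.where(improve, v_here, best_v)
            best_val = np.where(improve, val_here, best_val)
            half = (hi - lo) / (n_pts - 1)
            lo = np.maximum(best_v - half, self.drift_bounds[0])
            hi = np.minimum(best_v + half, self.drift_bounds[1])
        return best_v, best_val


def fit_group_ks(trials: pd.DataFrame, games: pd.DataFrame | None = None,
                 *, biased: bool = True, grid_dt: float = 0.005,
                 t_max: float | None = None, seed: int = 0, n_starts: int = 2,
                 maxiter: int = 120) -> FitResult:
    """Group-level KS fit: one drift per (DicDiff, ReceDiff) cell plus
    common ``(z, a, t0, szr)`` (``z`` fixed at 0.5 when ``biased=False``).

    Pro-social RTs are mapped to negative signed times and the
    count-weighted sum of per-cell KS distances between the empirical and
    the model's defective signed-RT CDF is minimized.  Model CDFs are
    tabulated on a ``grid_dt`` decision-time grid up to ``t_max``
    (default: beyond the slowest observed response).
    """
    df = trials if "dic_diff" in trials.columns else attach_game_columns(trials, games)
    cells, signed = _cell_arrays(df)
    if games is not None:
        design_cells = set(zip(games["dic_diff"].astype(int),
                               games["rece_diff"].astype(int)))
        empty = design_cells - set(cells)
        if empty:
            warnings.warn(f"{len(empty)} design cells have no trials and are skipped")
    rt = df["rt"].to_numpy(float)
    min_rt = float(rt.min())
    if t_max is None:
        t_max = float(max(10.0, rt.max() + 0.5))
    obj = _GroupObjective(cells, signed, grid_dt, t_max, DRIFT_BOUNDS)

    t0_hi = max(min_rt - 0.01, 0.02)
    t0_lo = min(0.05, 0.5 * t0_hi)

    def outer(theta):
        if biased:
            z, a, t0, szr_frac = theta
        else:
            a, t0, szr_frac = theta
            z = 0.5
        szr = szr_frac * 2.0 * min(z, 1.0 - z)
        _, vals = obj.best_drifts(z, a, t0, szr)
        return float(np.sum(obj.counts * vals))

    lo = ([0.05] if biased else []) + [0.5, t0_lo, 0.0]
    hi = ([0.95] if biased else []) + [8.0, t0_hi, 0.9]
    rng = np.random.default_rng(seed)
    starts = [np.array(([0.5] if biased else []) + [3.5, min(0.7 * min_rt, t0_hi), 0.1])]
    for _ in range(n_starts - 1):
        u = rng.random(len(lo))
        starts.append(np.array(lo) + (0.15 + 0.7 * u) * (np.array(hi) - np.array(lo)))

    best = None
    for x0 in starts:
        res = minimize(outer, x0, method="Nelder-Mead",
                       bounds=Bounds(np.array(lo), np.array(hi)),
                       options={"maxiter": maxiter, "fatol": 1e-3, "xatol": 2e-3})
        if best is None or res.fun < best.fun:
            best = res

    if biased:
        z, a, t0, szr_frac = best.x
    else:
        (a, t0, szr_frac), z = best.x, 0.5
    szr = float(szr_frac * 2.0 * min(z, 1.0 - z))
    drifts, _ = obj.best_drifts(z, a, t0, szr)
    params = DDMParams(a=float(a), z=float(z), t0=float(t0), szr=szr,
                       cell_drifts={c: float(v) for c, v in zip(cells, drifts)})
    k = len(cells) + (4 if biased else 3)
    return FitResult(params=params, objective=float(best.fun), n_obs=len(df),
                     k_params=k, converged=bool(best.success),
                     n_starts_used=len(starts))


def jackknife_se(group_fit_fn, subjects) -> dict[str, float]:
    """Leave-one-subject-out standard errors of a group-level estimator.

    ``group_fit_fn`` maps a list of subject ids to a flat ``{name: value}``
    dict; returns ``{name: SE}`` with
    ``SE = sqrt((n-1)/n * sum((theta_-i - mean)^2))``.
    """
    subjects = list(subjects)
    n = len(subjects)
    if n < 3:
        raise ValueError("jackknife needs at least 3 subjects")
    reps: list[dict[str, float]] = []
    for i, s in enumerate(subjects):
        keep = subjects[:i] + subjects[i + 1:]
        try:
            reps.append(dict(group_fit_fn(keep)))
        except Exception as exc:  # noqa: BLE001 - flagged, not fatal
            warnings.warn(f"leave-one-out fit failed for subject {s!r}: {exc}")
    if len(reps) < 3:
        raise RuntimeError("too few successful leave-one-out fits")
    m = len(reps)
    keys = reps[0].keys()
    out = {}
    for key in keys:
        vals = np.array([r[key] for r in reps], dtype=float)
        out[key] = float(np.sqrt((m - 1) / m * np.sum((vals - vals.mean()) ** 2)))
    return out
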