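"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the study conditions: 102 subjects, 200
mini-dictator games in four blocks (two time-free, one time-pressure
with a 2 s deadline, one time-delay with a 10 s viewing period), with
heterogeneous advantageous-inequality aversion ``beta`` and choices/RTs
produced by a biased DDM whose starting point anti-correlates with
``beta``:

* ``beta`` is drawn from a 50/50 mixture of Normal(0.1, 0.1^2) and
  Normal(0.7, 0.15^2), truncated to (-1, 2) — a selfish and a pro-social
  sub-population.
* the relative starting point is ``z = 0.5 - kappa * (beta - anchor)``
  clipped to [0.05, 0.95], with ``anchor`` between the two mixture
  components, so pro-social subjects start nearer the pro-social
  boundary and selfish subjects nearer the selfish one.
* drift rates are proportional to the Fehr-Schmidt utility difference:
  ``v = scale * (DicDiff - beta * (DicDiff + ReceDiff))``, i.e.
  coefficients ``(0, scale*(1-beta), -scale*beta)``.
* time pressure halves the threshold (scale 0.5, the same narrowing
  the threshold-manipulation experiment uses; optionally collapsing
  bounds) under a hard 2 s response deadline; timeouts are resolved by
  the sign of the accumulated evidence.  Time delay widens the threshold
  (scale 1.5); only the choice is informative, the recorded RT is
  10 s plus a motor latency and is flagged censored.

A separate routine replicates the threshold-manipulation simulation
experiment: 50 simulated subjects with drifts uniform on
[-2e-4, 2e-4] per ms, 1000 trials at threshold separations 2 and 1,
with the starting point unbiased, proportional to drift
(``R0 = a/2 + 5000 v``) or a fixed ``a/2 +/- 0.25`` offset.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .ddm import DDMParams, drift_rates
from .simulate import simulate_wiener

__all__ = [
    "SIM_EXPERIMENT_SIGMA",
    "CohortConfig",
    "SubjectGroundTruth",
    "sample_subjects",
    "simulate_trial_set",
    "simulate_threshold_experiment",
    "write_ground_truth_json",
]

#: Diffusion coefficient (evidence / sqrt(s)) for the threshold-manipulation
#: simulation experiment.  With drifts in [-2e-4, 2e-4] per ms and thresholds
#: 2 and 1, sigma = 0.5 spreads choice probabilities over most of [0, 1]
#: and keeps all three threshold contrasts (toward chance when unbiased,
#: away from chance when start-biased, proportionally or by a fixed
#: +/-0.25) resolvable at 1000 trials; see docs/methods.md for the
#: small-drift analysis behind this choice.
SIM_EXPERIMENT_SIGMA = 0.5

TRIAL_COLUMNS = ["subject_id", "game_id", "condition", "choice", "rt", "censored"]


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_subjects: int = 102
    # beta mixture: (weight, mean, sd) per component, truncated to beta_range
    beta_mixture: tuple = ((0.5, 0.1, 0.1), (0.5, 0.7, 0.15))
    beta_range: tuple = (-1.0, 2.0)
    kappa: float = 0.5
    # beta at which the starting point is unbiased (z = 0.5); the default
    # sits between the two mixture components so both the selfish and the
    # pro-social sub-population carry starting-point biases of comparable
    # size (|z - 0.5| ~ 0.09-0.18), within the spread of empirical fits
    beta_anchor: float = 0.35
    z_clip: tuple = (0.05, 0.95)
    a_mean: float = 3.5
    a_sd: float = 0.4
    t0_range: tuple = (0.25, 0.45)
    drift_scale: float = 0.05  # evidence/s per utility point
    szr: float = 0.0
    pressure_threshold_scale: float = 0.5
    delay_threshold_scale: float = 1.5
    pressure_deadline: float = 2.0
    pressure_collapse: bool = False
    delay_view_time: float = 10.0
    motor_latency_mean: float = 0.5
    motor_latency_sd: float = 0.2
    motor_latency_min: float = 0.15
    dt: float = 0.001
    bridge: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if not 0 < self.pressure_threshold_scale <= 1:
            raise ValueError("pressure_threshold_scale must be in (0, 1]")
        if self.delay_threshold_scale < 1:
            raise ValueError("delay_threshold_scale must be >= 1")
        if not (abs(sum(w for w, _, _ in self.beta_mixture) - 1.0) < 1e-9):
            raise ValueError("beta mixture weights must sum to 1")
        if self.kappa < 0 or self.drift_scale <= 0:
            raise ValueError("kappa must be >= 0 and drift_scale > 0")


@dataclass
class SubjectGroundTruth:
    subject_id: int
    beta_true: float
    ddm: DDMParams
    pressure_threshold_scale: float
    delay_threshold_scale: float
    motor_latency_mean: float
    motor_latency_sd: float


def sample_subjects(n: int, config: CohortConfig | None = None,
                    seed: int = 0) -> list[SubjectGroundTruth]:
    """Draw ``n`` subjects with beta-linked starting points."""
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    anchor = config.beta_anchor
    weights = np.array([w for w, _, _ in config.beta_mixture])
    subjects = []
    for i in range(n):
        while True:
            comp = rng.choice(len(weights), p=weights)
            _, mu, sd = config.beta_mixture[comp]
            beta = float(rng.normal(mu, sd))
            if config.beta_range[0] < beta < config.beta_range[1]:
                break
        z = float(np.clip(0.5 - config.kappa * (beta - anchor), *config.z_clip))
        a = float(np.clip(rng.normal(config.a_mean, config.a_sd), 1.0, 8.0))
        t0 = float(rng.uniform(*config.t0_range))
        k = config.drift_scale
        ddm = DDMParams(a=a, z=z, t0=t0, szr=config.szr,
                        drift_coefs=(0.0, k * (1.0 - beta), -k * beta))
        subjects.append(SubjectGroundTruth(
            subject_id=i + 1, beta_true=beta, ddm=ddm,
            pressure_threshold_scale=config.pressure_threshold_scale,
            delay_threshold_scale=config.delay_threshold_scale,
            motor_latency_mean=config.motor_latency_mean,
            motor_latency_sd=config.motor_latency_sd))
    return subjects


def simulate_trial_set(subjects, games: pd.DataFrame, seed: int = 0,
                       config: CohortConfig | None = None) -> pd.DataFrame:
    """Simulate every subject through all blocks of the games table.

    Returns a tidy trials table (one row per decision).  Pressure RTs
    are bounded by the deadline (timeouts resolved by the sign of the
    evidence about the midline, a fair coin at the midline exactly);
    delay RTs are ``view_time + motor latency`` and flagged censored.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    frames = []
    for cond, sub_games in games.groupby("condition", sort=False):
        # one vectorized sweep per condition over all subjects x games
        n_g = len(sub_games)
        v = np.concatenate([drift_rates(s.ddm, sub_games) for s in subjects])
        z = np.repeat([s.ddm.z for s in subjects], n_g)
        t0 = np.repeat([s.ddm.t0 for s in subjects], n_g)
        sid = np.repeat([s.subject_id for s in subjects], n_g)
        gid = np.tile(sub_games["game_id"].to_numpy(), len(subjects))
        n = n_g * len(subjects)
        if cond == "pressure":
            a_c = np.repeat([s.ddm.a * s.pressure_threshold_scale
                             for s in subjects], n_g)
            dl = np.maximum(config.pressure_deadline - t0, config.dt)
            res = simulate_wiener(n, v, a_c, z, dt=config.dt, szr=config.szr,
                                  deadline=dl, collapse=config.pressure_collapse,
                                  rng=rng, bridge=config.bridge)
            choice = res.choice_selfish.copy()
            rt = res.decision_time + t0
            timed_out = ~res.resolved
            if timed_out.any():
                e = res.evidence[timed_out]
                mid = a_c[timed_out] / 2.0
                coin = rng.random(int(timed_out.sum())) < 0.5
                choice[timed_out] = np.where(e == mid, coin, e > mid)
                rt[timed_out] = config.pressure_deadline
            censored = np.zeros(n, dtype=bool)
        elif cond == "delay":
            a_c = np.repeat([s.ddm.a * s.delay_threshold_scale
                             for s in subjects], n_g)
            # the decision time is unobservable here (RT is the viewing
            # period plus motor latency), so a coarser step and a longer
            # absorption budget are safe: with the bridge correction the
            # choice probabilities are exact at any step size
            res = simulate_wiener(n, v, a_c, z, dt=max(config.dt, 0.005),
                                  szr=config.szr, rng=rng, bridge=True,
                                  max_time=300.0)
            _require_resolved(res, cond)
            choice = res.choice_selfish
            mot_mu = np.repeat([s.motor_latency_mean for s in subjects], n_g)
            mot_sd = np.repeat([s.motor_latency_sd for s in subjects], n_g)
            motor = np.maximum(rng.normal(mot_mu, mot_sd),
                               config.motor_latency_min)
            rt = config.delay_view_time + motor
            censored = np.ones(n, dtype=bool)
        else:  # time-free
            a_c = np.repeat([s.ddm.a for s in subjects], n_g)
            res = simulate_wiener(n, v, a_c, z, dt=config.dt, szr=config.szr,
                                  rng=rng, bridge=config.bridge)
            _require_resolved(res, cond)
            choice = res.choice_selfish
            rt = res.decision_time + t0
            censored = np.zeros(n, dtype=bool)
        frames.append(pd.DataFrame({
            "subject_id": sid, "game_id": gid, "condition": cond,
            "choice": np.where(choice, "selfish", "prosocial"),
            "rt": rt, "censored": censored}))
    out = (pd.concat(frames, ignore_index=True)
           .sort_values(["subject_id", "condition", "game_id"], kind="stable")
           .reset_index(drop=True))
    return out[TRIAL_COLUMNS]


def _require_resolved(res, cond):
    if not res.resolved.all():
        raise RuntimeError(
            f"{cond}: diffusion not absorbed within the simulation time budget")


def simulate_threshold_experiment(bias_mode: str, n_subjects: int = 50,
                         n_trials: int = 1000, thresholds=(2.0, 1.0),
                         collapsing: bool = False, seed: int = 0, *,
                         sigma: float = SIM_EXPERIMENT_SIGMA, dt: float = 0.001,
                         deadline: float = 2.0,
                         max_time: float = 60.0) -> pd.DataFrame:
    """Threshold-manipulation simulation experiment.

    Simulated subjects carry a single drift ``v ~ U[-2e-4, 2e-4]`` per ms
    and are run for ``n_trials`` at each threshold separation in
    ``thresholds`` (wide = no time pressure, narrow = time pressure) with
    a 1 ms step.  ``bias_mode``:

    * ``"none"`` — starting point at ``a/2``;
    * ``"proportional"`` — ``R0 = a/2 + 5000 * v`` (clipped to [0, a]);
    * ``"fixed"`` — ``R0 = a/2 + 0.25 * sign(v)``.

    With ``collapsing=True`` the narrow threshold is replaced by the wide
    one whose bounds collapse linearly to the midline at ``deadline``
    (unresolved walkers decided by the sign of the evidence).  Returns a
    per-subject table of selfish-choice fractions.
    """
    if bias_mode not in ("none", "proportional", "fixed"):
        raise ValueError(f"unknown bias_mode {bias_mode!r}")
    rng = np.random.default_rng(seed)
    v_ms = rng.uniform(-2e-4, 2e-4, n_subjects)
    v_s = v_ms * 1000.0  # evidence per second

    records = {"subject_id": np.arange(1, n_subjects + 1), "drift_per_ms": v_ms}
    labels = ["wide", "narrow"]
    for label, a in zip(labels, thresholds):
        collapse_here = collapsing and label == "narrow"
        a_eff = thresholds[0] if collapse_here else a
        if bias_mode == "none":
            r0 = np.full(n_subjects, a_eff / 2.0)
        elif bias_mode == "proportional":
            r0 = a_eff / 2.0 + 5000.0 * v_ms
        else:
            r0 = a_eff / 2.0 + 0.25 * np.sign(v_ms)
        z = np.clip(r0 / a_eff, 0.0, 1.0)

        v_rep = np.repeat(v_s, n_trials)
        z_rep = np.repeat(z, n_trials)
        res = simulate_wiener(
            n_subjects * n_trials, v_rep, a_eff, z_rep, sigma=sigma, dt=dt,
            deadline=deadline if collapse_here else None,
            collapse=collapse_here, rng=rng, max_time=max_time)
        choice = res.choice_selfish.copy()
        unresolved = ~res.resolved
        if unresolved.any():
            e = res.evidence[unresolved]
            coin = rng.random(unresolved.sum()) < 0.5
            choice[unresolved] = np.where(e == a_eff / 2, coin, e > a_eff / 2)
        records[f"p_selfish_{label}"] = choice.reshape(n_subjects, n_trials).mean(axis=1)
        records[f"a_{label}"] = np.full(n_subjects, a_eff)
    return pd.DataFrame(records)


def write_ground_truth_json(subjects, path, extra: dict | None = None) -> None:
    payload = {
        "subjects": [
            {**{k: v for k, v in asdict(s).items() if k != "ddm"},
             "ddm": asdict(s.ddm)}
            for s in subjects
        ]
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
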