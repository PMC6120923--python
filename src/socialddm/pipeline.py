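"""End-to-end orchestration: generate -> estimate -> classify -> fit ->
compare -> predict, with all artifacts written as CSV/JSON.

Every output embeds the hash of the fully-resolved configuration (CSV
files as a leading ``# config_hash=...`` comment line, JSON files as a
field), so a run is reproducible from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import cohort as coh
from . import ddm as ddm_mod
from . import evaluation as ev
from . import preferences as prefs
from .task_design import full_design, median_indifference_beta

log = logging.getLogger("socialddm")

__all__ = ["PipelineConfig", "rt_strength_analysis", "run_full_pipeline"]


@dataclass
class PipelineConfig:
    """Seeds, sizes and switches for one full run."""

    seed_design: int = 11
    seed_cohort: int = 12
    seed_trials: int = 13
    seed_fits: int = 14
    seed_predictions: int = 15
    n_subjects: int = 102
    cohort: coh.CohortConfig = field(default_factory=coh.CohortConfig)
    # individual DDM fits; fit_subject_limit caps how many subjects get the
    # expensive per-subject DDM fits (None = all) — preference estimation
    # and the group stats always use the whole cohort
    run_individual_fits: bool = True
    fit_subject_limit: int | None = None
    fit_n_starts: int = 5
    fit_maxfev: int = 2000
    # group KS fits + out-of-sample prediction
    run_group_prediction: bool = True
    group_grid_dt: float = 0.01
    group_maxiter: int = 80
    group_n_starts: int = 1
    # leave-one-subject-out SEs for the group fits; off by default because
    # it multiplies the group-fit cost by the number of subjects
    group_jackknife: bool = False
    prediction_n_sims: int = 5000
    # threshold-manipulation simulation experiment
    run_threshold_sim: bool = True
    sim_n_subjects: int = 50
    sim_n_trials: int = 1000
    # RT / strength-of-preference analysis
    rt_bins: int = 11
    rt_first_half_only: bool = True
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.cohort, dict):
            self.cohort = coh.CohortConfig(**self.cohort)
        self.cohort = dataclasses.replace(self.cohort, n_subjects=self.n_subjects)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where results land does not change them
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def rt_strength_analysis(trials: pd.DataFrame, estimates: pd.DataFrame,
                         games: pd.DataFrame, condition: str, *,
                         n_bins: int = 11,
                         first_half_only: bool = False) -> dict:
    """Relationship between log(RT) and strength of preference.

    The per-trial utility difference (selfish minus pro-social option,
    using the condition-specific beta estimate) is standardized to
    [-1, 1] within subject by its maximum absolute value, the pooled
    data are cut into ``n_bins`` equal-count bins, and mean log(RT) is
    averaged within subject before taking across-subject means and SEs
    per bin.  Also returns per-subject OLS slopes of log(RT) on the
    absolute standardized utility difference, with a one-sample t-test
    across subjects (a two-stage stand-in for a mixed-effects model).
    """
    cond_group = {"free1": "free", "free2": "free"}.get(condition, condition)
    conds = ["free1", "free2"] if condition == "free" else [condition]
    df = trials[trials["condition"].isin(conds) & ~trials["censored"]].copy()
    if first_half_only:
        df = df[df["game_id"] <= 50]
    if df.empty:
        raise ValueError(f"no usable (non-censored) trials in condition {condition!r}")
    df = ddm_mod.attach_game_columns(df, games)
    bmap = (estimates[estimates["condition"] == cond_group]
            .set_index("subject_id")["beta"])
    df["beta_hat"] = df["subject_id"].map(bmap)
    if df["beta_hat"].isna().any():
        raise ValueError("missing beta estimate for some subjects")
    df["du"] = prefs.utility_difference(df["dic_diff"], df["rece_diff"], df["beta_hat"])
    scale = df.groupby("subject_id")["du"].transform(lambda s: np.abs(s).max())
    df["du_std"] = df["du"] / scale.replace(0.0, 1.0)
    df["log_rt"] = np.log(df["rt"])

    if len(df) < n_bins:
        raise ValueError("fewer trials than bins")
    df["bin"] = pd.qcut(df["du_std"].rank(method="first"), n_bins, labels=False)
    per_subj_bin = (df.groupby(["bin", "subject_id"])
                    .agg(log_rt=("log_rt", "mean"), du_std=("du_std", "mean")))
    binned = per_subj_bin.groupby("bin").agg(
        du_std=("du_std", "mean"), mean_log_rt=("log_rt", "mean"),
        se_log_rt=("log_rt", "sem"), n_subjects=("log_rt", "size")).reset_index()

    slopes = []
    for sid, sub in df.groupby("subject_id"):
        x = np.abs(sub["du_std"].to_numpy())
        y = sub["log_rt"].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            slopes.append((sid, 0.0))
            continue
        slopes.append((sid, float(np.polyfit(x, y, 1)[0])))
    slopes_df = pd.DataFrame(slopes, columns=["subject_id", "slope"])
    arr = slopes_df["slope"].to_numpy()
    if np.ptp(arr) == 0:
        tstat, pval = 0.0, 1.0
    else:
        tstat, pval = sps.ttest_1samp(arr, 0.0)
    return {
        "condition": condition,
        "binned": binned,
        "slopes": slopes_df,
        "mean_slope": float(arr.mean()),
        "t_stat": float(tstat),
        "p_value": float(pval),
    }


# ---------------------------------------------------------------------------


def run_full_pipeline(config: PipelineConfig | None = None) -> dict:
    """Execute the full chain and return (and optionally write) the
    report bundle.  Deterministic for a fixed config."""
    config = config or PipelineConfig()
    chash = config.config_hash
    bundle: dict = {"config": config.to_dict(), "config_hash": chash}
    timings: dict[str, float] = {}

    def stage(name):
        log.info("stage %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    try:
        s = stage("design")
        games = full_design(config.seed_design)
        cutoff = median_indifference_beta(games[games["condition"] == "free1"])
        bundle["games"] = games
        bundle["beta_cutoff"] = cutoff
        done(s)

        s = stage("cohort")
        subjects = coh.sample_subjects(config.n_subjects, config.cohort,
                                       seed=config.seed_cohort)
        trials = coh.simulate_trial_set(subjects, games, seed=config.seed_trials,
                                        config=config.cohort)
        bundle["subjects"] = subjects
        bundle["trials"] = trials
        done(s)

        s = stage("preferences")
        estimates = prefs.estimate_all(trials, games)
        wide = estimates.pivot(index="subject_id", columns="condition",
                               values="beta")
        cls = pd.DataFrame({
            "subject_id": wide.index,
            "beta_f": wide["free"].to_numpy(),
            "beta_p": wide["pressure"].to_numpy(),
            "beta_d": wide["delay"].to_numpy(),
        })
        cls["social_type"] = [prefs.classify_social_type(b, cutoff)
                              for b in cls["beta_f"]]
        cls["predisposition"] = [prefs.classify_predisposition(p, d)
                                 for p, d in zip(cls["beta_p"], cls["beta_d"])]
        truth = {sub.subject_id: sub for sub in subjects}
        cls["beta_true"] = cls["subject_id"].map({k: v.beta_true for k, v in truth.items()})
        cls["z_true"] = cls["subject_id"].map({k: v.ddm.z for k, v in truth.items()})
        bundle["estimates"] = estimates
        bundle["classification"] = cls
        bundle["stats"] = _preference_stats(cls)
        done(s)

        if config.run_individual_fits:
            s = stage("individual_fits")
            fits = _individual_fits(trials, games, cls, config)
            bundle["individual_fits"] = fits
            bundle["stats"].update(_fit_stats(fits, cls))
            done(s)

        if config.run_group_prediction:
            s = stage("group_prediction")
            pred_table, group_fits = _group_prediction(trials, games, cls, config)
            bundle["prediction_table"] = pred_table
            bundle["group_fits"] = group_fits
            done(s)

        if config.run_threshold_sim:
            s = stage("threshold_sim")
            sims = {mode: coh.simulate_threshold_experiment(
                        mode, config.sim_n_subjects, config.sim_n_trials,
                        seed=config.seed_predictions + i)
                    for i, mode in enumerate(("none", "proportional", "fixed"))}
            bundle["threshold_sim"] = sims
            done(s)

        s = stage("rt_strength")
        rt_tables = {}
        for cond in ("free", "pressure"):
            rt_tables[cond] = rt_strength_analysis(
                trials, estimates, games, cond, n_bins=config.rt_bins,
                first_half_only=(cond == "free" and config.rt_first_half_only))
        bundle["rt_strength"] = rt_tables
        done(s)
    except Exception as exc:
        exc.add_note(f"pipeline stage failed: {s}")
        if config.out_dir:
            _write_bundle(bundle, config, timings, failed_stage=s)
        raise

    bundle["timings"] = timings
    if config.out_dir:
        _write_bundle(bundle, config, timings)
    return bundle


def _preference_stats(cls: pd.DataFrame) -> dict:
    out = {}
    sel = cls[cls["social_type"] == "selfish"]
    pro = cls[cls["social_type"] == "prosocial"]
    for name, grp in (("selfish", sel), ("prosocial", pro)):
        if len(grp) >= 5:
            _, p_pf = prefs.wilcoxon_signed_rank(grp["beta_p"], grp["beta_f"])
            _, p_pd = prefs.wilcoxon_signed_rank(grp["beta_p"], grp["beta_d"])
        else:
            p_pf = p_pd = np.nan
        out[f"{name}_n"] = int(len(grp))
        out[f"{name}_median_dbeta_pd"] = float((grp["beta_p"] - grp["beta_d"]).median())
        out[f"{name}_wilcoxon_p_pressure_vs_free"] = p_pf
        out[f"{name}_wilcoxon_p_pressure_vs_delay"] = p_pd
    rho, p = prefs.spearman_rho(cls["beta_p"] - cls["beta_d"], cls["beta_f"])
    out["spearman_dbeta_betaf_rho"] = rho
    out["spearman_dbeta_betaf_p"] = p
    if len(sel) >= 3 and len(pro) >= 3:
        u = sps.mannwhitneyu(pro["beta_p"] - pro["beta_d"],
                             sel["beta_p"] - sel["beta_d"],
                             alternative="greater")
        out["amplification_ranksum_p"] = float(u.pvalue)
    return out


def _individual_fits(trials, games, cls, config: PipelineConfig) -> pd.DataFrame:
    free = trials[trials["condition"].isin(["free1", "free2"])]
    if config.fit_subject_limit is not None:
        keep = np.sort(free["subject_id"].unique())[: config.fit_subject_limit]
        free = free[free["subject_id"].isin(keep)]
    merged = ddm_mod.attach_game_columns(free, games)
    rows = []
    for i, (sid, sub) in enumerate(merged.groupby("subject_id", sort=True)):
        for biased in (True, False):
            fr = ddm_mod.fit_individual(sub, biased=biased,
                                        n_starts=config.fit_n_starts,
                                        seed=config.seed_fits + i,
                                        maxfev=config.fit_maxfev)
            dc, dd, dr = fr.params.drift_coefs
            rows.append({
                "subject_id": int(sid), "model": "biased" if biased else "unbiased",
                "z": fr.params.z, "a": fr.params.a, "t0": fr.params.t0,
                "d_c": dc, "d_d": dd, "d_r": dr,
                "loglik": fr.objective, "bic": fr.bic,
                "converged": fr.converged, "n_obs": fr.n_obs,
            })
    return pd.DataFrame(rows)


def _fit_stats(fits: pd.DataFrame, cls: pd.DataFrame) -> dict:
    wide_bic = fits.pivot(index="subject_id", columns="model", values="bic")
    z_hat = fits[fits["model"] == "biased"].set_index("subject_id")["z"]
    merged = (cls.set_index("subject_id").join(z_hat.rename("z_hat"))
              .dropna(subset=["z_hat"]))
    biased_wins = int((wide_bic["biased"] < wide_bic["unbiased"]).sum())
    out = {
        "bic_biased_wins": biased_wins,
        "bic_n_subjects": int(len(wide_bic)),
        "bic_binomial_p": prefs.exact_binomial_two_sided(biased_wins, len(wide_bic)),
    }
    rho, p = prefs.spearman_rho(merged["z_hat"], merged["beta_f"])
    out["spearman_zhat_betaf_rho"] = rho
    out["spearman_zhat_betaf_p"] = p
    sp = merged[merged["predisposition"] == "selfishly_predisposed"]
    pp = merged[merged["predisposition"] == "prosocially_predisposed"]
    if len(sp):
        k = int((sp["z_hat"] > 0.5).sum())
        out["selfish_predisposed_z_above_half"] = k
        out["selfish_predisposed_n"] = int(len(sp))
        out["selfish_predisposed_binomial_p"] = prefs.exact_binomial_two_sided(k, len(sp))
        out["selfish_predisposed_mean_z"] = float(sp["z_hat"].mean())
    if len(pp):
        k = int((pp["z_hat"] < 0.5).sum())
        out["prosocial_predisposed_z_below_half"] = k
        out["prosocial_predisposed_n"] = int(len(pp))
        out["prosocial_predisposed_binomial_p"] = prefs.exact_binomial_two_sided(k, len(pp))
        out["prosocial_predisposed_mean_z"] = float(pp["z_hat"].mean())
    return out


def _group_prediction(trials, games, cls, config: PipelineConfig):
    """Split-half protocol: fit each predisposition group on Games 1-50
    (first time-free block), predict Games 51-100 (second block)."""
    free1 = trials[trials["condition"] == "free1"]
    free2 = trials[trials["condition"] == "free2"]
    games_free2 = games[games["condition"] == "free2"]
    rows = []
    group_fits = {}
    lam_parts: dict[str, list] = {}
    for predis in ("selfishly_predisposed", "prosocially_predisposed"):
        ids = cls.loc[cls["predisposition"] == predis, "subject_id"]
        fit_tr = ddm_mod.attach_game_columns(
            free1[free1["subject_id"].isin(ids)], games)
        held_tr = ddm_mod.attach_game_columns(
            free2[free2["subject_id"].isin(ids)], games)
        if fit_tr.empty or held_tr.empty:
            continue
        row = {"group": predis, "n_subjects": int(ids.size)}
        for biased in (True, False):
            name = "biased_ddm" if biased else "unbiased_ddm"
            fr = ddm_mod.fit_group_ks(fit_tr, games,
                                      biased=biased,
                                      grid_dt=config.group_grid_dt,
                                      seed=config.seed_fits,
                                      n_starts=config.group_n_starts,
                                      maxiter=config.group_maxiter)
            if biased and config.group_jackknife:
                def refit(keep_ids, _tr=fit_tr):
                    sub = _tr[_tr["subject_id"].isin(keep_ids)]
                    f = ddm_mod.fit_group_ks(
                        sub, games, biased=True,
                        grid_dt=config.group_grid_dt, seed=config.seed_fits,
                        n_starts=1, maxiter=config.group_maxiter)
                    return {"z": f.params.z, "a": f.params.a,
                            "t0": f.params.t0, "szr": f.params.szr}

                fr.extra["jackknife_se"] = ddm_mod.jackknife_se(
                    refit, list(ids))
            group_fits[f"{predis}:{name}"] = fr
            pr = ev.split_half_prediction(fr, held_tr, games_free2,
                                          n_sims=config.prediction_n_sims,
                                          seed=config.seed_predictions)
            row[f"sum_ae_{name}"] = pr.summed_ae
            lam_parts.setdefault(name, []).append(
                (pr.predicted.reindex(held_tr["game_id"]).to_numpy(),
                 held_tr["choice"].to_numpy()))
        for include_rt in (False, True):
            name = "logit_rt" if include_rt else "logit"
            lf = ev.fit_logit(fit_tr, include_rt=include_rt)
            p_trial = ev.predict_logit_probs(lf, held_tr)
            pred = (pd.Series(p_trial, index=held_tr["game_id"].to_numpy())
                    .groupby(level=0).mean())
            pred.index.name = "game_id"
            ae, total = ev.absolute_error_sum(pred, held_tr)
            row[f"sum_ae_{name}"] = total
            lam_parts.setdefault(name, []).append((p_trial, held_tr["choice"].to_numpy()))
        rows.append(row)
    table = pd.DataFrame(rows)
    lam_row = {"group": "pooled_lambda"}
    for name, parts in lam_parts.items():
        preds = np.concatenate([p for p, _ in parts])
        chs = np.concatenate([c for _, c in parts])
        lam_row[f"lambda_{name}"] = ev.cramers_lambda(preds, chs)
    table = pd.concat([table, pd.DataFrame([lam_row])], ignore_index=True)
    return table, group_fits


# ---------------------------------------------------------------------------
# artifact writing


def _write_csv(frame: pd.DataFrame, path: Path, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        frame.to_csv(fh, index=False)


def _write_bundle(bundle: dict, config: PipelineConfig, timings: dict,
                  failed_stage: str | None = None) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = bundle["config_hash"]
    if "games" in bundle:
        _write_csv(bundle["games"], out / "games.csv", chash)
    if "trials" in bundle:
        _write_csv(bundle["trials"], out / "trials.csv", chash)
    if "subjects" in bundle:
        coh.write_ground_truth_json(bundle["subjects"], out / "ground_truth.json",
                                    extra={"config_hash": chash})
    if "estimates" in bundle:
        _write_csv(bundle["estimates"], out / "estimates.csv", chash)
    if "classification" in bundle:
        _write_csv(bundle["classification"], out / "classification.csv", chash)
    if "individual_fits" in bundle:
        _write_csv(bundle["individual_fits"], out / "fits_individual.csv", chash)
        _write_csv(_group_params_table(bundle), out / "ddm_params_by_group.csv", chash)
    if "prediction_table" in bundle:
        _write_csv(bundle["prediction_table"], out / "prediction_comparison.csv", chash)
    if "group_fits" in bundle:
        payload = {"config_hash": chash}
        for key, fr in bundle["group_fits"].items():
            p = fr.params
            payload[key] = {
                "z": p.z, "a": p.a, "t0": p.t0, "szr": p.szr,
                "objective": fr.objective, "k_params": fr.k_params,
                "jackknife_se": fr.extra.get("jackknife_se"),
                "drifts": {f"d{c[0]}_r{c[1]}": v for c, v in p.cell_drifts.items()},
            }
        (out / "group_fits.json").write_text(json.dumps(payload, indent=1))
    if "threshold_sim" in bundle:
        for mode, frame in bundle["threshold_sim"].items():
            _write_csv(frame, out / f"threshold_sim_{mode}.csv", chash)
    for cond, res in bundle.get("rt_strength", {}).items():
        _write_csv(res["binned"], out / f"rt_strength_{cond}.csv", chash)
    run_log = {
        "config_hash": chash,
        "config": bundle["config"],
        "timings_s": timings,
        "failed_stage": failed_stage,
        "stats": _jsonable(bundle.get("stats", {})),
        "versions": _versions(),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1, default=str))


def _group_params_table(bundle: dict) -> pd.DataFrame:
    fits = bundle["individual_fits"]
    cls = bundle["classification"][["subject_id", "predisposition"]]
    merged = fits[fits["model"] == "biased"].merge(cls, on="subject_id")
    rows = []
    for predis, sub in merged.groupby("predisposition"):
        rows.append({
            "group": predis, "level": "individual_mean",
            "z": sub["z"].mean(), "a": sub["a"].mean(), "t0": sub["t0"].mean(),
            "n_subjects": len(sub),
        })
    for key, fr in bundle.get("group_fits", {}).items():
        if key.endswith(":biased_ddm"):
            p = fr.params
            rows.append({"group": key.split(":")[0], "level": "group_ks",
                         "z": p.z, "a": p.a, "t0": p.t0, "n_subjects": np.nan})
    return pd.DataFrame(rows)


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.integer,)):
            out[k] = int(v)
        elif isinstance(v, (np.floating, float)):
            out[k] = float(v)
        else:
            out[k] = v
    return out


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__

    return {"socialddm": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__}
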