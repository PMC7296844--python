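"""End-to-end pipeline: simulate -> fit behaviour -> compare models -> GLM ->
fit DCM -> PEB -> split-sample replication, driven by a YAML-able config."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, behavior, dcm, glm, hierfit, io, peb, rl, synth
from .task import TaskConfig

logger = logging.getLogger("rewardconn")

REQUIRED_KEYS = ("seed", "n_subjects", "out_dir")

DEFAULT_CONFIG = {
    "seed": 0,
    "n_subjects": 20,
    "out_dir": "results",
    "generating_model": 3,
    "model_ids": [1, 2, 3, 4, 5],
    "n_trials": 66,
    "n_choice_trials": 33,
    "n_scans": 500,
    "snr": 1.0,
    "n_splits": 20,
    "variance_threshold_pct": 10.0,
    "glm_variant": "modulated",
    "dcm_max_iter": 24,
    "ibic_samples": 2000,
}


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def validate_config(config: dict) -> dict:
    for key in REQUIRED_KEYS:
        if key not in config:
            raise ConfigError(f"missing required config key: {key!r}")
    merged = dict(DEFAULT_CONFIG)
    merged.update(config)
    unknown = set(merged) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return merged


def run_pipeline(config: dict) -> dict:
    """Run every stage on a synthetic cohort and write results to out_dir."""
    cfg = validate_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": cfg, "version": __version__, "seeds": {"master": cfg["seed"]}}
    t0 = time.time()
    rng = np.random.default_rng(cfg["seed"])

    def stage(name, fn):
        logger.info("stage %s ...", name)
        try:
            return fn()
        except Exception as exc:
            raise StageError(name, exc) from exc

    # --- simulate ---------------------------------------------------------
    task = TaskConfig.compact(
        n_scans=cfg["n_scans"],
        n_trials=cfg["n_trials"],
        n_choice_trials=cfg["n_choice_trials"],
    )
    cohort_bundle = stage(
        "simulate",
        lambda: synth.generate_dcm_cohort(
            cfg["n_subjects"], seed=rng, n_scans=cfg["n_scans"], snr=cfg["snr"], config=task,
            model=cfg["generating_model"],
        ),
    )
    cohort = cohort_bundle.subjects
    covariates = synth.cohort_covariates(cohort)
    io.write_covariates(out / "covariates.csv", covariates)
    for s, y in zip(cohort, cohort_bundle.data):
        io.write_events(out / f"{s.subject_id}_events.tsv", s.trials, task)
        io.write_roi_timeseries(out / f"{s.subject_id}_roi.csv", y, task.tr)
    results["simulate"] = {"n_subjects": len(cohort), "n_trials": len(cohort[0].trials)}

    # --- fit behaviour ----------------------------------------------------
    gen_model = rl.MODELS[cfg["generating_model"]]
    prior, fits = stage("fit-behavior", lambda: hierfit.em_group_fit(cohort, gen_model, seed=rng))
    results["fit_behavior"] = {
        "model": gen_model.model_id,
        "prior_mu": prior.mu,
        "prior_sigma2": prior.sigma2,
    }

    # --- compare models ---------------------------------------------------
    comparison = stage(
        "compare-models",
        lambda: hierfit.compare_models(
            cohort, model_set=cfg["model_ids"], seed=rng, n_mc_samples=cfg["ibic_samples"]
        ),
    )
    results["compare_models"] = {"ibic": comparison.ibic, "winner": comparison.winner}

    # --- GLM ---------------------------------------------------------------
    def run_glm():
        spec = glm.DesignSpec(tr=task.tr, n_scans=cfg["n_scans"])
        betas = []
        for s, fit, y in zip(cohort, fits, cohort_bundle.data):
            params = rl.RLParams.from_theta(fit.theta_map, gen_model)
            _, rpes = rl.rpe_series(s.trials, gen_model, params)
            events = io.trials_to_events(s.trials, task)
            X = glm.build_design(
                events, variant=cfg["glm_variant"], modulator_values=rpes, spec=spec
            )
            b, _ = glm.fit_first_level(y[:, 1], X)  # ventral striatum series
            betas.append(b[list(X.columns).index("outcome_modulator" if cfg["glm_variant"] == "modulated" else "outcome_win_choice")])
        rho, p = glm.second_level_correlation(np.asarray(betas), covariates["qids"].to_numpy())
        return {"rpe_beta_qids_spearman_rho": rho, "p": p}

    results["glm"] = stage("glm", run_glm)

    # --- fit DCM ------------------------------------------------------------
    def run_dcm():
        posts = []
        for y, u in zip(cohort_bundle.data, cohort_bundle.inputs):
            posts.append(
                dcm.invert_vl(cohort_bundle.spec, y, u, max_iter=cfg["dcm_max_iter"])
            )
        return posts

    posteriors = stage("fit-dcm", run_dcm)
    qids = covariates["qids"].to_numpy(dtype=float)
    keep = dcm.filter_subjects(posteriors, qids=qids, threshold_pct=cfg["variance_threshold_pct"])
    results["fit_dcm"] = {
        "mean_explained_variance": float(np.mean(keep["explained_variance"])),
        "n_included": int(keep["included"].size),
        "n_excluded": keep["excluded_count"],
        "qids_welch_p": keep.get("qids_welch_p"),
    }

    # --- PEB + BMR/BMA ------------------------------------------------------
    def run_peb():
        idx = keep["included"]
        a_sl = cohort_bundle.spec.a_indices
        means = np.array([posteriors[i].mu[a_sl] for i in idx])
        covs = np.array([posteriors[i].cov[a_sl, a_sl] for i in idx])
        # small demo cohorts cannot support the full covariate set
        columns = peb.COVARIATES[1:] if idx.size >= 12 else ("qids",)
        design = peb.build_design(
            covariates.iloc[idx], columns=columns, drop_degenerate=True
        )
        fit = peb.peb_fit(means, covs, design)
        models = peb.greedy_search(fit)
        avg = peb.bma(models)
        eff, p_on = avg.effect_summary(fit, "qids", peb.MPFC_TO_VS_INDEX)
        return {
            "free_energy": fit.free_energy,
            "qids_mpfc_to_vs_effect": eff,
            "qids_mpfc_to_vs_p_nonzero": p_on,
            "means": means,
            "covs": covs,
            "idx": idx,
        }

    peb_out = stage("peb", run_peb)
    results["peb"] = {k: v for k, v in peb_out.items() if k not in ("means", "covs", "idx")}

    # --- split-sample replication --------------------------------------------
    def run_rep():
        n_half = peb_out["idx"].size // 2
        rep = peb.split_sample_replication(
            peb_out["means"],
            peb_out["covs"],
            covariates.iloc[peb_out["idx"]],
            n_splits=cfg["n_splits"],
            seed=np.random.default_rng(cfg["seed"] + 1),
            design_columns=peb.COVARIATES[1:] if n_half >= 12 else ("qids",),
        )
        return {
            "proportion_negative": rep["proportion_negative"],
            "n_models": rep["n_models"],
        }

    results["replicate"] = stage("replicate", run_rep)
    results["runtime_s"] = time.time() - t0
    io.write_results(out / "results.json", results)
    (out / "run.log").write_text(
        f"rewardconn {__version__}\nseed={cfg['seed']}\nruntime={results['runtime_s']:.1f}s\n"
    )
    return results
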