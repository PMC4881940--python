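"""Config-driven end-to-end orchestration.

A single nested mapping (usually loaded from YAML) drives the full chain:
simulate (or ingest) a cohort, preprocess, estimate twin similarity and the
ACE decompositions, fit the growth models, and optionally run the power
simulation.  Every stochastic step carries an explicit seed, and a run
manifest records the package version, a stable hash of the normalized
config, seeds, row counts and per-stage wall time, so identical configs
reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, design
from .cohort import read_cohort_csv, validate_cohort, write_cohort_csv
from .growth import compare_growth_models, fit_growth, predicted_trajectory
from .params import CholeskyACEParams, MeanTrajectory, proportions_to_loadings
from .power import power_heritability
from .preprocess import preprocess_cohort
from .simulate import apply_missingness, simulate_cohort
from .twin import (
    falconer_estimates,
    fit_cholesky_ace,
    fit_univariate_ace,
    intraclass_correlation,
    likelihood_ci,
    stage_specific_proportion,
)

__all__ = ["validate_config", "run_pipeline", "config_hash", "load_config"]

log = logging.getLogger("twinstage")

_DEFAULTS = {
    "seed": None,  # required: every run names its seed explicitly
    "output_dir": "results/run",
    "generator": {
        "n_mz": design.N_MZ_PAIRS,
        "n_dz": design.N_DZ_PAIRS,
        "age_mean": design.AGE_MEAN,
        "age_sd": design.AGE_SD,
        "female_fraction": design.FEMALE_FRACTION,
        "outcomes": {"wellbeing": {"proportions": "wellbeing"}, "mentalhealth": {"proportions": "mentalhealth"}},
        "trajectory": {
            "baseline_mean": 0.0,
            "control_increment": 0.0,
            "intervention_increment": 0.07,
            "age_effect": 0.0,
            "sex_effect": 0.0,
        },
        "missingness": [1.0 - r for r in design.STAGE_RETENTION],
        "seed": None,
        "input_csv": None,
    },
    "preprocessing": {"rank_normalize": True, "per_stage_transform": True, "correct_age_sex": True},
    "models": {
        "stages": [1, 2, 3, 4],
        "ci_level": 0.95,
        "compute_ci": False,
        "restarts": 5,
        "missing_mode": "fiml",
        "seed": None,
    },
    "growth": {"time_coding": "occasion"},
    "power": {
        "run": False,
        "n_mz": design.N_MZ_PAIRS,
        "n_dz": design.N_DZ_PAIRS,
        "a2": 0.40,
        "c2": 0.0,
        "alpha": 0.05,
        "reps": 500,
        "seed": None,
    },
}


def _merge(defaults, user, path, errors):
    out = {}
    for key, dval in defaults.items():
        if isinstance(dval, dict) and key != "outcomes":
            out[key] = _merge(dval, (user or {}).get(key, {}) or {}, f"{path}.{key}", errors)
        else:
            out[key] = (user or {}).get(key, dval)
    for key in user or {}:
        if key not in defaults:
            errors.append(f"unknown key {path}.{key}")
    return out


def _resolve_params(spec: dict, name: str, errors: list) -> CholeskyACEParams | None:
    has_p = "proportions" in spec
    has_l = "loadings" in spec
    if has_p and has_l:
        errors.append(f"generator.outcomes.{name}: give exactly one of proportions or loadings, not both")
        return None
    if not has_p and not has_l:
        errors.append(f"generator.outcomes.{name}: needs proportions or loadings")
        return None
    try:
        if has_l:
            l = spec["loadings"]
            return CholeskyACEParams(np.array(l["a"]), np.array(l["c"]), np.array(l["e"]))
        p = spec["proportions"]
        if isinstance(p, str):
            tables = {"wellbeing": design.WELLBEING_COMPONENTS, "mentalhealth": design.MENTALHEALTH_COMPONENTS}
            p = tables[p]
        a, c, e = np.array(p["a"], float), np.array(p["c"], float), np.array(p["e"], float)
        row_sums = a.sum(axis=1) + c.sum(axis=1) + e.sum(axis=1)
        bad = np.flatnonzero(np.abs(row_sums - 1.0) > 0.02)
        if bad.size:
            errors.append(
                f"generator.outcomes.{name}: proportions at stage(s) {(bad + 1).tolist()} "
                f"sum to {np.round(row_sums[bad], 3).tolist()}, not 1 ± 0.02"
            )
            return None
        return proportions_to_loadings(a, c, e)
    except (KeyError, ValueError) as exc:
        errors.append(f"generator.outcomes.{name}: {exc}")
        return None


def validate_config(config: dict) -> dict:
    """Materialize defaults and check the whole config, reporting all errors.

    Sub-block seeds left unset are derived deterministically from the
    top-level seed.  Raises ``ValueError`` listing every problem found.
    """
    errors: list[str] = []
    cfg = _merge(_DEFAULTS, config or {}, "config", errors)
    if cfg["seed"] is None:
        errors.append("config.seed: a top-level seed is required")
    else:
        ss = np.random.SeedSequence(int(cfg["seed"]))
        derived = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
        for block, d in zip(("generator", "models", "power"), derived):
            if cfg[block]["seed"] is None:
                cfg[block]["seed"] = d
    gen = cfg["generator"]
    if gen.get("input_csv") is None:
        params = {}
        for name, spec in (gen.get("outcomes") or {}).items():
            p = _resolve_params(spec or {}, name, errors)
            if p is not None:
                params[name] = p
        cfg["_params"] = params
        if not params and not errors:
            errors.append("generator.outcomes: at least one outcome is required")
    rates = np.asarray(gen["missingness"], dtype=float)
    if rates.shape != (4,) or (rates < 0).any() or (rates >= 1).any():
        errors.append("generator.missingness: four proportions in [0, 1) required")
    if cfg["models"]["missing_mode"] not in ("fiml", "complete"):
        errors.append("models.missing_mode: must be 'fiml' or 'complete'")
    if not 0 < cfg["models"]["ci_level"] < 1:
        errors.append("models.ci_level: must be in (0, 1)")
    if errors:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return cfg


def config_hash(config: dict) -> str:
    """Stable hash of the normalized config (private keys excluded)."""
    public = {k: v for k, v in config.items() if not k.startswith("_")}
    return hashlib.sha256(json.dumps(public, sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def _icc_table(processed: pd.DataFrame, outcomes) -> pd.DataFrame:
    rows = []
    for outcome in outcomes:
        for zyg in ("MZ", "DZ"):
            cells = {}
            for stage in (1, 2, 3, 4):
                est = intraclass_correlation(processed, outcome, stage)
                r, n = (est.r_mz, est.n_mz_pairs) if zyg == "MZ" else (est.r_dz, est.n_dz_pairs)
                cells[f"stage{stage}"] = f"{r:.2f} (N={n})"
            rows.append({"outcome": outcome, "zygosity": zyg, **cells})
    return pd.DataFrame(rows)


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis chain; returns the run report dict.

    Stage order: simulate (or ingest) → preprocess → ICC/Falconer →
    univariate ACE per stage → four-stage Cholesky ACE → derived
    stage-specific proportions → growth models → optional power.  Any
    stage failure aborts with the stage name; partial outputs already
    written remain on disk next to a ``FAILED`` marker.
    """
    cfg = validate_config(config)
    out = Path(out_dir if out_dir is not None else cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"manifest": {
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seeds": {"top": cfg["seed"], "generator": cfg["generator"]["seed"],
                  "models": cfg["models"]["seed"], "power": cfg["power"]["seed"]},
        "stages": {},
    }}
    stage_name = "setup"
    try:
        # ---- simulate / ingest -------------------------------------------
        stage_name = "simulate"
        t0 = time.perf_counter()
        gen = cfg["generator"]
        if gen.get("input_csv"):
            cohort = read_cohort_csv(gen["input_csv"])
        else:
            traj = MeanTrajectory(**gen["trajectory"])
            frames = []
            for i, (name, params) in enumerate(sorted(cfg["_params"].items())):
                frames.append(
                    simulate_cohort(
                        gen["n_mz"], gen["n_dz"], params, traj,
                        age_mean=gen["age_mean"], age_sd=gen["age_sd"],
                        female_fraction=gen["female_fraction"],
                        seed=gen["seed"] + i, outcome=name,
                    )
                )
            base = frames[0][["family_id", "zygosity", "twin_index", "sex", "age"]]
            for f in frames[1:]:  # share one set of families/covariates
                f[["family_id", "zygosity", "twin_index", "sex", "age"]] = base.values
            cohort = validate_cohort(pd.concat(frames, ignore_index=True))
            cohort = apply_missingness(cohort, gen["missingness"], seed=gen["seed"] + 1000)
        write_cohort_csv(cohort, out / "cohort.csv")
        report["cohort"] = cohort
        _mark(report, "simulate", t0, len(cohort))

        # ---- preprocess ---------------------------------------------------
        stage_name = "preprocess"
        t0 = time.perf_counter()
        prep = cfg["preprocessing"]
        # composites keep the stage means (growth modeling); the twin-model
        # table additionally gets the rank-normal + age/sex transforms,
        # which by construction centre every stage
        composites = preprocess_cohort(cohort, rank_normalize=False, correct_age_sex=False)
        composites.to_csv(out / "composites.csv", index=False)
        processed = preprocess_cohort(
            cohort,
            rank_normalize=prep["rank_normalize"],
            correct_age_sex=prep["correct_age_sex"],
            per_stage_transform=prep["per_stage_transform"],
        )
        processed.to_csv(out / "processed.csv", index=False)
        report["composites"], report["processed"] = composites, processed
        outcomes = sorted(processed["outcome"].unique())
        _mark(report, "preprocess", t0, len(processed))

        # ---- twin descriptives -------------------------------------------
        stage_name = "icc_falconer"
        t0 = time.perf_counter()
        icc = _icc_table(processed, outcomes)
        icc.to_csv(out / "icc_table.csv", index=False)
        fal_rows = []
        for outcome in outcomes:
            for stage in (1, 2, 3, 4):
                est = intraclass_correlation(processed, outcome, stage)
                f = falconer_estimates(est.r_mz, est.r_dz)
                fal_rows.append(
                    {"outcome": outcome, "stage": stage, "r_mz": est.r_mz, "r_dz": est.r_dz,
                     "a2": f.a2, "c2": f.c2, "e2": f.e2}
                )
        falconer = pd.DataFrame(fal_rows)
        falconer.to_csv(out / "falconer.csv", index=False)
        report["icc_table"], report["falconer"] = icc, falconer
        _mark(report, "icc_falconer", t0, len(falconer))

        # ---- ACE fits -----------------------------------------------------
        stage_name = "univariate_ace"
        t0 = time.perf_counter()
        mdl = cfg["models"]
        uni_rows = []
        for outcome in outcomes:
            for stage in mdl["stages"]:
                fit = fit_univariate_ace(processed, stage, outcome,
                                         restarts=mdl["restarts"], seed=mdl["seed"])
                uni_rows.append(
                    {"outcome": outcome, "stage": stage,
                     "a2": fit.components.total("A", 1), "c2": fit.components.total("C", 1),
                     "e2": fit.components.total("E", 1), "loglik": fit.loglik,
                     "converged": fit.converged}
                )
        uni = pd.DataFrame(uni_rows)
        uni.to_csv(out / "univariate_ace.csv", index=False)
        report["univariate_ace"] = uni
        _mark(report, "univariate_ace", t0, len(uni))

        stage_name = "cholesky_ace"
        t0 = time.perf_counter()
        chol_fits = {}
        ssp_rows = []
        for outcome in outcomes:
            fit = fit_cholesky_ace(processed, outcome, mode=mdl["missing_mode"],
                                   restarts=mdl["restarts"], seed=mdl["seed"])
            chol_fits[outcome] = fit
            if mdl["compute_ci"]:
                for comp in ("A", "C", "E"):
                    for stage in (1, 2, 3, 4):
                        for f in list(range(1, stage + 1)) + ["total"]:
                            fit.components.ci[(comp, f, stage)] = likelihood_ci(
                                fit, comp, f, stage, level=mdl["ci_level"]
                            )
            fit.components.to_wide(decimals=2).to_csv(out / f"components_{outcome}.csv")
            for comp in ("A", "C", "E"):
                for stage in (2, 3, 4):
                    ssp_rows.append(
                        {"outcome": outcome, "component": comp, "stage": stage,
                         "stage_specific_proportion": stage_specific_proportion(fit.components, comp, stage)}
                    )
        ssp = pd.DataFrame(ssp_rows)
        ssp.to_csv(out / "stage_specific.csv", index=False)
        report["cholesky_fits"], report["stage_specific"] = chol_fits, ssp
        _mark(report, "cholesky_ace", t0, len(ssp))

        # ---- growth models ------------------------------------------------
        stage_name = "growth"
        t0 = time.perf_counter()
        g_rows, cmp_rows, traj_rows = [], [], []
        for outcome in outcomes:
            sub = composites[composites["outcome"] == outcome]
            uncond = fit_growth(sub, "unconditional")
            piece = fit_growth(sub, "piecewise")
            for fit in (uncond, piece):
                g_rows.append(
                    {"outcome": outcome, "model": fit.model, "gamma_00": fit.gamma_00,
                     "gamma_10": fit.gamma_10, "gamma_20": fit.gamma_20,
                     "se_gamma_10": fit.se[1], "se_gamma_20": fit.se[2] if fit.se.size > 2 else np.nan,
                     "loglik": fit.loglik, "aic": fit.aic, "bic": fit.bic,
                     "n_parameters": fit.n_free_parameters, "n_observations": fit.n_observations}
                )
            comp = compare_growth_models(uncond, piece)
            cmp_rows.append({"outcome": outcome, **{k: v for k, v in comp.items() if k != "preferred"},
                             **{f"preferred_{k}": v for k, v in comp["preferred"].items()}})
            tr = predicted_trajectory(piece)
            tr.insert(0, "outcome", outcome)
            traj_rows.append(tr)
        growth = pd.DataFrame(g_rows)
        growth.to_csv(out / "growth_fits.csv", index=False)
        gcomp = pd.DataFrame(cmp_rows)
        gcomp.to_csv(out / "growth_comparison.csv", index=False)
        traj = pd.concat(traj_rows, ignore_index=True)
        traj.to_csv(out / "predicted_trajectory.csv", index=False)
        report["growth_fits"], report["growth_comparison"], report["trajectory"] = growth, gcomp, traj
        _mark(report, "growth", t0, len(growth))

        # ---- power --------------------------------------------------------
        if cfg["power"]["run"]:
            stage_name = "power"
            t0 = time.perf_counter()
            pw = cfg["power"]
            res = power_heritability(pw["n_mz"], pw["n_dz"], pw["a2"], pw["c2"],
                                     alpha=pw["alpha"], reps=pw["reps"], seed=pw["seed"])
            power_df = pd.DataFrame([{"n_mz": pw["n_mz"], "n_dz": pw["n_dz"], "a2": pw["a2"],
                                      "c2": pw["c2"], "alpha": pw["alpha"], "reps": res.reps,
                                      "power": res.power, "mc_se": res.se}])
            power_df.to_csv(out / "power.csv", index=False)
            report["power"] = power_df
            _mark(report, "power", t0, 1)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage_name}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage '{stage_name}': {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(report["manifest"], fh, indent=2, sort_keys=True)
    return report


def _mark(report, name, t0, n_records):
    dt = time.perf_counter() - t0
    report["manifest"]["stages"][name] = {"seconds": round(dt, 3), "records": n_records}
    log.info("stage %-14s %8.2fs  %d records", name, dt, n_records)
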