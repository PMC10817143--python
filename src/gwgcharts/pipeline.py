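"""End-to-end pipeline: simulate/load -> clean -> describe -> SSD -> impute
-> centiles, with a hash manifest for reproducibility checks.

Every artifact is delimited text (UTF-8, comma separator, '.' decimal);
the manifest lists each output file with its SHA-256 so two runs with the
same configuration and seed can be compared byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .centiles import (CENTILES_DEFAULT, evaluate_centiles, fit_bccg,
                       pool_centile_models)
from .harmonize import (CleaningConfig, apply_eligibility,
                        derive_subject_fields, derive_visit_fields)
from .heterogeneity import DEFAULT_GA_BINS, assign_ga_bin, ssd_table
from .imputation import ImputationSpec, impute_pipeline, rubin_pool
from .report import QUANTILE_FOOTER, describe
from .synthetic import (CohortConfig, default_bmi_reference,
                        default_height_reference, generate_cohort)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("gwgcharts")

CENTILES = CENTILES_DEFAULT


@dataclass
class PipelineConfig:
    """Top-level configuration; inputs are either file paths or the simulator."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    imputation: ImputationSpec = field(default_factory=ImputationSpec)
    subjects_path: str | None = None     # set both to skip simulation
    visits_path: str | None = None
    ssd_min_n: int = 10                  # sensitivity threshold
    fit_centiles: bool = True
    centile_shift: float = 10.0
    centile_mu_df: int = 4
    centile_min_obs: int = 300
    centile_week_grid: tuple[int, int] = (5, 40)
    impute_enabled: bool = True
    seed: int = 0

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = dict(data)
        if "cohort" in kwargs:
            c = dict(kwargs["cohort"])
            if "bmi_category_probs" in c:
                c["bmi_category_probs"] = tuple(c["bmi_category_probs"])
            if "first_visit_week_distribution" in c:
                c["first_visit_week_distribution"] = {
                    int(k): float(v)
                    for k, v in c["first_visit_week_distribution"].items()}
            kwargs["cohort"] = CohortConfig(**c)
        if "cleaning" in kwargs:
            kwargs["cleaning"] = CleaningConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in kwargs["cleaning"].items()})
        if "imputation" in kwargs:
            imp = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in kwargs["imputation"].items()}
            kwargs["imputation"] = ImputationSpec(**imp)
        if "centile_week_grid" in kwargs:
            kwargs["centile_week_grid"] = tuple(kwargs["centile_week_grid"])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Writer:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.files: list[Path] = []

    def csv(self, df: pd.DataFrame, name: str, footer: str | None = None) -> Path:
        path = self.out_dir / name
        with open(path, "w", encoding="utf-8", newline="") as fh:
            df.to_csv(fh, index=False)
            if footer:
                fh.write(footer + "\n")
        self.files.append(path)
        return path

    def text(self, content: str, name: str) -> Path:
        path = self.out_dir / name
        path.write_text(content + "\n", encoding="utf-8")
        self.files.append(path)
        return path


def _age_year_bin(age: float) -> str:
    return str(int(age))


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages; return the manifest (also written to disk).

    Any stage failure raises with the stage name attached so callers can
    abort with a meaningful exit status.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    w = _Writer(out)
    manifest: dict = {"stages": [], "files": {}}
    stage = "setup"
    try:
        h_ref = default_height_reference()
        b_ref = default_bmi_reference()

        # ---- simulate or load -----------------------------------------
        stage = "simulate"
        if config.subjects_path and config.visits_path:
            subjects = pd.read_csv(config.subjects_path)
            visits = pd.read_csv(config.visits_path)
            log.info("loaded %d subjects, %d visits", len(subjects), len(visits))
        else:
            cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
            subjects, visits, truth = generate_cohort(cohort_cfg, h_ref, b_ref)
            w.csv(subjects, "subjects_raw.csv")
            w.csv(visits, "visits_raw.csv")
            w.csv(truth.site_shifts, "truth_site_shifts.csv")
            log.info("simulated %d subjects, %d visits", len(subjects),
                     len(visits))
        manifest["stages"].append("simulate")

        # ---- clean -----------------------------------------------------
        stage = "clean"
        subjects_d = derive_subject_fields(subjects, h_ref, b_ref)
        visits_d = derive_visit_fields(visits, subjects_d)
        subj, vis, ledger = apply_eligibility(subjects_d, visits_d,
                                              config.cleaning)
        w.csv(ledger.to_frame(), "exclusion_ledger.csv")
        w.text(ledger.to_text(), "exclusion_ledger.txt")
        w.csv(subj, "subjects_clean.csv")
        w.csv(vis, "visits_clean.csv")
        log.info("clean: %d -> %d subjects, %d -> %d visits",
                 ledger.subjects_in, ledger.subjects_out,
                 ledger.visits_in, ledger.visits_out)
        manifest["stages"].append("clean")

        # ---- describe --------------------------------------------------
        stage = "describe"
        w.csv(describe(subj, vis, by="site"), "describe_by_site.csv",
              QUANTILE_FOOTER)
        w.csv(describe(subj, vis, by="bmi_category"),
              "describe_by_category.csv", QUANTILE_FOOTER)
        manifest["stages"].append("describe")

        # ---- SSD -------------------------------------------------------
        stage = "ssd"
        cat = subj.set_index("subject_id")["bmi_category"]
        gwg_long = vis.copy()
        gwg_long["bmi_category"] = cat.reindex(gwg_long["subject_id"]).to_numpy()
        gwg_long["site"] = subj.set_index("subject_id")["site"] \
            .reindex(gwg_long["subject_id"]).to_numpy()
        gwg_long["ga_bin"] = [assign_ga_bin(g) for g in gwg_long["ga_weeks"]]
        w.csv(ssd_table(gwg_long, "gwg_kg"), "ssd_gwg.csv")
        w.csv(ssd_table(gwg_long, "gwg_kg", min_n=config.ssd_min_n),
              "ssd_gwg_sensitivity.csv")
        haz_long = subj.copy()
        haz_long["age_bin"] = [_age_year_bin(a) for a in subj["maternal_age_y"]]
        w.csv(ssd_table(haz_long, "haz", bin_col="age_bin"), "ssd_haz.csv")
        manifest["stages"].append("ssd")

        # ---- impute ----------------------------------------------------
        stage = "impute"
        completed = [vis]
        if config.impute_enabled:
            spec = dataclasses.replace(config.imputation, seed=config.seed + 1)
            # a toggled category with no complete first-trimester cases
            # cannot be modelled; skip it rather than abort the run
            lo, hi = spec.window
            complete = set(vis.loc[vis["ga_weeks"].between(lo, hi),
                                   "subject_id"])
            feasible = tuple(
                c for c in spec.categories
                if len(set(cat.index[cat == c]) & complete) >= 3)
            if set(feasible) != set(spec.categories):
                log.info("impute: skipping categories without complete "
                         "cases: %s", sorted(set(spec.categories) - set(feasible)))
                spec = dataclasses.replace(spec, categories=feasible)
            completed, diag = impute_pipeline(subj, vis, spec)
            w.csv(diag, "imputation_diagnostics.csv")
            for k, cd in enumerate(completed, start=1):
                w.csv(cd, f"visits_imp{k}.csv")
            lo, hi = spec.window
            pooled_rows = []
            for category in spec.categories:
                ids = set(cat.index[cat == category])
                Qs, Us = [], []
                for cd in completed:
                    ft = cd[cd["subject_id"].isin(ids)
                            & cd["ga_weeks"].between(lo, hi)]["gwg_kg"].dropna()
                    if len(ft) > 1:
                        Qs.append(ft.mean())
                        Us.append(ft.var(ddof=1) / len(ft))
                if len(Qs) >= 2:
                    est = rubin_pool(Qs, Us)
                    ci = est.confint()
                    pooled_rows.append({
                        "bmi_category": category,
                        "estimand": "mean_first_trimester_gwg_kg",
                        "Qbar": est.Qbar, "Ubar": est.Ubar, "B": est.B,
                        "T": est.T, "df": est.df,
                        "ci_low": ci[0], "ci_high": ci[1]})
            if pooled_rows:
                w.csv(pd.DataFrame(pooled_rows), "pooled_estimates.csv")
        manifest["stages"].append("impute")

        # ---- centiles --------------------------------------------------
        stage = "fit_centiles"
        if config.fit_centiles:
            grid = np.arange(config.centile_week_grid[0],
                             config.centile_week_grid[1] + 1)
            imputed_cats = set(config.imputation.categories) \
                if config.impute_enabled else set()
            for category in sorted(cat.dropna().unique()):
                ids = set(cat.index[cat == category])
                datasets = completed if category in imputed_cats else [vis]
                models = []
                for cd in datasets:
                    d = cd[cd["subject_id"].isin(ids)].dropna(subset=["gwg_kg"])
                    # BCCG support: records at or below -shift cannot enter
                    n_off = int((d["gwg_kg"] <= -config.centile_shift + 0.1).sum())
                    if n_off:
                        log.info("centiles: %s: dropping %d records outside "
                                 "the shifted support", category, n_off)
                        d = d[d["gwg_kg"] > -config.centile_shift + 0.1]
                    if len(d) < config.centile_min_obs:
                        continue
                    models.append(fit_bccg(
                        d["ga_weeks"].to_numpy(float),
                        d["gwg_kg"].to_numpy(float),
                        mu_df=config.centile_mu_df,
                        shift=config.centile_shift))
                if not models:
                    log.info("centiles: skipping %s (too few records)", category)
                    continue
                w.csv(evaluate_centiles(models[0], grid, CENTILES),
                      f"centiles_{category}.csv")
                if len(models) > 1:
                    w.csv(pool_centile_models(models, grid, CENTILES),
                          f"centiles_{category}_pooled.csv")
                model_blob = {
                    "bmi_category": category,
                    "shift": models[0].shift,
                    "deviance": round(models[0].deviance_, 6),
                    "aic": round(models[0].aic_, 6),
                    "edf": models[0].edf_,
                    "converged": bool(models[0].converged_),
                    "mu_coef": [round(float(v), 8) for v in models[0].mu_coef_],
                    "sigma_coef": [round(float(v), 8)
                                   for v in models[0].sigma_coef_],
                    "nu_coef": [round(float(v), 8) for v in models[0].nu_coef_],
                }
                w.text(yaml.safe_dump(model_blob, sort_keys=True).rstrip(),
                       f"centile_model_{category}.yaml")
        manifest["stages"].append("fit_centiles")

        # ---- manifest --------------------------------------------------
        stage = "manifest"
        for path in w.files:
            manifest["files"][path.name] = _sha256(path)
        manifest_path = out / "manifest.json"
        manifest_path.write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n",
            encoding="utf-8")
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
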