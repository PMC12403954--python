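"""Table formats, run configuration and the pipeline runner.

Tables travel as CSV/TSV with headers; models and manifests as JSON (kept
human-diffable so orderings can be audited); configuration as YAML.  Every
randomized stage consumes a child seed derived deterministically from the
master seed and the stage name.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InvalidConfigError, PipelineError, SchemaError
from .model import EventSet

__all__ = [
    "read_biomarker_table",
    "read_clinical_table",
    "write_table",
    "RunConfig",
    "run_pipeline",
    "stage_seed",
]

BIOMARKER_META = ["subject_id", "group", "visit", "age", "sex", "tiv", "scanner"]
CLINICAL_REQUIRED = ["subject_id", "edss"]

_STAGE_TAGS = {"match": 21, "fit": 22, "cv": 23, "simulate": 24}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic child seed for a named pipeline stage (< 2**31)."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _read(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df.to_csv(path, sep=sep, index=isinstance(df.index, pd.Index) and df.index.name is not None)


def read_biomarker_table(path) -> pd.DataFrame:
    """Read and validate a biomarker table (CSV or TSV).

    Requires the metadata columns plus at least one numeric biomarker
    column; rejects duplicate (subject, visit) keys and non-finite
    biomarker values, reporting the offending columns/rows.
    """
    df = _read(path)
    missing = [c for c in BIOMARKER_META if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    if "visit" not in df.columns:
        df["visit"] = "baseline"
    dup = df.duplicated(subset=["subject_id", "visit"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # 1-based + header
        raise SchemaError(f"{path}: duplicate subject-visit rows at file lines {rows}")
    from .preprocess import biomarker_columns

    bios = biomarker_columns(df)
    if not bios:
        raise SchemaError(f"{path}: no biomarker columns found")
    bad_cols = [b for b in bios if not np.isfinite(df[b].to_numpy(dtype=float)).all()]
    if bad_cols:
        raise SchemaError(f"{path}: non-finite biomarker values in columns {bad_cols}")
    return df


def read_clinical_table(path) -> pd.DataFrame:
    df = _read(path)
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    dup = df.duplicated(subset=["subject_id"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()
        raise SchemaError(f"{path}: duplicate subject rows at file lines {rows}")
    return df


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serializable)."""

    biomarker_table: str
    seed: int
    output_dir: str = "sustainz_out"
    clinical_table: str | None = None
    followup_table: str | None = None
    z_levels: tuple[float, ...] = (1.0, 2.0, 3.0)
    z_max: float = 5.0
    sigma: float = 1.0
    c_max: int = 3
    folds: int = 10
    n_starts: int = 25
    cv_n_starts: int | None = None
    mcmc_iters: int = 10_000
    parsimony_delta: float = 5.0
    batch_var: str = "scanner"
    group_var: str = "group"
    adjust_covariates: tuple[str, ...] = ("age", "sex", "tiv")
    zscore_covariates: tuple[str, ...] = ("age", "sex")
    characterize_covariates: tuple[str, ...] = ("age", "sex", "disease_duration")
    hc_label: str = "HC"

    def __post_init__(self):
        if self.seed is None:
            raise InvalidConfigError("seed is mandatory")
        for name in (
            "z_levels",
            "adjust_covariates",
            "zscore_covariates",
            "characterize_covariates",
        ):
            object.__setattr__(self, name, tuple(getattr(self, name)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "seed" not in d:
            raise InvalidConfigError(f"{path}: seed is mandatory")
        cfg = cls(**d)
        for p in (cfg.biomarker_table, cfg.clinical_table, cfg.followup_table):
            if p is not None and not Path(p).exists():
                raise InvalidConfigError(f"referenced file does not exist: {p}")
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def content_hash(self) -> str:
        d = asdict(self)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute preprocess → fit → select → assign → characterize.

    Writes all artifacts plus ``manifest.json`` (config hash, seed,
    version, stage timings) into the output directory, which is returned.
    Any stage failure halts the run with the stage name and cause.
    """
    from .assign import assign_table, longitudinal_stability, subtype_prevalence
    from .characterize import adjusted_group_test, dmt_response, stage_correlations
    from .fit import fit_sustain
    from .preprocess import adjust_batch_covariates, biomarker_columns, compute_zscores, match_controls

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": [],
    }

    def stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                return self_

            def __exit__(self_, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_.t0, 3)
                if exc is not None:
                    raise PipelineError(name, str(exc)) from exc
                manifest["stages"].append(name)

        return _Timer()

    with stage("read"):
        table = read_biomarker_table(config.biomarker_table)
        clinical = read_clinical_table(config.clinical_table) if config.clinical_table else None
        followup = read_biomarker_table(config.followup_table) if config.followup_table else None

    with stage("preprocess"):
        adjusted = adjust_batch_covariates(
            table,
            batch_var=config.batch_var,
            covariates=config.adjust_covariates,
            group_var=config.group_var,
        )
        with open(out / "adjustment.json", "w") as fh:
            json.dump(adjusted.attrs["adjustment"], fh, indent=1)
        write_table(adjusted, out / "adjusted.csv")
        hcs = adjusted[adjusted[config.group_var] == config.hc_label]
        patients = adjusted[adjusted[config.group_var] != config.hc_label]
        matches = match_controls(
            patients, hcs, vars=list(config.zscore_covariates), seed=stage_seed(config.seed, "match")
        )
        write_table(matches, out / "matches.csv")
        matched_hcs = hcs.set_index("subject_id").loc[matches["hc_id"]].reset_index()
        bios = biomarker_columns(adjusted)
        Z = compute_zscores(patients, matched_hcs, bios, covariates=config.zscore_covariates)
        Z.to_csv(out / "zscores.csv")

    with stage("fit"):
        es = EventSet.from_biomarkers(bios, config.z_levels, config.z_max)
        fit = fit_sustain(
            Z,
            es,
            c_max=config.c_max,
            folds=config.folds,
            n_starts=config.n_starts,
            cv_n_starts=config.cv_n_starts,
            mcmc_iters=config.mcmc_iters,
            seed=stage_seed(config.seed, "fit"),
            sigma=config.sigma,
            parsimony_delta=config.parsimony_delta,
        )
        fit.to_json(out / "model.json")
        pd.DataFrame(
            {"C": list(fit.cvic), "cvic": list(fit.cvic.values())}
        ).to_csv(out / "cvic.csv", index=False)
        for c, m in enumerate(fit.selected_models):
            np.savetxt(
                out / f"positional_density_subtype{c}.csv",
                m.positional_density,
                delimiter=",",
            )

    with stage("assign"):
        assignments = assign_table(Z, fit)
        assignments.to_csv(out / "assignments.csv")
        prevalence = subtype_prevalence(assignments)
        prevalence.to_csv(out / "prevalence.csv")
        if followup is not None:
            adj_fu = adjust_batch_covariates(
                pd.concat([table, followup], ignore_index=True),
                batch_var=config.batch_var,
                covariates=config.adjust_covariates,
                group_var=config.group_var,
            )
            fu_rows = adj_fu[adj_fu["visit"] == "followup"]
            fu_rows = fu_rows[fu_rows[config.group_var] != config.hc_label]
            Z_fu = compute_zscores(fu_rows, matched_hcs, bios, covariates=config.zscore_covariates)
            fu_assign = assign_table(Z_fu, fit, visit="followup")
            fu_assign.to_csv(out / "assignments_followup.csv")
            stability = longitudinal_stability(assignments, fu_assign)
            with open(out / "stability.json", "w") as fh:
                json.dump(stability, fh, indent=1)

    if clinical is not None:
        with stage("characterize"):
            merged = clinical.set_index("subject_id").join(assignments, how="inner")
            merged["class"] = merged["ml_subtype"].map(
                lambda c: "NA" if c < 0 else f"subtype_{c}"
            )
            results = {}
            for var in ("edss", "n_relapses"):
                if var in merged.columns:
                    try:
                        res = adjusted_group_test(
                            merged,
                            var,
                            "class",
                            [c for c in config.characterize_covariates if c in merged.columns and c != var],
                        )
                        results[var] = {"H": res["H"], "p": res["p"]}
                        res["posthoc"].to_csv(out / f"posthoc_{var}.csv", index=False)
                    except Exception as exc:
                        warnings.warn(f"group test for {var} skipped: {exc}", stacklevel=2)
            with open(out / "group_tests.json", "w") as fh:
                json.dump(results, fh, indent=1)
            corr_vars = [
                v for v in ("edss", "n_relapses", "cvlt", "bvmt", "pasat", "sdmt", "cowat") if v in merged.columns
            ]
            sub_corrs = []
            for lab, grp in merged[merged["ml_subtype"] >= 0].groupby("ml_subtype"):
                tab = stage_correlations(
                    grp,
                    "weighted_stage",
                    corr_vars,
                    [c for c in config.characterize_covariates if c in merged.columns],
                )
                tab.insert(0, "subtype", lab)
                sub_corrs.append(tab)
            if sub_corrs:
                pd.concat(sub_corrs, ignore_index=True).to_csv(out / "stage_correlations.csv", index=False)
            if {"treatment", "followup_relapses", "followup_edss", "followup_time"} <= set(merged.columns):
                try:
                    resp = dmt_response(clinical, assignments)
                    for ep, tab in resp["rates"].items():
                        tab.to_csv(out / f"dmt_response_{ep}.csv", index=False)
                except Exception as exc:
                    warnings.warn(f"treatment-response analysis skipped: {exc}", stacklevel=2)
    else:
        manifest["notes"] = ["clinical table absent: characterization skipped"]

    manifest["timings_sec"] = timings
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
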