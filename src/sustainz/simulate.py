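"""Synthetic cohorts with known subtype/stage ground truth.

The generator emulates the structure of a multi-scanner volumetric study of
two demyelinating diseases: a healthy-control cohort plus patient cohorts
drawn from ``C`` latent atrophy subtypes.  Each patient carries a true
subtype (drawn from the mixing fractions), a true stage, and raw biomarker
volumes produced by *inverting* the piecewise-linear z-score model: the
expected z at the patient's stage is converted back to a raw volume by
subtracting ``z * noise_sd`` from the healthy prediction (atrophy lowers
volume), on top of scanner batch offsets, age/sex/TIV covariate effects and
Gaussian measurement noise.  Stage-linked clinical outcomes (EDSS on the
half-point grid, relapse counts, time-to-progression with subtype-specific
hazards) and follow-up scans with non-negative stage advancement complete
the picture.

Raw volumes are on an arbitrary but realistic scale (ml; cord area in mm²);
the downstream pipeline is invariant to this choice after z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidConfigError
from .model import EventSet, is_valid_ordering, stage_z_matrix

__all__ = [
    "ClinicalModel",
    "SimConfig",
    "default_orderings",
    "generate_hc_cohort",
    "generate_patient_cohort",
    "generate_clinical",
    "generate_followup",
]

#: default biomarker panel: global/regional brain volumes (ml) plus the mean
#: upper cervical cord area (mm²)
DEFAULT_BIOMARKERS = (
    "cortical_gm",
    "subcortical_gm",
    "cerebral_wm",
    "cerebellar_gm",
    "cerebellar_wm",
    "brainstem",
    "hippocampus",
    "mucca",
)

_DEFAULT_BASELINES = {
    "cortical_gm": 470.0,
    "subcortical_gm": 58.0,
    "cerebral_wm": 450.0,
    "cerebellar_gm": 102.0,
    "cerebellar_wm": 28.0,
    "brainstem": 22.0,
    "hippocampus": 8.2,
    "mucca": 72.0,
}

# independent RNG stream tags per generator function
_STREAM = {"hc": 11, "patients": 12, "clinical": 13, "followup": 14}


@dataclass
class ClinicalModel:
    """Coefficients linking true stage/subtype to clinical outcomes.

    The stage scale is the event count (0..E); hazards are per month.
    """

    edss_intercept: float = 1.5
    edss_stage_slope: float = 0.12
    edss_noise_sd: float = 1.0
    relapse_rates: tuple[float, ...] = (1.2, 2.4)  # Poisson mean per subtype
    hazard_base: float = 0.008  # progression hazard at stage 0, reference subtype
    hazard_subtype_hr: tuple[float, ...] = (1.0, 2.0)
    hazard_stage_hr: float = 1.02  # multiplicative per stage
    censor_time: float = 60.0  # administrative censoring, months
    followup_relapse_rate_per_year: tuple[float, ...] = (0.25, 0.6)

    def validate(self, n_subtypes: int):
        if len(self.relapse_rates) != n_subtypes or len(self.hazard_subtype_hr) != n_subtypes:
            raise InvalidConfigError("clinical_model rates must have one entry per subtype")
        if min(self.relapse_rates) < 0 or self.hazard_base < 0 or min(self.hazard_subtype_hr) < 0:
            raise InvalidConfigError("rates and hazards must be non-negative")
        if min(self.followup_relapse_rate_per_year) < 0:
            raise InvalidConfigError("rates and hazards must be non-negative")
        if self.edss_noise_sd < 0:
            raise InvalidConfigError("edss_noise_sd must be non-negative")


def default_orderings(event_set: EventSet, n_subtypes: int, seed: int = 0) -> list[np.ndarray]:
    """Well-separated ground-truth orderings.

    Subtypes are region-sequential: each biomarker runs through its full
    threshold ladder before the next region begins.  Subtype 0 follows the
    panel order ("cortical-first"), subtype 1 the reversed panel order
    ("cord-first"); further subtypes progress from a rotated starting
    region.  This makes the latent trajectories strongly distinct from the
    earliest stages on, the regime the recovery experiments are meant to
    probe.
    """
    B = event_set.n_biomarkers
    levels = [len(l) for l in event_set.z_levels]
    if len(set(levels)) != 1:
        from .model import random_ordering

        rng = np.random.default_rng(seed)
        return [random_ordering(event_set, rng) for _ in range(n_subtypes)]
    L = levels[0]
    starts = np.arange(B) * L
    out = []
    for c in range(n_subtypes):
        if c == 0:
            order_b = np.arange(B)
        elif c == 1:
            order_b = np.arange(B)[::-1]
        else:
            order_b = np.roll(np.arange(B), -(B // n_subtypes) * (c - 1) - 1)
        out.append(np.concatenate([np.arange(s, s + L) for s in starts[order_b]]))
    return out


@dataclass
class SimConfig:
    """Configuration of a synthetic study; the ground truth of the cohort.

    Scalar covariate/batch effects apply to every biomarker after scaling by
    that biomarker's baseline volume, so effect sizes are comparable across
    structures of very different size.
    """

    n_hc: int = 700  # controls outnumber patients, as in the emulated study
    n_patients: int = 600
    biomarkers: tuple[str, ...] = DEFAULT_BIOMARKERS
    z_levels: tuple[float, ...] = (1.0, 2.0, 3.0)
    z_max: float = 5.0
    n_subtypes: int = 2
    orderings: list | None = None  # defaults to default_orderings(...)
    fractions: tuple[float, ...] = (0.6, 0.4)
    #: probability over true stages 0..E; None = uniform on 1..E
    stage_distribution: np.ndarray | None = None
    #: scanner -> additive offset as a fraction of each biomarker's baseline
    batch_offsets: dict = field(default_factory=lambda: {"scanner_A": 0.0, "scanner_B": 0.01, "scanner_C": -0.008})
    age_slope: float = -0.002  # fraction of baseline per year
    sex_offset: float = 0.06  # male minus female, fraction of baseline
    tiv_slope: float = 0.0004  # fraction of baseline per ml TIV
    noise_sd: float = 0.02  # residual SD, fraction of baseline
    clinical_model: ClinicalModel = field(default_factory=ClinicalModel)
    followup_stage_increment_mean: float = 2.0  # Poisson mean of stage advance
    followup_years: float = 2.0
    patient_group: str = "MS"
    female_fraction: float = 0.7
    age_range: tuple[float, float] = (18.0, 65.0)
    tiv_mean: float = 1450.0
    tiv_sd: float = 110.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    # -- derived objects -------------------------------------------------
    @property
    def event_set(self) -> EventSet:
        return EventSet.from_biomarkers(self.biomarkers, self.z_levels, self.z_max)

    @property
    def baselines(self) -> np.ndarray:
        return np.array([_DEFAULT_BASELINES.get(b, 100.0) for b in self.biomarkers])

    def resolved_orderings(self) -> list[np.ndarray]:
        if self.orderings is None:
            return default_orderings(self.event_set, self.n_subtypes, self.seed)
        return [np.asarray(o, dtype=int) for o in self.orderings]

    def resolved_stage_distribution(self) -> np.ndarray:
        E = self.event_set.n_events
        if self.stage_distribution is None:
            p = np.zeros(E + 1)
            p[1:] = 1.0 / E
            return p
        p = np.asarray(self.stage_distribution, dtype=float)
        return p

    def validate(self):
        if self.n_hc < 1 or self.n_patients < 1:
            raise InvalidConfigError("cohort sizes must be positive")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be positive")
        f = np.asarray(self.fractions, dtype=float)
        if len(f) != self.n_subtypes or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise InvalidConfigError("fractions must be non-negative, one per subtype, summing to 1")
        es = self.event_set
        for o in self.resolved_orderings():
            if not is_valid_ordering(es, o):
                raise InvalidConfigError(
                    "ground-truth ordering violates within-biomarker threshold order"
                )
        if len(self.resolved_orderings()) != self.n_subtypes:
            raise InvalidConfigError("one ordering per subtype is required")
        p = self.resolved_stage_distribution()
        if len(p) != es.n_events + 1 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise InvalidConfigError("stage_distribution must be a distribution over 0..E")
        self.clinical_model.validate(self.n_subtypes)
        if self.followup_stage_increment_mean < 0:
            raise InvalidConfigError("followup stage increments must be non-negative")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise InvalidConfigError("female_fraction must lie in [0, 1]")

    # -- (de)serialization ------------------------------------------------
    def to_yaml(self, path):
        d = asdict(self)
        d["orderings"] = [list(map(int, o)) for o in self.resolved_orderings()]
        sd = self.stage_distribution
        d["stage_distribution"] = None if sd is None else [float(x) for x in sd]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "clinical_model" in d and isinstance(d["clinical_model"], dict):
            cm = d["clinical_model"]
            for key in ("relapse_rates", "hazard_subtype_hr", "followup_relapse_rate_per_year"):
                if key in cm:
                    cm[key] = tuple(cm[key])
            d["clinical_model"] = ClinicalModel(**cm)
        for key in ("biomarkers", "z_levels", "fractions", "age_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAM[stream]])


def _covariates(config: SimConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = config.age_range
    scanners = sorted(config.batch_offsets)
    return pd.DataFrame(
        {
            "age": rng.uniform(lo, hi, n),
            "sex": (rng.random(n) >= config.female_fraction).astype(int),  # 1 = male
            "tiv": rng.normal(config.tiv_mean, config.tiv_sd, n),
            "scanner": np.array(scanners)[rng.integers(0, len(scanners), n)],
        }
    )


def _expected_volumes(config: SimConfig, cov: pd.DataFrame) -> np.ndarray:
    """Healthy expected volume for each subject x biomarker.

    Covariate effects are centered at the middle of their generating ranges
    so the baseline constant is the expected volume of an average subject.
    """
    base = config.baselines
    lo, hi = config.age_range
    age_c = cov["age"].to_numpy() - 0.5 * (lo + hi)
    sex = cov["sex"].to_numpy()
    tiv_c = cov["tiv"].to_numpy() - config.tiv_mean
    offsets = np.array([config.batch_offsets[s] for s in cov["scanner"]])
    eff = (
        config.age_slope * age_c[:, None]
        + config.sex_offset * sex[:, None]
        + config.tiv_slope * tiv_c[:, None]
        + offsets[:, None]
    )
    return base[None, :] * (1.0 + eff)


def _assemble(config: SimConfig, ids, group, cov, volumes, visit="baseline") -> pd.DataFrame:
    df = pd.DataFrame({"subject_id": ids, "group": group, "visit": visit})
    df = pd.concat([df, cov.reset_index(drop=True)], axis=1)
    for j, b in enumerate(config.biomarkers):
        df[b] = volumes[:, j]
    return df


def generate_hc_cohort(config: SimConfig) -> pd.DataFrame:
    """Healthy-control biomarker table (one row per subject)."""
    config.validate()
    rng = _rng(config, "hc")
    n = config.n_hc
    cov = _covariates(config, n, rng)
    noise = rng.normal(0.0, 1.0, (n, len(config.biomarkers))) * (
        config.noise_sd * config.baselines
    )
    volumes = _expected_volumes(config, cov) + noise
    ids = [f"HC{i:05d}" for i in range(n)]
    return _assemble(config, ids, "HC", cov, volumes)


def generate_patient_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient biomarker table plus the ground-truth table.

    Each patient draws a subtype from the mixing fractions and a stage from
    the stage distribution; expected z-scores come from that subtype's
    trajectory at that stage, and are mapped to raw volumes through the
    healthy prediction and the residual SD.
    """
    config.validate()
    rng = _rng(config, "patients")
    n = config.n_patients
    es = config.event_set
    orderings = config.resolved_orderings()
    G = [stage_z_matrix(es, o) for o in orderings]  # (B, E+1) each

    subtype = rng.choice(config.n_subtypes, size=n, p=np.asarray(config.fractions, float))
    stages = rng.choice(es.n_events + 1, size=n, p=config.resolved_stage_distribution())
    cov = _covariates(config, n, rng)
    expected = _expected_volumes(config, cov)
    scale = config.noise_sd * config.baselines  # volume units per z unit
    z_true = np.stack([G[c][:, k] for c, k in zip(subtype, stages)])
    noise = rng.normal(0.0, 1.0, (n, es.n_biomarkers)) * scale
    volumes = expected - z_true * scale + noise

    ids = [f"P{i:05d}" for i in range(n)]
    table = _assemble(config, ids, config.patient_group, cov, volumes)
    truth = pd.DataFrame(
        {
            "subject_id": ids,
            "true_subtype": subtype,
            "true_stage": stages,
            "scanner": cov["scanner"].to_numpy(),
            "age": cov["age"].to_numpy(),
            "sex": cov["sex"].to_numpy(),
            "tiv": cov["tiv"].to_numpy(),
        }
    )
    return table, truth


def _edss_grid(x: np.ndarray) -> np.ndarray:
    return np.clip(np.round(x * 2.0) / 2.0, 0.0, 10.0)


def generate_clinical(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Stage-/subtype-linked clinical outcomes for the generated patients.

    EDSS is a monotone function of true stage plus ordinal noise on the
    half-point grid; relapse counts are Poisson with subtype-specific
    rates; follow-up time and the disability-progression event follow an
    exponential model with subtype- and stage-dependent hazard plus
    administrative censoring.  Follow-up EDSS is generated consistently
    with the progression flag under the threshold rule (>= 1.0 step for
    baseline <= 5.5, >= 0.5 above).
    """
    if len(truth) == 0:
        raise InvalidConfigError("ground-truth table is empty")
    config.validate()
    cm = config.clinical_model
    rng = _rng(config, "clinical")
    n = len(truth)
    stage = truth["true_stage"].to_numpy()
    subtype = truth["true_subtype"].to_numpy()

    edss = _edss_grid(
        cm.edss_intercept + cm.edss_stage_slope * stage + rng.normal(0, cm.edss_noise_sd, n)
    )
    n_relapses = rng.poisson(np.asarray(cm.relapse_rates)[subtype])

    hazard = cm.hazard_base * np.asarray(cm.hazard_subtype_hr)[subtype] * cm.hazard_stage_hr**stage
    draws = rng.exponential(1.0, n)  # unit-rate draws scaled by 1/hazard
    event_time = np.where(hazard > 0, draws / np.where(hazard > 0, hazard, 1.0), np.inf)
    followup_time = np.minimum(event_time, cm.censor_time)
    progression = (event_time <= cm.censor_time).astype(int)

    step = np.where(edss > 5.5, 0.5, 1.0)
    raise_amt = step + rng.choice([0.0, 0.5], n)
    stay_amt = np.where(step == 1.0, rng.choice([0.0, 0.5], n), 0.0)
    followup_edss = _edss_grid(np.where(progression == 1, edss + raise_amt, edss + stay_amt))
    # clipping at 10 cannot cancel a progression step (grid tops out at 10)
    followup_edss = np.where(
        (progression == 1) & (followup_edss < edss + step), np.minimum(edss + step, 10.0), followup_edss
    )

    fu_rel_rate = np.asarray(cm.followup_relapse_rate_per_year)[subtype] * followup_time / 12.0
    followup_relapses = rng.poisson(fu_rel_rate)

    disease_duration = np.round(rng.lognormal(3.2, 0.8, n), 1)
    education = np.clip(np.round(rng.normal(13, 3, n)), 6, 22)
    cognitive = {
        "cvlt": 85.0 - 0.8 * stage,
        "bvmt": 38.0 - 0.35 * stage,
        "pasat": 50.0 - 0.4 * stage,
        "sdmt": 50.0 - 0.45 * stage,
        "cowat": 24.0 - 0.25 * stage,
    }
    treatment = np.where(rng.random(n) < 0.55, "DMT", "immunosuppressant")

    out = pd.DataFrame(
        {
            "subject_id": truth["subject_id"].to_numpy(),
            "age": truth["age"].to_numpy(),
            "sex": truth["sex"].to_numpy(),
            "education": education,
            "disease_duration": disease_duration,
            "n_relapses": n_relapses,
            "edss": edss,
            "followup_time": np.round(followup_time, 2),
            "progression_event": progression,
            "followup_edss": followup_edss,
            "followup_relapses": followup_relapses,
            "treatment": treatment,
        }
    )
    for name, mean in cognitive.items():
        out[name] = np.round(mean + rng.normal(0, 6.0, n), 0)
    return out


def generate_followup(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Follow-up biomarker table: same subtype, stage advanced by a
    non-negative (Poisson) increment, volumes regenerated at the new stage."""
    config.validate()
    rng = _rng(config, "followup")
    n = len(truth)
    es = config.event_set
    orderings = config.resolved_orderings()
    G = [stage_z_matrix(es, o) for o in orderings]

    increment = rng.poisson(config.followup_stage_increment_mean, n)
    new_stage = np.minimum(truth["true_stage"].to_numpy() + increment, es.n_events)
    subtype = truth["true_subtype"].to_numpy()

    cov = pd.DataFrame(
        {
            "age": truth["age"].to_numpy() + config.followup_years,
            "sex": truth["sex"].to_numpy(),
            "tiv": truth["tiv"].to_numpy(),
            "scanner": truth["scanner"].to_numpy(),
        }
    )
    expected = _expected_volumes(config, cov)
    scale = config.noise_sd * config.baselines
    z_true = np.stack([G[c][:, k] for c, k in zip(subtype, new_stage)])
    noise = rng.normal(0.0, 1.0, (n, es.n_biomarkers)) * scale
    volumes = expected - z_true * scale + noise

    table = _assemble(
        config, truth["subject_id"].to_numpy(), config.patient_group, cov, volumes, visit="followup"
    )
    table["true_followup_stage"] = new_stage
    return table
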