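"""Harmonization and atrophy z-scoring of raw biomarker tables.

Three steps take raw volumes to model-ready z-scores:

1. :func:`adjust_batch_covariates` — per biomarker, an OLS fit with scanner
   (batch) indicators, covariates (age, sex, TIV) and diagnostic-group
   indicators; the fitted batch and covariate contributions are removed
   while the group contribution is retained, so genuine disease effects
   survive harmonization.
2. :func:`match_controls` — greedy 1:1 nearest-neighbour matching of
   controls to patients on standardized age with exact sex match.
3. :func:`compute_zscores` — per biomarker, an OLS model ``value ~ age +
   sex`` fitted on the matched controls; z = (observed − predicted) /
   SD(control residuals), sign-flipped so that *positive z means atrophy*
   (smaller volume than expected).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError

__all__ = [
    "adjust_batch_covariates",
    "match_controls",
    "compute_zscores",
    "biomarker_columns",
]

_META_COLS = {"subject_id", "group", "visit", "age", "sex", "tiv", "scanner"}


def biomarker_columns(table: pd.DataFrame) -> list[str]:
    """Numeric columns that are not covariates/identifiers."""
    out = []
    for c in table.columns:
        if c in _META_COLS or c.startswith("true_"):
            continue
        if pd.api.types.is_numeric_dtype(table[c]):
            out.append(c)
    return out


def _dummies(series: pd.Series, prefix: str) -> tuple[np.ndarray, list[str]]:
    levels = sorted(pd.unique(series.astype(str)))
    cols = [f"{prefix}[{l}]" for l in levels[1:]]  # first level is reference
    X = np.column_stack([(series.astype(str) == l).astype(float) for l in levels[1:]]) if len(levels) > 1 else np.empty((len(series), 0))
    return X, cols


def _name_collinear(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedy QR-style scan for columns adding no rank."""
    bad, kept = [], np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            bad.append(name)
        else:
            kept = cand
    return bad


def adjust_batch_covariates(
    table: pd.DataFrame,
    batch_var: str = "scanner",
    covariates: Sequence[str] = ("age", "sex", "tiv"),
    group_var: str = "group",
    biomarkers: Sequence[str] | None = None,
    allow_confounded: bool = False,
) -> pd.DataFrame:
    """Remove batch and covariate contributions, preserving group effects.

    Covariates are centered at their sample means before fitting, so the
    adjusted values are re-centered at the covariate means and the
    reference-batch level.  If diagnostic group is confounded with batch
    (the combined design is rank-deficient) a
    :class:`~sustainz.errors.DegenerateDataError` names the collinear
    columns unless ``allow_confounded`` drops the group term instead.
    """
    if biomarkers is None:
        biomarkers = biomarker_columns(table)
    counts = table[batch_var].value_counts()
    if (counts < 2).any():
        small = list(counts.index[counts < 2])
        raise DegenerateDataError(f"batches with fewer than 2 subjects: {small}")

    Xb, names_b = _dummies(table[batch_var], batch_var)
    Xg, names_g = _dummies(table[group_var], group_var)
    cov = table.loc[:, list(covariates)].astype(float)
    if cov.isna().any().any():
        raise DegenerateDataError("missing covariate values in rows entering adjustment")
    Xc = cov.to_numpy() - cov.to_numpy().mean(axis=0)
    names_c = list(covariates)
    # zero-variance covariates carry no adjustable contribution
    keep_c = [j for j in range(Xc.shape[1]) if np.ptp(Xc[:, j]) > 0]
    Xc, names_c = Xc[:, keep_c], [names_c[j] for j in keep_c]

    ones = np.ones((len(table), 1))
    X = np.column_stack([ones, Xb, Xc, Xg])
    names = ["Intercept"] + names_b + names_c + names_g
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _name_collinear(X, names)
        if allow_confounded and all(b.startswith(group_var) for b in bad):
            keep = [j for j, n in enumerate(names) if n not in bad]
            X, names = X[:, keep], [names[j] for j in keep]
            names_g = [n for n in names_g if n in names]
            warnings.warn(
                f"group term confounded with batch; dropped columns {bad} "
                "(allow_confounded=True)",
                stacklevel=2,
            )
        else:
            raise DegenerateDataError(
                f"rank-deficient adjustment design; collinear columns: {bad} "
                "(group confounded with batch?)"
            )

    Y = table.loc[:, list(biomarkers)].astype(float).to_numpy()
    if not np.all(np.isfinite(Y)):
        raise DegenerateDataError("non-finite biomarker values")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)

    # remove batch + covariate contributions only
    nb, nc = len(names_b), len(names_c)
    removed = X[:, 1 : 1 + nb + nc] @ beta[1 : 1 + nb + nc]
    out = table.copy()
    out.loc[:, list(biomarkers)] = Y - removed
    out.attrs["adjustment"] = {
        "columns": names,
        "coefficients": {b: beta[:, j].tolist() for j, b in enumerate(biomarkers)},
    }
    return out


def match_controls(
    patients: pd.DataFrame,
    hcs: pd.DataFrame,
    vars: Sequence[str] = ("age", "sex"),
    ratio: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Greedy 1:``ratio`` nearest-neighbour control matching.

    Continuous variables are standardized (pooled SD); ``sex`` (if listed)
    is matched exactly.  Patients are visited in a seed-randomized order
    and controls are used without replacement.  Returns a frame with
    columns ``patient_id`` and ``hc_id``.
    """
    exact = [v for v in vars if v == "sex"]
    cont = [v for v in vars if v != "sex"]
    pooled = pd.concat([patients[cont], hcs[cont]], axis=0)
    sd = pooled.std(ddof=1).replace(0.0, 1.0)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))

    available = hcs.reset_index(drop=True)
    avail_mask = np.ones(len(available), dtype=bool)
    hc_std = (available[cont] / sd).to_numpy()
    pairs, unmatched = [], []
    pat = patients.reset_index(drop=True)
    pat_std = (pat[cont] / sd).to_numpy()
    for i in order:
        ok = avail_mask.copy()
        for v in exact:
            ok &= (available[v].to_numpy() == pat.loc[i, v])
        idx = np.flatnonzero(ok)
        if len(idx) < ratio:
            unmatched.append(pat.loc[i, "subject_id"])
            continue
        d = np.linalg.norm(hc_std[idx] - pat_std[i], axis=1)
        chosen = idx[np.argsort(d, kind="stable")[:ratio]]
        avail_mask[chosen] = False
        for j in chosen:
            pairs.append((pat.loc[i, "subject_id"], available.loc[j, "subject_id"]))
    if unmatched:
        raise DegenerateDataError(
            f"insufficient controls to match patients: {sorted(unmatched)}"
        )
    out = pd.DataFrame(pairs, columns=["patient_id", "hc_id"])
    return out.sort_values("patient_id", kind="stable").reset_index(drop=True)


def compute_zscores(
    patients: pd.DataFrame,
    matched_hcs: pd.DataFrame,
    biomarkers: Sequence[str] | None = None,
    covariates: Sequence[str] = ("age", "sex"),
    flip_sign: bool = True,
) -> pd.DataFrame:
    """Atrophy z-scores of patients relative to the matched controls.

    Per biomarker an OLS model ``value ~ covariates`` is fitted on the
    matched controls; the patient z-score is the standardized residual
    from that model (control residual SD, df = n − p), sign-flipped so
    atrophy (volume below prediction) is positive.

    Returns a frame indexed by ``subject_id`` with one column per
    biomarker.
    """
    if len(matched_hcs) == 0:
        raise DegenerateDataError("matched control set is empty")
    if biomarkers is None:
        biomarkers = biomarker_columns(patients)

    Xh = np.column_stack(
        [np.ones(len(matched_hcs))] + [matched_hcs[c].astype(float).to_numpy() for c in covariates]
    )
    Xp = np.column_stack(
        [np.ones(len(patients))] + [patients[c].astype(float).to_numpy() for c in covariates]
    )
    if len(matched_hcs) <= Xh.shape[1]:
        raise DegenerateDataError("too few matched controls for the covariate model")

    Yh = matched_hcs.loc[:, list(biomarkers)].astype(float).to_numpy()
    Yp = patients.loc[:, list(biomarkers)].astype(float).to_numpy()
    beta, *_ = np.linalg.lstsq(Xh, Yh, rcond=None)
    resid = Yh - Xh @ beta
    dof = len(matched_hcs) - Xh.shape[1]
    sd = np.sqrt((resid**2).sum(axis=0) / dof)
    floor = 1e-8 * np.maximum(1.0, np.abs(Yh).mean(axis=0))
    if np.any(sd <= floor):
        bad = [b for b, s, f in zip(biomarkers, sd, floor) if s <= f]
        raise DegenerateDataError(f"zero control residual SD for biomarkers: {bad}")

    z = (Yp - Xp @ beta) / sd
    if flip_sign:
        z = -z
    return pd.DataFrame(z, index=pd.Index(patients["subject_id"], name="subject_id"), columns=list(biomarkers))
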