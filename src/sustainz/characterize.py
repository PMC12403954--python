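"""Clinical and MRI characterization of subtypes and stages.

Rank-based group comparisons (Kruskal–Wallis with Dunn post-hoc),
categorical tests (chi-squared with a Fisher fallback for sparse 2×2
tables), covariate-adjusted Spearman correlations of stage with clinical
variables, Cox proportional-hazards models (univariate, multivariate and
stepwise-backward), one-vs-all regional contrasts adjusted for stage, and
treatment-response contingency analyses.  Covariate adjustment for the
rank-based procedures is by linear-model residualization before ranking.

False-discovery-rate control is Benjamini–Hochberg throughout; each
function applies it within one explicit comparison family (the pairwise
contrasts of one variable, or one variable family within a stratum) and
reports both raw and adjusted p-values.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InvalidConfigError

__all__ = [
    "flag_edss_progression",
    "flag_spms_conversion",
    "benjamini_hochberg",
    "dunn_test",
    "adjusted_group_test",
    "categorical_test",
    "stage_correlations",
    "cox_models",
    "one_vs_all_contrast",
    "dmt_response",
]

_EDSS_GRID_TOL = 1e-9


def _check_edss(x):
    x = np.asarray(x, dtype=float)
    on_grid = np.abs(x * 2 - np.round(x * 2)) < _EDSS_GRID_TOL
    ok = (x >= 0) & (x <= 10) & on_grid
    if not np.all(ok | np.isnan(x)):
        raise InvalidConfigError("EDSS values must lie on the 0-10 half-point grid")
    return x


def flag_edss_progression(baseline_edss, followup_edss):
    """Disability progression: Δ ≥ 1.0 if baseline ≤ 5.5, else Δ ≥ 0.5.

    Missing follow-up yields a missing result (pd.NA), never False.
    Accepts scalars or aligned arrays.
    """
    scalar = np.ndim(baseline_edss) == 0 and np.ndim(followup_edss) == 0
    b = np.atleast_1d(_check_edss(baseline_edss))
    f = np.atleast_1d(_check_edss(followup_edss))
    delta = f - b
    prog = np.where(b <= 5.5, delta >= 1.0, delta >= 0.5)
    result = pd.array(prog, dtype="boolean")
    result[np.isnan(b) | np.isnan(f)] = pd.NA
    return result[0] if scalar else result


def flag_spms_conversion(
    records: pd.DataFrame,
    min_sustained_months: float = 6.0,
    min_edss: float = 4.0,
):
    """Conversion to secondary-progressive disease from a visit timeline.

    ``records`` holds one subject's longitudinal visits with columns
    ``months`` (from baseline), ``edss`` and ``relapse`` (0/1, a relapse
    since the previous visit).  Conversion requires a disability
    progression (per :func:`flag_edss_progression` vs. baseline) sustained
    for at least ``min_sustained_months``, relapse-free over the sustained
    window, reaching EDSS ≥ ``min_edss``.  Returns pd.NA when follow-up is
    shorter than the sustained window.
    """
    rec = records.sort_values("months").reset_index(drop=True)
    if len(rec) < 2:
        return pd.NA
    if rec["months"].iloc[-1] - rec["months"].iloc[0] < min_sustained_months:
        return pd.NA
    base = rec["edss"].iloc[0]
    for i in range(1, len(rec)):
        if not bool(flag_edss_progression(base, rec["edss"].iloc[i])):
            continue
        start = rec["months"].iloc[i]
        window = rec[rec["months"] >= start]
        sustained = window[window["months"] <= start + min_sustained_months]
        horizon = rec["months"].iloc[-1] - start
        if horizon < min_sustained_months:
            continue
        held = (
            bool((sustained["edss"] >= min_edss).all())
            and bool(
                flag_edss_progression(base, float(sustained["edss"].min()))
            )
            and not bool(sustained["relapse"].iloc[1:].any() or rec["relapse"].iloc[i])
        )
        if held:
            return True
    return False


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidConfigError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None or covariates.shape[1] == 0:
        return y - y.mean()
    X = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def dunn_test(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's rank-based pairwise post-hoc test with tie correction.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T/(12(N−1))) (1/n_i + 1/n_j))
    with T = Σ(t³ − t) over tied groups; BH adjustment across all pairs.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ranks = stats.rankdata(values)
    N = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    T = float(((tie_counts**3) - tie_counts).sum())
    var_term = N * (N + 1) / 12.0 - T / (12.0 * (N - 1))
    labels = pd.unique(groups)
    rows = []
    for a, b in combinations(labels, 2):
        ra, rb = ranks[groups == a], ranks[groups == b]
        se = np.sqrt(var_term * (1.0 / len(ra) + 1.0 / len(rb)))
        z = (ra.mean() - rb.mean()) / se
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": 2 * stats.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    out["p_fdr"] = benjamini_hochberg(out["p_raw"].to_numpy())
    return out


def adjusted_group_test(
    data: pd.DataFrame,
    variable: str,
    group_var: str,
    covariates: Sequence[str] = (),
) -> dict:
    """Covariate-adjusted Kruskal–Wallis with Dunn post-hoc.

    The variable is residualized on the covariates (OLS) before ranking;
    post-hoc pairwise Dunn tests carry raw and BH-adjusted p-values (one
    family = all pairwise contrasts of this variable).
    """
    cols = [variable, group_var, *covariates]
    d = data.loc[:, cols].dropna()
    counts = d[group_var].value_counts()
    if len(counts) < 2 or (counts < 3).any():
        raise DegenerateDataError("need >= 2 groups with >= 3 subjects each")
    y = d[variable].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateDataError(f"variable {variable!r} is constant")
    cov = d.loc[:, list(covariates)].to_numpy(dtype=float) if covariates else None
    resid = _residualize(y, cov)
    groups = d[group_var].to_numpy()
    samples = [resid[groups == g] for g in pd.unique(groups)]
    H, p = stats.kruskal(*samples)
    posthoc = dunn_test(resid, groups)
    return {"H": float(H), "p": float(p), "posthoc": posthoc, "n": len(d)}


def categorical_test(table, min_expected: float = 5.0, method: str = "auto") -> dict:
    """Chi-squared test of a contingency table, Fisher fallback for 2×2.

    ``method`` is ``"auto"`` (chi-squared, switching to Fisher's exact for
    a 2×2 table with any expected cell below ``min_expected``),
    ``"fisher"`` or ``"midp"`` (Fisher mid-p, 2×2 only).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise InvalidConfigError("contingency table must be at least 2x2")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        if t.shape == (2, 2) and method in ("auto", "fisher", "midp"):
            # an empty outcome column carries no evidence of association
            return {"method": "fisher", "statistic": float("nan"), "p": 1.0}
        raise DegenerateDataError("contingency table has an empty margin")
    chi2, p_chi, dof, expected = stats.chi2_contingency(t, correction=False)
    if method == "auto":
        use_fisher = t.shape == (2, 2) and np.any(expected < min_expected)
        method = "fisher" if use_fisher else "chi2"
    if method == "chi2":
        return {"method": "chi2", "statistic": float(chi2), "p": float(p_chi), "dof": int(dof)}
    if t.shape != (2, 2):
        raise InvalidConfigError("Fisher's exact test requires a 2x2 table")
    odds, p = stats.fisher_exact(t)
    if method == "fisher":
        return {"method": "fisher", "statistic": float(odds), "p": float(p)}
    if method == "midp":
        ti = t.astype(int)
        N, K, n, x = int(ti.sum()), int(ti[0].sum()), int(ti[:, 0].sum()), int(ti[0, 0])
        rv = stats.hypergeom(N, K, n)
        support = np.arange(max(0, K + n - N), min(K, n) + 1)
        pmf = rv.pmf(support)
        p_obs = rv.pmf(x)
        p_mid = float(pmf[pmf <= p_obs * (1 + 1e-12)].sum() - 0.5 * p_obs)
        return {"method": "midp", "statistic": float(odds), "p": p_mid}
    raise InvalidConfigError(f"unknown method {method!r}")


def stage_correlations(
    data: pd.DataFrame,
    stage_var: str,
    variables: Sequence[str],
    covariates: Sequence[str] = (),
    min_n: int = 10,
) -> pd.DataFrame:
    """Partial Spearman correlations of stage with clinical variables.

    Both stage and each variable are residualized on the covariates before
    ranking; BH adjustment runs across the variable family.  Variables
    with fewer than ``min_n`` complete pairs or no variance yield missing
    results with a warning.
    """
    rows = []
    for v in variables:
        cols = [stage_var, v, *[c for c in covariates if c != v]]
        d = data.loc[:, cols].dropna()
        if len(d) < min_n:
            warnings.warn(f"{v}: fewer than {min_n} complete observations", stacklevel=2)
            rows.append({"variable": v, "n": len(d), "rho": np.nan, "p_raw": np.nan})
            continue
        y1 = d[stage_var].to_numpy(dtype=float)
        y2 = d[v].to_numpy(dtype=float)
        if np.ptp(y1) == 0 or np.ptp(y2) == 0:
            warnings.warn(f"{v}: constant input, correlation undefined", stacklevel=2)
            rows.append({"variable": v, "n": len(d), "rho": np.nan, "p_raw": np.nan})
            continue
        cov_cols = [c for c in covariates if c != v]
        cov = d.loc[:, cov_cols].to_numpy(dtype=float) if cov_cols else None
        rho, p = stats.spearmanr(_residualize(y1, cov), _residualize(y2, cov))
        rows.append({"variable": v, "n": len(d), "rho": float(rho), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    ok = out["p_raw"].notna()
    out["p_fdr"] = np.nan
    if ok.any():
        out.loc[ok, "p_fdr"] = benjamini_hochberg(out.loc[ok, "p_raw"].to_numpy())
    return out


def _cox_fit(df: pd.DataFrame, duration_col: str, event_col: str, covariates: list[str]):
    from lifelines import CoxPHFitter

    cph = CoxPHFitter()
    cph.fit(
        df.loc[:, [duration_col, event_col, *covariates]],
        duration_col=duration_col,
        event_col=event_col,
    )
    s = cph.summary
    out = pd.DataFrame(
        {
            "covariate": s.index,
            "HR": s["exp(coef)"].to_numpy(),
            "HR_lower95": s["exp(coef) lower 95%"].to_numpy(),
            "HR_upper95": s["exp(coef) upper 95%"].to_numpy(),
            "p": s["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def cox_models(
    records: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
    retention_p: float = 0.10,
) -> dict:
    """Univariate, multivariate and stepwise-backward Cox models.

    Backward elimination removes the least significant covariate until all
    retained covariates have p < ``retention_p``.  Covariates whose
    univariate fit fails to converge are flagged (not silently dropped).
    """
    d = records.loc[:, [duration_col, event_col, *covariates]].dropna()
    if (d[duration_col] <= 0).any():
        raise InvalidConfigError("durations must be positive")
    if int(d[event_col].sum()) < 10:
        raise DegenerateDataError("fewer than 10 events")
    zero_var = [c for c in covariates if np.ptp(d[c].to_numpy(dtype=float)) == 0]
    if zero_var:
        raise DegenerateDataError(f"zero-variance covariates: {zero_var}")

    failures: dict[str, str] = {}
    uni_rows = []
    for c in covariates:
        try:
            uni_rows.append(_cox_fit(d, duration_col, event_col, [c]))
        except Exception as exc:  # convergence / separation
            failures[c] = str(exc)
    univariate = pd.concat(uni_rows, ignore_index=True) if uni_rows else pd.DataFrame()

    try:
        multivariate = _cox_fit(d, duration_col, event_col, list(covariates))
    except Exception as exc:
        failures["<multivariate>"] = str(exc)
        multivariate = pd.DataFrame()

    kept = list(covariates)
    final = multivariate
    while len(kept) > 0:
        try:
            final = _cox_fit(d, duration_col, event_col, kept)
        except Exception as exc:
            failures["<stepwise>"] = str(exc)
            break
        worst = final.loc[final["p"].idxmax()]
        if worst["p"] < retention_p:
            break
        kept = [c for c in kept if c != worst["covariate"]]
        if not kept:
            final = pd.DataFrame()
    return {
        "univariate": univariate,
        "multivariate": multivariate,
        "final": final,
        "final_covariates": kept,
        "failures": failures,
        "n": len(d),
        "n_events": int(d[event_col].sum()),
    }


def one_vs_all_contrast(
    Z: pd.DataFrame,
    assignments: pd.DataFrame,
    regions: Sequence[str] | None = None,
    min_per_subtype: int = 5,
) -> pd.DataFrame:
    """Per-region one-subtype-vs-all-others t-values, adjusted for stage.

    Restricted to subtypeable subjects; per region and subtype an OLS
    model ``z ~ is_subtype + weighted_stage`` is fitted and the t statistic
    of the subtype indicator reported.
    """
    import statsmodels.api as sm

    sub = assignments[assignments["ml_subtype"] >= 0]
    labels = sorted(sub["ml_subtype"].unique())
    if len(labels) < 2:
        raise DegenerateDataError("one-vs-all contrast needs >= 2 subtypes")
    counts = sub["ml_subtype"].value_counts()
    labels = [l for l in labels if counts[l] >= min_per_subtype]
    if len(labels) < 2:
        raise DegenerateDataError("fewer than 2 subtypes with enough subjects")
    if regions is None:
        regions = list(Z.columns)
    Zs = Z.loc[sub.index]
    rows = []
    for s_lab in labels:
        ind = (sub["ml_subtype"] == s_lab).astype(float).to_numpy()
        X = sm.add_constant(np.column_stack([ind, sub["weighted_stage"].to_numpy()]))
        for r in regions:
            res = sm.OLS(Zs[r].to_numpy(dtype=float), X).fit()
            rows.append(
                {
                    "subtype": s_lab,
                    "region": r,
                    "t": float(res.tvalues[1]),
                    "p": float(res.pvalues[1]),
                }
            )
    return pd.DataFrame(rows)


def dmt_response(
    clinical: pd.DataFrame,
    assignments: pd.DataFrame,
    treatment_value: str = "DMT",
) -> dict:
    """Treatment-response rates per subtype with pairwise Fisher tests.

    Responders: *relapse* endpoint — no relapse during follow-up
    (``followup_relapses == 0``); *EDSS* endpoint — no EDSS worsening
    (per the progression thresholds).  Rates are reported per assigned
    class (NA and each subtype) among treated subjects with follow-up;
    pairwise Fisher p-values are BH-adjusted within each endpoint family.
    Empty classes are omitted with a warning.
    """
    merged = clinical.set_index("subject_id").join(assignments, how="inner")
    treated = merged[merged["treatment"] == treatment_value].copy()
    treated = treated.dropna(subset=["followup_time"])
    if len(treated) == 0:
        raise DegenerateDataError("no treated subjects with follow-up")
    treated["class"] = treated["ml_subtype"].map(lambda c: "NA" if c < 0 else f"subtype_{c}")
    prog = flag_edss_progression(treated["edss"].to_numpy(), treated["followup_edss"].to_numpy())
    treated["responder_relapse"] = treated["followup_relapses"].astype(float) == 0
    treated["responder_edss"] = ~pd.array(prog, dtype="boolean")

    out: dict = {"rates": {}, "tests": {}}
    for endpoint in ("relapse", "edss"):
        col = f"responder_{endpoint}"
        rows = []
        for lab, grp in treated.groupby("class", sort=True):
            resp = grp[col].dropna()
            if len(resp) == 0:
                warnings.warn(f"{endpoint}: class {lab} has no evaluable subjects", stacklevel=2)
                continue
            rows.append(
                {
                    "class": lab,
                    "responders": int(resp.sum()),
                    "total": int(len(resp)),
                    "percent": float(100.0 * resp.sum() / len(resp)),
                }
            )
        rates = pd.DataFrame(rows)
        out["rates"][endpoint] = rates
        pair_rows = []
        for a, b in combinations(rates["class"], 2):
            ra = rates.set_index("class").loc[a]
            rb = rates.set_index("class").loc[b]
            tab = [
                [ra["responders"], ra["total"] - ra["responders"]],
                [rb["responders"], rb["total"] - rb["responders"]],
            ]
            res = categorical_test(tab, method="fisher")
            pair_rows.append({"class_a": a, "class_b": b, "p_raw": res["p"]})
        tests = pd.DataFrame(pair_rows)
        if len(tests):
            tests["p_fdr"] = benjamini_hochberg(tests["p_raw"].to_numpy())
        out["tests"][endpoint] = tests
    return out
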