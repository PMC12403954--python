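"""Subject-level subtype and stage assignment.

A subject is *subtypeable* when some subtype explains their z-scores better
than the stage-0 (no abnormality) alternative:

* ``L_0 = prod_b N(z_b; 0, sigma_b)`` — the stage-0 likelihood;
* ``L_c = f_c * (1/E) * sum_{k=1..E} P(x | S_c, k)`` — subtype c's
  likelihood, summed over the post-onset stages (stage 0 is the
  alternative, so it is excluded from the subtype sum by default).

Subjects with ``L_0 >= max_c L_c`` are flagged *normal-appearing* (NA);
ties resolve conservatively to NA.  Every subject — NA or not — also gets
a probability-weighted stage, the posterior-expected stage over the full
``(subtype, stage 0..E)`` grid.

Follow-up visits are assigned with the baseline-fitted model (never
refitted) so that longitudinal subtype stability and stage progression are
measured against a fixed reference.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import InvalidConfigError
from .fit import SubtypeModel, SuStaInFit, _as_matrix
from .model import EventSet, stage_loglik_matrix, stage_z_matrix

__all__ = ["assign_subtype", "assign_stage", "assign_table", "longitudinal_stability", "subtype_prevalence"]


def _stage_logliks(Zm: np.ndarray, es: EventSet, models: Sequence[SubtypeModel], sigma):
    """(n, C, E+1) stage log-likelihood cube."""
    return np.stack(
        [
            stage_loglik_matrix(Zm, es, m.ordering, sigma, G=stage_z_matrix(es, m.ordering))
            for m in models
        ],
        axis=1,
    )


def _posteriors(Zm, es, models, sigma, include_stage0_in_subtype: bool):
    cube = _stage_logliks(Zm, es, models, sigma)  # (n, C, E+1)
    logf = np.log(np.maximum([m.fraction for m in models], 1e-300))
    E = es.n_events
    log_l0 = cube[:, 0, 0]  # same for every subtype: all trajectories are 0 at stage 0
    if include_stage0_in_subtype:
        log_lc = logf[None, :] + logsumexp(cube, axis=2) - np.log(E + 1)
    else:
        log_lc = logf[None, :] + logsumexp(cube[:, :, 1:], axis=2) - np.log(E)
    return cube, log_l0, log_lc


def assign_subtype(
    z_row,
    fit: SuStaInFit | Sequence[SubtypeModel],
    event_set: EventSet | None = None,
    sigma=None,
    include_stage0_in_subtype: bool = False,
):
    """NA flag, most likely subtype and posterior for one subject.

    Returns ``(is_na, ml_subtype, posterior)`` where ``posterior`` has
    ``C + 1`` entries: stage-0/NA first, then each subtype.  ``ml_subtype``
    is ``-1`` for NA subjects.
    """
    models, es, s = _resolve(fit, event_set, sigma)
    Zm = np.atleast_2d(np.asarray(z_row, dtype=float))
    _, log_l0, log_lc = _posteriors(Zm, es, models, s, include_stage0_in_subtype)
    lw = np.concatenate([log_l0[:, None], log_lc], axis=1)
    post = np.exp(lw - logsumexp(lw, axis=1)[:, None])
    is_na = log_l0[0] >= log_lc[0].max()  # ties -> NA (conservative)
    ml = -1 if is_na else int(np.argmax(log_lc[0]))
    return bool(is_na), ml, post[0]


def assign_stage(
    z_row,
    fit: SuStaInFit | Sequence[SubtypeModel],
    event_set: EventSet | None = None,
    sigma=None,
    ml_subtype_only: bool = False,
) -> float:
    """Probability-weighted stage of one subject.

    ``weighted_stage = sum_c sum_k k * P(c, k | x)`` with
    ``P(c, k) ∝ f_c * (1/(E+1)) * P(x | S_c, k)`` over the full grid
    (k = 0..E, all subtypes).  With ``ml_subtype_only`` the sum runs over
    the most likely subtype alone.
    """
    models, es, s = _resolve(fit, event_set, sigma)
    Zm = np.atleast_2d(np.asarray(z_row, dtype=float))
    cube, _, log_lc = _posteriors(Zm, es, models, s, False)
    logf = np.log(np.maximum([m.fraction for m in models], 1e-300))
    lw = logf[None, :, None] + cube[0][None, :, :]  # (1, C, E+1); 1/(E+1) cancels
    if ml_subtype_only:
        c = int(np.argmax(log_lc[0]))
        lw = lw[:, c : c + 1, :]
    w = np.exp(lw - logsumexp(lw))
    k = np.arange(es.n_events + 1, dtype=float)
    return float((w.sum(axis=1) * k).sum())


def _resolve(fit, event_set, sigma):
    if isinstance(fit, SuStaInFit):
        return fit.selected_models, fit.event_set, fit.sigma if sigma is None else sigma
    if event_set is None:
        raise InvalidConfigError("event_set is required when passing raw models")
    if not fit:
        raise InvalidConfigError("no fitted model")
    return list(fit), event_set, 1.0 if sigma is None else sigma


def assign_table(
    Z,
    fit: SuStaInFit | Sequence[SubtypeModel],
    event_set: EventSet | None = None,
    sigma=None,
    visit: str = "baseline",
    include_stage0_in_subtype: bool = False,
) -> pd.DataFrame:
    """Vectorized assignment of a whole z-score matrix.

    Returns one row per subject: NA flag, ML subtype (−1 for NA), the
    posterior over (stage 0, subtypes) and the probability-weighted stage.
    """
    models, es, s = _resolve(fit, event_set, sigma)
    Zm, index = _as_matrix(Z)
    cube, log_l0, log_lc = _posteriors(Zm, es, models, s, include_stage0_in_subtype)
    lw = np.concatenate([log_l0[:, None], log_lc], axis=1)
    post = np.exp(lw - logsumexp(lw, axis=1)[:, None])
    is_na = log_l0 >= log_lc.max(axis=1)
    ml = np.where(is_na, -1, np.argmax(log_lc, axis=1))

    logf = np.log(np.maximum([m.fraction for m in models], 1e-300))
    lw_stage = logf[None, :, None] + cube
    w = np.exp(lw_stage - logsumexp(lw_stage, axis=(1, 2))[:, None, None])
    k = np.arange(es.n_events + 1, dtype=float)
    weighted_stage = (w.sum(axis=1) * k[None, :]).sum(axis=1)

    out = pd.DataFrame(
        {
            "is_na": is_na,
            "ml_subtype": ml,
            "weighted_stage": weighted_stage,
            "p_stage0": post[:, 0],
            "visit": visit,
        },
        index=pd.Index(index, name="subject_id"),
    )
    for c in range(len(models)):
        out[f"p_subtype_{c}"] = post[:, 1 + c]
    return out


def subtype_prevalence(assignments: pd.DataFrame) -> pd.Series:
    """Percentage of subjects per assigned class (NA and each subtype)."""
    lab = assignments["ml_subtype"].map(lambda c: "NA" if c < 0 else f"subtype_{c}")
    return (lab.value_counts(sort=False) / len(assignments) * 100.0).rename("percent")


def longitudinal_stability(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
    stage_tol: float = 0.5,
) -> dict:
    """Subtype stability and stage progression across two visits.

    Reports (a) the proportion with the same assignment at both visits or
    an NA→subtype transition; (b) the proportion with the same subtype
    among pairs subtypeable at both visits; and (c) stage-progression
    categories lower/same/higher, where ``|Δstage| < stage_tol`` counts as
    "same".  Unpaired subjects are excluded with a warning.
    """
    merged = baseline.join(followup, how="inner", lsuffix="_bl", rsuffix="_fu")
    n_unpaired = len(baseline) + len(followup) - 2 * len(merged)
    if n_unpaired > 0:
        warnings.warn(f"excluding {n_unpaired} unpaired visit rows", stacklevel=2)
    if len(merged) == 0:
        raise InvalidConfigError("no paired subjects between visits")

    bl, fu = merged["ml_subtype_bl"], merged["ml_subtype_fu"]
    same = bl == fu
    na_to_subtype = (bl == -1) & (fu >= 0)
    stable_a = same | na_to_subtype

    both_subtyped = (bl >= 0) & (fu >= 0)
    n_b = int(both_subtyped.sum())
    stable_b = same & both_subtyped

    delta = merged["weighted_stage_fu"] - merged["weighted_stage_bl"]
    cat = pd.Series(
        np.where(delta.abs() < stage_tol, "same", np.where(delta > 0, "higher", "lower")),
        index=merged.index,
    )

    def pct(num, den):
        return float(100.0 * num / den) if den else float("nan")

    return {
        "n_pairs": int(len(merged)),
        "stable_or_na_to_subtype": int(stable_a.sum()),
        "stable_or_na_to_subtype_pct": pct(stable_a.sum(), len(merged)),
        "n_both_subtyped": n_b,
        "stable_both_subtyped": int(stable_b.sum()),
        "stable_both_subtyped_pct": pct(stable_b.sum(), n_b),
        "stage_lower": int((cat == "lower").sum()),
        "stage_same": int((cat == "same").sum()),
        "stage_higher": int((cat == "higher").sum()),
        "stage_lower_pct": pct((cat == "lower").sum(), len(merged)),
        "stage_same_pct": pct((cat == "same").sum(), len(merged)),
        "stage_higher_pct": pct((cat == "higher").sum(), len(merged)),
    }
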