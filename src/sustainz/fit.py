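"""Fitting the subtype mixture over event orderings.

The model is a C-component mixture: each subtype ``c`` has an event
ordering ``S_c`` and a mixing fraction ``f_c``; a subject's marginal under
subtype ``c`` averages the stage likelihood over the uniform stage prior
0..E.  The dataset log-likelihood is

    sum_i log sum_c f_c * P(x_i | S_c).

Fitting follows the usual hierarchy for this model family:

* C = 1: multi-start greedy ascent over orderings (repeated single-event
  repositioning passes until no improvement), one start seeded by a
  data-driven heuristic, the rest random.
* C -> C + 1: each current cluster's hard-assigned subjects are split into
  two random halves, each half fitted as a single trajectory, and all
  orderings plus fractions jointly re-optimized by EM (responsibilities /
  fraction updates / weighted greedy ordering ascent) until the
  log-likelihood change falls below tolerance; the best split is kept.
* Finally, Metropolis MCMC over orderings (uniform pairwise swaps,
  proposals violating within-biomarker threshold order rejected) at fixed
  fractions yields posterior ordering samples and positional densities.

The number of subtypes is selected by ten-fold cross-validation:
``CVIC(C) = -2 * sum_folds heldout-loglik(C)``, smallest C within a
parsimony margin of the minimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import DegenerateDataError, InvalidConfigError
from .model import (
    EventSet,
    is_valid_ordering,
    random_ordering,
    stage_loglik_matrix,
    stage_z_batch,
    stage_z_matrix,
)

__all__ = [
    "SubtypeModel",
    "SuStaInFit",
    "loglik_dataset",
    "fit_fixed_C",
    "fit_sustain",
    "mcmc_orderings",
    "crossval_cvic",
    "select_C",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class SubtypeModel:
    """One fitted subtype: ML ordering, mixing fraction, MCMC summaries."""

    ordering: np.ndarray
    fraction: float
    mcmc_orderings: np.ndarray | None = None  # (n_samples, E)
    mcmc_loglik: np.ndarray | None = None
    positional_density: np.ndarray | None = None  # (E, E) event x position

    def to_dict(self, event_set: EventSet | None = None) -> dict:
        d = {
            "ordering": [int(e) for e in self.ordering],
            "fraction": float(self.fraction),
        }
        if event_set is not None:
            d["events"] = [event_set.event_label(e) for e in self.ordering]
        if self.positional_density is not None:
            d["positional_density"] = self.positional_density.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SubtypeModel":
        pd_ = d.get("positional_density")
        return cls(
            ordering=np.asarray(d["ordering"], dtype=int),
            fraction=float(d["fraction"]),
            positional_density=None if pd_ is None else np.asarray(pd_, dtype=float),
        )


@dataclass
class SuStaInFit:
    """Models for C = 1..C_max with CVIC-based selection."""

    event_set: EventSet
    models_by_c: dict[int, list[SubtypeModel]]
    loglik_by_c: dict[int, float]
    cvic: dict[int, float] | None
    selected_c: int
    seed: int
    sigma: float | np.ndarray = 1.0
    fold_ids: pd.Series | None = None
    em_traces: dict[int, list[float]] = field(default_factory=dict)

    @property
    def selected_models(self) -> list[SubtypeModel]:
        return self.models_by_c[self.selected_c]

    def to_dict(self) -> dict:
        return {
            "event_set": self.event_set.to_dict(),
            "models_by_c": {
                str(c): [m.to_dict(self.event_set) for m in ms]
                for c, ms in self.models_by_c.items()
            },
            "loglik_by_c": {str(c): float(v) for c, v in self.loglik_by_c.items()},
            "cvic": None if self.cvic is None else {str(c): float(v) for c, v in self.cvic.items()},
            "selected_c": int(self.selected_c),
            "seed": int(self.seed),
            "sigma": np.asarray(self.sigma, dtype=float).tolist(),
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "SuStaInFit":
        sigma = np.asarray(d.get("sigma", 1.0), dtype=float)
        if sigma.ndim == 0:
            sigma = float(sigma)
        return cls(
            event_set=EventSet.from_dict(d["event_set"]),
            models_by_c={int(c): [SubtypeModel.from_dict(m) for m in ms] for c, ms in d["models_by_c"].items()},
            loglik_by_c={int(c): float(v) for c, v in d["loglik_by_c"].items()},
            cvic=None if d.get("cvic") is None else {int(c): float(v) for c, v in d["cvic"].items()},
            selected_c=int(d["selected_c"]),
            seed=int(d.get("seed", 0)),
            sigma=sigma,
        )

    @classmethod
    def from_json(cls, path) -> "SuStaInFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# likelihood plumbing


def _as_matrix(Z) -> tuple[np.ndarray, pd.Index]:
    if isinstance(Z, pd.DataFrame):
        return Z.to_numpy(dtype=float), Z.index
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    return Z, pd.RangeIndex(len(Z))


def _log_marginal_col(Z: np.ndarray, es: EventSet, ordering: np.ndarray, sigma) -> np.ndarray:
    """log P(x_i | S) for every subject (uniform stage prior)."""
    ll = stage_loglik_matrix(Z, es, ordering, sigma, G=stage_z_matrix(es, ordering))
    return logsumexp(ll, axis=1) - np.log(es.n_events + 1)


def _mixture_loglik(log_margs: np.ndarray, fractions: np.ndarray) -> float:
    lw = np.log(fractions)[None, :] + log_margs
    return float(logsumexp(lw, axis=1).sum())


def loglik_dataset(Z, models: Sequence[SubtypeModel], event_set: EventSet, sigma=1.0) -> float:
    """Total dataset log-likelihood under a fitted subtype mixture."""
    if len(models) == 0:
        raise InvalidConfigError("at least one subtype model is required")
    Zm, _ = _as_matrix(Z)
    if Zm.size == 0:
        raise DegenerateDataError("empty data")
    fractions = np.array([m.fraction for m in models], dtype=float)
    if np.any(fractions < 0) or abs(fractions.sum() - 1.0) > 1e-8:
        raise InvalidConfigError("fractions must be non-negative and sum to 1")
    log_margs = np.column_stack(
        [_log_marginal_col(Zm, event_set, m.ordering, sigma) for m in models]
    )
    return _mixture_loglik(log_margs, fractions)


# ---------------------------------------------------------------------------
# greedy ascent over orderings


def _heuristic_ordering(Z: np.ndarray, es: EventSet, weights: np.ndarray | None = None) -> np.ndarray:
    """Data-driven start: events sorted by threshold / mean abnormality.

    Biomarkers with larger (weighted) mean z come earlier; within a
    biomarker the shared denominator keeps thresholds in increasing order,
    so the result is always a valid ordering.
    """
    w = np.ones(len(Z)) if weights is None else weights
    wsum = w.sum()
    mean_z = (w @ Z) / wsum if wsum > 0 else Z.mean(axis=0)
    score = es.event_z / np.maximum(mean_z[es.event_biomarker], 1e-6)
    return np.argsort(score, kind="stable")


def _insert_candidates(es: EventSet, ordering: np.ndarray, e: int) -> list[np.ndarray]:
    """All valid orderings obtained by repositioning event ``e``."""
    E = es.n_events
    pos = int(np.flatnonzero(ordering == e)[0])
    base = np.delete(ordering, pos)
    bm = es.event_biomarker
    same = np.flatnonzero(bm[base] == bm[e])
    ez = es.event_z
    lo = 0
    hi = E - 1  # inclusive insertion slots 0..E-1
    for p in same:
        if ez[base[p]] < ez[e]:
            lo = max(lo, p + 1)
        else:
            hi = min(hi, p)
    cands = []
    for p in range(lo, hi + 1):
        if p == pos:
            continue
        cands.append(np.insert(base, p, e))
    return cands


def _batch_objective(
    Zs: np.ndarray,
    zz: np.ndarray,
    es: EventSet,
    cands: Sequence[np.ndarray],
    s: np.ndarray,
    const: float,
    weights: np.ndarray | None,
) -> np.ndarray:
    """(Weighted) marginal log-likelihood objective of candidate orderings."""
    E = es.n_events
    ncand = len(cands)
    Gs = stage_z_batch(es, np.stack(cands)) / s[None, :, None]  # (ncand, B, E+1)
    dot = (Zs @ Gs.transpose(1, 0, 2).reshape(es.n_biomarkers, -1)).reshape(len(Zs), ncand, E + 1)
    ll = -0.5 * (zz[:, None, None] - 2.0 * dot + (Gs**2).sum(axis=1)[None, :, :]) - const
    mx = ll.max(axis=2)
    marg = mx + np.log(np.exp(ll - mx[:, :, None]).sum(axis=2)) - np.log(E + 1)  # (n, ncand)
    if weights is None:
        return marg.sum(axis=0)
    return weights @ marg


def _greedy_ascent(
    Z: np.ndarray,
    es: EventSet,
    ordering: np.ndarray,
    sigma,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
    max_passes: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float]:
    """Single-event repositioning passes until no improvement."""
    s = np.broadcast_to(np.asarray(sigma, dtype=float), (es.n_biomarkers,)).astype(float)
    Zs = Z / s
    zz = (Zs**2).sum(axis=1)
    const = float(np.log(s).sum()) + 0.5 * es.n_biomarkers * np.log(2 * np.pi)
    cur = np.asarray(ordering, dtype=int).copy()
    cur_obj = float(_batch_objective(Zs, zz, es, [cur], s, const, weights)[0])
    E = es.n_events
    for _ in range(max_passes):
        improved = False
        for e in rng.permutation(E):
            cands = _insert_candidates(es, cur, int(e))
            if not cands:
                continue
            obj = _batch_objective(Zs, zz, es, cands, s, const, weights)
            j = int(np.argmax(obj))
            if obj[j] > cur_obj + tol:
                cur, cur_obj = cands[j], float(obj[j])
                improved = True
        if not improved:
            break
    return cur, cur_obj


def _greedy_multistart(
    Z: np.ndarray,
    es: EventSet,
    sigma,
    rng: np.random.Generator,
    n_starts: int,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    starts = [_heuristic_ordering(Z, es, weights)]
    starts += [random_ordering(es, rng) for _ in range(max(0, n_starts - 1))]
    best, best_obj = None, -np.inf
    for s0 in starts:
        o, obj = _greedy_ascent(Z, es, s0, sigma, rng, weights)
        if obj > best_obj:
            best, best_obj = o, obj
    return best, best_obj


# ---------------------------------------------------------------------------
# EM over fractions and orderings


def _em(
    Z: np.ndarray,
    es: EventSet,
    orderings: list[np.ndarray],
    fractions: np.ndarray,
    sigma,
    rng: np.random.Generator,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[list[np.ndarray], np.ndarray, float, list[float]]:
    """Coordinate ascent: responsibilities -> fractions -> orderings.

    Returns (orderings, fractions, loglik, trace); the trace of observed
    log-likelihoods is non-decreasing (exact E-step, improving M-steps).
    """
    orderings = [o.copy() for o in orderings]
    fractions = np.asarray(fractions, dtype=float).copy()
    margs = np.column_stack([_log_marginal_col(Z, es, o, sigma) for o in orderings])
    trace: list[float] = []
    for it in range(max_iter):
        lw = np.log(np.maximum(fractions, 1e-300))[None, :] + margs
        norm = logsumexp(lw, axis=1)
        ll = float(norm.sum())
        trace.append(ll)
        if it > 0 and trace[-1] - trace[-2] < tol * max(1.0, abs(trace[-2])):
            break
        r = np.exp(lw - norm[:, None])
        fractions = np.maximum(r.mean(axis=0), 1e-12)
        fractions /= fractions.sum()
        for c in range(len(orderings)):
            orderings[c], _ = _greedy_ascent(Z, es, orderings[c], sigma, rng, weights=r[:, c], max_passes=3)
            margs[:, c] = _log_marginal_col(Z, es, orderings[c], sigma)
    ll = _mixture_loglik(margs, fractions)
    trace.append(ll)
    return orderings, fractions, ll, trace


# ---------------------------------------------------------------------------
# hierarchical fit over C


def _split_candidates(Z: np.ndarray, idx: np.ndarray, rng: np.random.Generator, n_random: int):
    """Ways to split one cluster's subjects in two for the C -> C+1 step.

    Yields a shape-based 2-means split first (z rows normalized to unit
    length, so severity is factored out and the split follows the spatial
    pattern), then ``n_random`` random halves.  The random halves are the
    classical initialization; the shape split adds a data-driven candidate
    that separates overlapping orderings far more reliably.
    """
    from scipy.cluster.vq import kmeans2

    if len(idx) >= 8:
        P = Z[idx]
        P = P / np.maximum(np.linalg.norm(P, axis=1, keepdims=True), 1e-9)
        try:
            _, lab = kmeans2(P, 2, minit="++", seed=int(rng.integers(2**31)))
            h1, h2 = idx[lab == 0], idx[lab == 1]
            if len(h1) >= 2 and len(h2) >= 2:
                yield h1, h2
        except Exception:
            pass
    for _ in range(n_random):
        halves = rng.permutation(idx)
        yield halves[: len(idx) // 2], halves[len(idx) // 2 :]


def _fit_sequence(
    Z: np.ndarray,
    es: EventSet,
    c_max: int,
    n_starts: int,
    sigma,
    rng: np.random.Generator,
    em_tol: float = 1e-6,
    n_split_tries: int = 3,
) -> tuple[dict[int, tuple[list[np.ndarray], np.ndarray, float]], dict[int, list[float]]]:
    """Fit C = 1..c_max hierarchically; returns per-C (orderings, fractions, loglik)."""
    n = len(Z)
    if c_max > es.n_events or c_max > n:
        raise InvalidConfigError("number of subtypes exceeds events or subjects")
    out: dict[int, tuple[list[np.ndarray], np.ndarray, float]] = {}
    traces: dict[int, list[float]] = {}

    o1, ll1 = _greedy_multistart(Z, es, sigma, rng, n_starts)
    out[1] = ([o1], np.array([1.0]), ll1)
    traces[1] = [ll1]

    split_starts = max(3, n_starts // 3)
    for c in range(2, c_max + 1):
        orderings, fractions, _ = out[c - 1]
        margs = np.column_stack([_log_marginal_col(Z, es, o, sigma) for o in orderings])
        lw = np.log(fractions)[None, :] + margs
        hard = np.argmax(lw, axis=1)
        best: tuple[list[np.ndarray], np.ndarray, float, list[float]] | None = None
        for j in range(c - 1):
            idx = np.flatnonzero(hard == j)
            if len(idx) < 4:
                continue
            for h1, h2 in _split_candidates(Z, idx, rng, n_split_tries):
                oa, _ = _greedy_multistart(Z[h1], es, sigma, rng, split_starts)
                ob, _ = _greedy_multistart(Z[h2], es, sigma, rng, split_starts)
                new_orderings = [o for k, o in enumerate(orderings) if k != j] + [oa, ob]
                f_others = [f for k, f in enumerate(fractions) if k != j]
                fj = fractions[j]
                new_fractions = np.array(
                    f_others + [fj * len(h1) / len(idx), fj * len(h2) / len(idx)]
                )
                res = _em(Z, es, new_orderings, new_fractions, sigma, rng, tol=em_tol)
                if best is None or res[2] > best[2]:
                    best = res
        if best is None:
            # no cluster large enough: split the full sample at random
            halves = rng.permutation(n)
            h1, h2 = halves[: n // 2], halves[n // 2 :]
            oa, _ = _greedy_multistart(Z[h1], es, sigma, rng, split_starts)
            ob, _ = _greedy_multistart(Z[h2], es, sigma, rng, split_starts)
            new_orderings = list(orderings[:-1]) + [oa, ob]
            new_fractions = np.append(fractions[:-1], [fractions[-1] / 2, fractions[-1] / 2])
            best = _em(Z, es, new_orderings, new_fractions, sigma, rng, tol=em_tol)
        out[c] = (best[0], best[1], best[2])
        traces[c] = best[3]
    return out, traces


def mcmc_orderings(
    Z,
    event_set: EventSet,
    orderings: Sequence[np.ndarray],
    fractions: Sequence[float],
    iters: int,
    seed: int | np.random.Generator = 0,
    sigma=1.0,
    thin: int = 10,
    track_counts: bool = False,
    cache_size: int = 8192,
):
    """Metropolis sampling over subtype orderings at fixed fractions.

    One iteration proposes a uniform swap of two event positions in one
    uniformly chosen subtype's ordering; proposals breaking the
    within-biomarker threshold order are rejected (the chain stays put,
    which keeps the kernel symmetric on the constrained space).

    Returns a dict with per-subtype thinned ``samples``, their joint
    ``loglik`` values, per-subtype ``positional_density`` (E x E,
    accumulated over *all* iterations, rows sum to 1) and, optionally,
    per-subtype visit ``counts`` keyed by ordering tuple.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Zm, _ = _as_matrix(Z)
    es = event_set
    E = es.n_events
    C = len(orderings)
    cur = [np.asarray(o, dtype=int).copy() for o in orderings]
    for o in cur:
        if not is_valid_ordering(es, o):
            raise InvalidConfigError("initial MCMC ordering is invalid")
    fr = np.asarray(fractions, dtype=float)
    logf = np.log(np.maximum(fr, 1e-300))

    cache: dict[bytes, np.ndarray] = {}

    def marg(o: np.ndarray) -> np.ndarray:
        key = o.tobytes()
        col = cache.get(key)
        if col is None:
            col = _log_marginal_col(Zm, es, o, sigma)
            if len(cache) < cache_size:
                cache[key] = col
        return col

    margs = np.column_stack([marg(o) for o in cur])
    cur_ll = _mixture_loglik(margs, fr)

    density = np.zeros((C, E, E))
    pos_idx = np.arange(E)
    samples: list[list[np.ndarray]] = [[] for _ in range(C)]
    logliks: list[float] = []
    counts: list[dict[tuple, int]] | None = [dict() for _ in range(C)] if track_counts else None
    bm = es.event_biomarker
    ez = es.event_z

    for it in range(iters):
        c = int(rng.integers(C)) if C > 1 else 0
        i, j = rng.choice(E, size=2, replace=False)
        o = cur[c]
        ei, ej = o[i], o[j]
        # swap validity: only the two moved events can break threshold order
        prop = o.copy()
        prop[i], prop[j] = ej, ei
        valid = True
        lo, hi = (i, j) if i < j else (j, i)
        for e, newpos in ((ei, j), (ej, i)):
            same = bm[o] == bm[e]
            for p in range(lo, hi + 1):
                if p != i and p != j and same[p]:
                    if (ez[o[p]] < ez[e]) != (p < newpos):
                        valid = False
                        break
            if not valid:
                break
        if valid and bm[ei] == bm[ej]:
            valid = False  # swapping two events of one biomarker always breaks order
        if valid:
            col = marg(prop)
            new_margs = margs.copy()
            new_margs[:, c] = col
            new_ll = _mixture_loglik(new_margs, fr)
            if np.log(rng.random()) < new_ll - cur_ll:
                cur[c] = prop
                margs = new_margs
                cur_ll = new_ll
        for c2 in range(C):
            density[c2][cur[c2], pos_idx] += 1.0
            if counts is not None:
                key = tuple(int(x) for x in cur[c2])
                counts[c2][key] = counts[c2].get(key, 0) + 1
        if it % thin == 0:
            for c2 in range(C):
                samples[c2].append(cur[c2].copy())
            logliks.append(cur_ll)

    density /= iters
    out = {
        "samples": [np.stack(s) for s in samples],
        "loglik": np.asarray(logliks),
        "positional_density": [density[c] for c in range(C)],
        "final_orderings": cur,
    }
    if counts is not None:
        out["counts"] = counts
    return out


def fit_fixed_C(
    Z,
    event_set: EventSet,
    C: int,
    n_starts: int = 25,
    mcmc_iters: int = 10_000,
    seed: int = 0,
    sigma=1.0,
    em_tol: float = 1e-6,
    n_split_tries: int = 3,
    return_info: bool = False,
):
    """Fit a C-subtype model (hierarchical init + EM + MCMC).

    With ``mcmc_iters = 0`` the MCMC stage is skipped and positional
    densities degenerate to the ML ordering.
    """
    Zm, _ = _as_matrix(Z)
    if C < 1:
        raise InvalidConfigError("C must be >= 1")
    rng = np.random.default_rng(seed)
    seq, traces = _fit_sequence(Zm, event_set, C, n_starts, sigma, rng, em_tol, n_split_tries)
    orderings, fractions, ll = seq[C]
    E = event_set.n_events
    models = []
    if mcmc_iters > 0:
        res = mcmc_orderings(Zm, event_set, orderings, fractions, mcmc_iters, rng, sigma)
        for c in range(C):
            models.append(
                SubtypeModel(
                    ordering=orderings[c],
                    fraction=float(fractions[c]),
                    mcmc_orderings=res["samples"][c],
                    mcmc_loglik=res["loglik"],
                    positional_density=res["positional_density"][c],
                )
            )
    else:
        for c in range(C):
            dens = np.zeros((E, E))
            dens[orderings[c], np.arange(E)] = 1.0
            models.append(
                SubtypeModel(ordering=orderings[c], fraction=float(fractions[c]), positional_density=dens)
            )
    if return_info:
        return models, {"loglik": ll, "em_trace": traces[C], "em_traces": traces, "sequence": seq}
    return models


# ---------------------------------------------------------------------------
# cross-validation and model selection


def _fold_assignment(index: pd.Index, folds: int, rng: np.random.Generator, groups=None) -> pd.Series:
    """Seeded stratified fold labels, invariant to row order of the input."""
    ids = pd.Index(index)
    order = np.argsort(ids.to_numpy(), kind="stable")
    sorted_ids = ids.to_numpy()[order]
    if groups is None:
        strata = {None: sorted_ids}
    else:
        g = pd.Series(np.asarray(groups), index=ids).loc[sorted_ids]
        strata = {k: v.index.to_numpy() for k, v in g.groupby(g, sort=True)}
    fold = pd.Series(index=ids, dtype=int, name="fold")
    for _, members in sorted(strata.items(), key=lambda kv: str(kv[0])):
        perm = rng.permutation(len(members))
        for r, i in enumerate(perm):
            fold.loc[members[i]] = r % folds
    return fold


def crossval_cvic(
    Z,
    event_set: EventSet,
    c_range: Iterable[int] = (1, 2, 3, 4, 5),
    folds: int = 10,
    seed: int = 0,
    groups=None,
    n_starts: int = 25,
    sigma=1.0,
    em_tol: float = 1e-6,
    n_split_tries: int = 3,
) -> dict:
    """Ten-fold cross-validated information criterion per candidate C.

    Folds are a seeded stratified partition (every subject in exactly one
    test fold); models are fitted on each training 9/10 and scored on the
    held-out tenth; ``CVIC(C) = -2 * sum_folds heldout-loglik``.
    """
    Zm, index = _as_matrix(Z)
    c_list = sorted(set(int(c) for c in c_range))
    n = len(Zm)
    if folds > n:
        raise InvalidConfigError("more folds than subjects")
    rng = np.random.default_rng(seed)
    fold = _fold_assignment(index, folds, rng, groups)
    fold_arr = fold.loc[index].to_numpy()

    heldout = {c: 0.0 for c in c_list}
    for f in range(folds):
        test = fold_arr == f
        train = ~test
        fit_rng = np.random.default_rng([seed, 100 + f])
        seq, _ = _fit_sequence(
            Zm[train], event_set, max(c_list), n_starts, sigma, fit_rng, em_tol, n_split_tries
        )
        for c in c_list:
            orderings, fractions, _ = seq[c]
            margs = np.column_stack(
                [_log_marginal_col(Zm[test], event_set, o, sigma) for o in orderings]
            )
            heldout[c] += _mixture_loglik(margs, fractions)
    cvic = {c: -2.0 * heldout[c] for c in c_list}
    return {"cvic": cvic, "folds": fold, "heldout_loglik": heldout}


def select_C(cvic, parsimony_delta: float = 5.0) -> int:
    """Smallest C whose CVIC is within ``parsimony_delta`` of the minimum.

    ``cvic`` may be a mapping {C: value} or a sequence for C = 1, 2, ...
    Ties and near-ties resolve toward lower complexity.
    """
    if isinstance(cvic, Mapping):
        items = sorted((int(c), float(v)) for c, v in cvic.items())
    else:
        items = list(enumerate((float(v) for v in cvic), start=1))
    if not items:
        raise InvalidConfigError("cvic is empty")
    best = min(v for _, v in items)
    for c, v in items:  # ascending C
        if v <= best + parsimony_delta:
            return c
    raise AssertionError("unreachable")


def fit_sustain(
    Z,
    event_set: EventSet,
    c_max: int = 5,
    folds: int = 10,
    n_starts: int = 25,
    mcmc_iters: int = 10_000,
    seed: int = 0,
    sigma=1.0,
    parsimony_delta: float = 5.0,
    groups=None,
    cv_n_starts: int | None = None,
    do_cv: bool = True,
) -> SuStaInFit:
    """End-to-end fit: hierarchy over C, CVIC selection, MCMC for the pick.

    ``cv_n_starts`` optionally reduces greedy restarts inside
    cross-validation (the CV surface is flatter, so fewer restarts
    suffice); defaults to ``n_starts``.
    """
    Zm, index = _as_matrix(Z)
    rng = np.random.default_rng([seed, 1])
    seq, traces = _fit_sequence(Zm, event_set, c_max, n_starts, sigma, rng)

    cvic_res = None
    if do_cv:
        cvic_res = crossval_cvic(
            Z,
            event_set,
            c_range=range(1, c_max + 1),
            folds=folds,
            seed=seed,
            groups=groups,
            n_starts=cv_n_starts if cv_n_starts is not None else n_starts,
            sigma=sigma,
        )
        selected = select_C(cvic_res["cvic"], parsimony_delta)
    else:
        selected = c_max

    models_by_c: dict[int, list[SubtypeModel]] = {}
    E = event_set.n_events
    for c, (orderings, fractions, _) in seq.items():
        ms = []
        for k in range(c):
            dens = np.zeros((E, E))
            dens[orderings[k], np.arange(E)] = 1.0
            ms.append(SubtypeModel(ordering=orderings[k], fraction=float(fractions[k]), positional_density=dens))
        models_by_c[c] = ms
    if mcmc_iters > 0:
        orderings, fractions, _ = seq[selected]
        res = mcmc_orderings(
            Zm, event_set, orderings, fractions, mcmc_iters, np.random.default_rng([seed, 2]), sigma
        )
        models_by_c[selected] = [
            SubtypeModel(
                ordering=orderings[c],
                fraction=float(fractions[c]),
                mcmc_orderings=res["samples"][c],
                mcmc_loglik=res["loglik"],
                positional_density=res["positional_density"][c],
            )
            for c in range(selected)
        ]
    return SuStaInFit(
        event_set=event_set,
        models_by_c=models_by_c,
        loglik_by_c={c: v[2] for c, v in seq.items()},
        cvic=None if cvic_res is None else cvic_res["cvic"],
        selected_c=selected,
        seed=seed,
        sigma=sigma,
        fold_ids=None if cvic_res is None else cvic_res["folds"],
        em_traces=traces,
    )
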