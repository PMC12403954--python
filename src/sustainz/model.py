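"""Piecewise-linear z-score event model.

The disease-progression model used throughout this package describes each
atrophy subtype as an ordered sequence of *events*: a biomarker's atrophy
z-score crossing a fixed threshold (by default z = 1, 2 and 3).  With ``E``
events in total, a subject's *stage* ``k`` in ``0..E`` means the first ``k``
events of the subtype's ordering have occurred.  Between events each
biomarker's expected z-score rises linearly, from 0 at stage 0 through its
thresholds at the stages where its events sit, up to a ceiling ``z_max`` at
stage E.  Observed z-scores scatter around that expectation with Gaussian
noise (unit SD by default, since inputs are control-referenced z-scores).

This module defines the event grid (:class:`EventSet`), orderings over it,
the expected-trajectory evaluation, and the per-subject stage likelihoods
that the fitting and assignment modules build on.  All likelihood work is
done in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import InvalidConfigError

__all__ = [
    "EventSet",
    "trajectory",
    "stage_z_matrix",
    "stage_loglik_matrix",
    "stage_likelihood",
    "subject_marginal",
    "is_valid_ordering",
    "random_ordering",
    "all_orderings",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class EventSet:
    """The event grid: biomarkers crossed with their z thresholds.

    Parameters
    ----------
    biomarkers
        Ordered biomarker names.
    z_levels
        Per-biomarker strictly increasing threshold tuples (default
        ``(1, 2, 3)`` for every biomarker).
    z_max
        Per-biomarker trajectory ceiling, strictly above the last
        threshold (default 5).

    Events are indexed ``0..E-1`` in biomarker-major order; within one
    biomarker, event ids increase with the threshold.
    """

    biomarkers: tuple[str, ...]
    z_levels: tuple[tuple[float, ...], ...]
    z_max: tuple[float, ...]

    def __post_init__(self):
        if len(self.biomarkers) == 0:
            raise InvalidConfigError("at least one biomarker is required")
        if len(self.z_levels) != len(self.biomarkers) or len(self.z_max) != len(self.biomarkers):
            raise InvalidConfigError("z_levels and z_max must match the number of biomarkers")
        for name, levels, zmax in zip(self.biomarkers, self.z_levels, self.z_max):
            if len(levels) == 0:
                raise InvalidConfigError(f"biomarker {name!r} has no thresholds")
            if any(b <= a for a, b in zip(levels, levels[1:])):
                raise InvalidConfigError(f"thresholds for {name!r} must be strictly increasing")
            if zmax <= levels[-1]:
                raise InvalidConfigError(
                    f"z_max for {name!r} must exceed its largest threshold ({levels[-1]})"
                )

    @classmethod
    def from_biomarkers(
        cls,
        biomarkers: Sequence[str],
        z_levels: Sequence[float] = (1.0, 2.0, 3.0),
        z_max: float = 5.0,
    ) -> "EventSet":
        """Build an event set with the same thresholds for every biomarker."""
        names = tuple(str(b) for b in biomarkers)
        levels = tuple(tuple(float(z) for z in z_levels) for _ in names)
        return cls(names, levels, tuple(float(z_max) for _ in names))

    @property
    def n_biomarkers(self) -> int:
        return len(self.biomarkers)

    @property
    def n_events(self) -> int:
        """Total number of events E."""
        return sum(len(l) for l in self.z_levels)

    @property
    def event_biomarker(self) -> np.ndarray:
        """Biomarker index of each event id (length E)."""
        cached = self.__dict__.get("_event_biomarker")
        if cached is None:
            cached = np.repeat(np.arange(self.n_biomarkers), [len(l) for l in self.z_levels])
            object.__setattr__(self, "_event_biomarker", cached)
        return cached

    @property
    def event_z(self) -> np.ndarray:
        """Threshold value of each event id (length E)."""
        cached = self.__dict__.get("_event_z")
        if cached is None:
            cached = np.concatenate([np.asarray(l, float) for l in self.z_levels])
            object.__setattr__(self, "_event_z", cached)
        return cached

    def event_label(self, event_id: int) -> str:
        b = self.event_biomarker[event_id]
        return f"{self.biomarkers[b]}:z>={self.event_z[event_id]:g}"

    def to_dict(self) -> dict:
        return {
            "biomarkers": list(self.biomarkers),
            "z_levels": [list(l) for l in self.z_levels],
            "z_max": list(self.z_max),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventSet":
        return cls(
            tuple(d["biomarkers"]),
            tuple(tuple(float(z) for z in l) for l in d["z_levels"]),
            tuple(float(z) for z in d["z_max"]),
        )


def is_valid_ordering(event_set: EventSet, ordering: np.ndarray) -> bool:
    """True iff ``ordering`` permutes all events and respects, for every
    biomarker, the increasing order of its thresholds."""
    ordering = np.asarray(ordering)
    E = event_set.n_events
    if ordering.shape != (E,) or not np.array_equal(np.sort(ordering), np.arange(E)):
        return False
    pos = np.empty(E, dtype=int)
    pos[ordering] = np.arange(E)
    bm = event_set.event_biomarker
    for b in range(event_set.n_biomarkers):
        p = pos[bm == b]  # event ids increase with threshold within a biomarker
        if np.any(np.diff(p) <= 0):
            return False
    return True


def _check_ordering(event_set: EventSet, ordering: np.ndarray) -> np.ndarray:
    ordering = np.asarray(ordering, dtype=int)
    if not is_valid_ordering(event_set, ordering):
        raise InvalidConfigError(
            "ordering is not a valid permutation of the event grid "
            "(within-biomarker threshold order must be preserved)"
        )
    return ordering


def random_ordering(event_set: EventSet, rng: np.random.Generator) -> np.ndarray:
    """Uniform random valid ordering (uniform over interleavings)."""
    bm = event_set.event_biomarker
    slots = rng.permutation(bm)  # multiset of biomarker labels in random order
    ordering = np.empty(event_set.n_events, dtype=int)
    next_event = {}
    start = 0
    for b, levels in enumerate(event_set.z_levels):
        next_event[b] = start
        start += len(levels)
    for i, b in enumerate(slots):
        ordering[i] = next_event[b]
        next_event[b] += 1
    return ordering


def all_orderings(event_set: EventSet) -> list[np.ndarray]:
    """Exhaustively enumerate every valid ordering (small E only)."""
    counts = [len(l) for l in event_set.z_levels]
    starts = np.cumsum([0] + counts[:-1])
    out: list[np.ndarray] = []

    def rec(prefix: list[int], used: list[int]):
        if len(prefix) == event_set.n_events:
            out.append(np.array(prefix, dtype=int))
            return
        for b in range(event_set.n_biomarkers):
            if used[b] < counts[b]:
                used[b] += 1
                prefix.append(int(starts[b] + used[b] - 1))
                rec(prefix, used)
                prefix.pop()
                used[b] -= 1

    rec([], [0] * event_set.n_biomarkers)
    return out


def _anchors(event_set: EventSet, ordering: np.ndarray, b: int):
    """Interpolation anchors (stage, z) for biomarker ``b``."""
    E = event_set.n_events
    pos = np.empty(E, dtype=int)
    pos[ordering] = np.arange(1, E + 1)  # stage at which each event completes
    ids = np.flatnonzero(event_set.event_biomarker == b)
    xp = np.concatenate(([0.0], pos[ids].astype(float)))
    fp = np.concatenate(([0.0], event_set.event_z[ids]))
    if xp[-1] < E:
        xp = np.append(xp, float(E))
        fp = np.append(fp, event_set.z_max[b])
    # if the last threshold sits at stage E the trajectory jumps to z_max
    # exactly at E; interpolation below E uses the threshold anchor.
    return xp, fp


def trajectory(
    event_set: EventSet,
    ordering: np.ndarray,
    biomarker: int | str,
    k,
) -> np.ndarray | float:
    """Expected z-score ``g_b(k)`` of one biomarker at (real) stage ``k``.

    Piecewise-linear through (0, 0), each of the biomarker's threshold
    events at its stage position, and (E, z_max).  Defined for
    ``k in [0, E]``; monotone nondecreasing; ``g_b(E) = z_max`` exactly.
    """
    ordering = _check_ordering(event_set, ordering)
    if isinstance(biomarker, str):
        biomarker = event_set.biomarkers.index(biomarker)
    k_arr = np.asarray(k, dtype=float)
    E = event_set.n_events
    if np.any(k_arr < 0) or np.any(k_arr > E):
        raise ValueError(f"stage k must lie in [0, {E}]")
    xp, fp = _anchors(event_set, ordering, biomarker)
    g = np.interp(k_arr, xp, fp)
    g = np.where(k_arr == E, event_set.z_max[biomarker], g)
    return float(g) if np.isscalar(k) else g


def stage_z_matrix(event_set: EventSet, ordering: np.ndarray) -> np.ndarray:
    """Expected z at every integer stage: matrix ``G`` of shape (B, E+1)."""
    E = event_set.n_events
    stages = np.arange(E + 1, dtype=float)
    G = np.empty((event_set.n_biomarkers, E + 1))
    for b in range(event_set.n_biomarkers):
        xp, fp = _anchors(event_set, ordering, b)
        G[b] = np.interp(stages, xp, fp)
        G[b, E] = event_set.z_max[b]
    return G


def stage_z_batch(event_set: EventSet, orderings: np.ndarray) -> np.ndarray:
    """Vectorized :func:`stage_z_matrix` for a batch of orderings.

    Parameters
    ----------
    orderings
        (n_cand, E) integer array, one valid ordering per row.

    Returns
    -------
    (n_cand, B, E+1) array of expected z per candidate, biomarker, stage.
    """
    es = event_set
    orderings = np.atleast_2d(np.asarray(orderings, dtype=int))
    ncand, E = orderings.shape
    B = es.n_biomarkers
    counts = [len(l) for l in es.z_levels]
    pos = np.empty_like(orderings)
    np.put_along_axis(pos, orderings, np.broadcast_to(np.arange(1, E + 1), orderings.shape), axis=1)

    if len(set(counts)) != 1:
        return np.stack([stage_z_matrix(es, o) for o in orderings])

    L = counts[0]
    ids = np.arange(E).reshape(B, L)
    A = L + 2  # anchors per biomarker: 0, thresholds, E
    xp = np.empty((ncand, B, A))
    xp[..., 0] = 0.0
    xp[..., 1 : L + 1] = pos[:, ids]
    xp[..., L + 1] = float(E)
    fp = np.empty((B, A))
    fp[:, 0] = 0.0
    fp[:, 1 : L + 1] = np.asarray(es.z_levels, dtype=float)
    fp[:, L + 1] = np.asarray(es.z_max, dtype=float)

    k = np.arange(E + 1, dtype=float)
    seg = np.clip((k[None, None, :, None] >= xp[:, :, None, :]).sum(axis=-1) - 1, 0, A - 2)
    ci = np.arange(ncand)[:, None, None]
    bi = np.arange(B)[None, :, None]
    x0, x1 = xp[ci, bi, seg], xp[ci, bi, seg + 1]
    f0, f1 = fp[bi, seg], fp[bi, seg + 1]
    G = f0 + (f1 - f0) * (k[None, None, :] - x0) / np.maximum(x1 - x0, 1e-12)
    G[..., E] = np.asarray(es.z_max, dtype=float)[None, :]
    return G


def _as_sigma(event_set: EventSet, sigma) -> np.ndarray:
    s = np.broadcast_to(np.asarray(sigma, dtype=float), (event_set.n_biomarkers,))
    if np.any(s <= 0):
        raise InvalidConfigError("sigma must be positive")
    return s


def stage_loglik_matrix(
    Z: np.ndarray,
    event_set: EventSet,
    ordering: np.ndarray,
    sigma=1.0,
    *,
    G: np.ndarray | None = None,
) -> np.ndarray:
    """Log density of each subject at each integer stage.

    Parameters
    ----------
    Z
        (n, B) z-score matrix.
    G
        Optional precomputed ``stage_z_matrix`` (skips the validity check;
        used by the fitter's inner loops).

    Returns
    -------
    (n, E+1) array with entry ``log prod_b N(z_b; g_b(k), sigma_b)``.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if not np.all(np.isfinite(Z)):
        raise ValueError("z-scores must be finite")
    if Z.shape[1] != event_set.n_biomarkers:
        raise ValueError("z row length must equal the number of biomarkers")
    s = _as_sigma(event_set, sigma)
    if G is None:
        G = stage_z_matrix(event_set, _check_ordering(event_set, ordering))
    Zs = Z / s
    Gs = G / s[:, None]
    const = float(np.log(s).sum()) + 0.5 * event_set.n_biomarkers * _LOG_2PI
    # ||z - g||^2 = ||z||^2 - 2 z.g + ||g||^2, vectorised over (subject, stage)
    sq = (Zs**2).sum(axis=1)[:, None] - 2.0 * Zs @ Gs + (Gs**2).sum(axis=0)[None, :]
    return -0.5 * sq - const


def stage_likelihood(z_row, event_set: EventSet, ordering, k: int, sigma=1.0) -> float:
    """Density of one subject at integer stage ``k`` (natural scale)."""
    k = int(k)
    if not 0 <= k <= event_set.n_events:
        raise ValueError(f"stage k must lie in [0, {event_set.n_events}]")
    ll = stage_loglik_matrix(np.atleast_2d(z_row), event_set, ordering, sigma)
    return float(np.exp(ll[0, k]))


def subject_marginal(z_row, event_set: EventSet, ordering, sigma=1.0) -> float:
    """Log marginal ``log P(x | S)`` under a uniform stage prior on 0..E."""
    ll = stage_loglik_matrix(np.atleast_2d(z_row), event_set, ordering, sigma)
    return float(logsumexp(ll[0]) - np.log(event_set.n_events + 1))
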