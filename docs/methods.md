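# Methods

## The model

`sustainz` implements subtype-and-stage inference (SuStaIn) with the
piecewise-linear z-score event model for volumetric atrophy biomarkers.
The data are per-subject atrophy z-scores `z_ib` (positive = atrophy
relative to matched healthy controls).  An *event* is a biomarker crossing
a fixed threshold (defaults `z = 1, 2, 3`); with `B` biomarkers and `L`
thresholds the grid has `E = B·L` events.  A *subtype* `c` is an ordering
`S_c` of all `E` events that respects the within-biomarker threshold order;
a subject's *stage* `k ∈ {0, …, E}` means the first `k` events of its
subtype's ordering have occurred.

Between events, each biomarker's expected z rises linearly: the trajectory
`g_b(k; S)` interpolates through `(0, 0)`, each of the biomarker's
threshold events at its stage position, and `(E, z_max)` with `z_max = 5`
by default (a ceiling beyond the last threshold; configurable).  Observed
z-scores are Gaussian around the trajectory with `σ_b = 1` (the natural
choice for control-referenced z-scores; configurable).  The subject
marginal under a subtype averages the stage likelihood over a uniform
stage prior including stage 0:

    P(x | S) = (1/(E+1)) Σ_{k=0..E} Π_b N(z_b ; g_b(k; S), σ_b)

and the dataset log-likelihood is the usual mixture form
`Σ_i log Σ_c f_c P(x_i | S_c)` with mixing fractions `f_c`.

Negative z-scores (better than controls) enter the Gaussian untruncated;
truncating them would bias subjects toward stage 0.

## Fitting

* **C = 1** — multi-start greedy ascent over orderings: repeated
  single-event repositioning passes until no move improves the marginal
  likelihood, from 25 starts by default (one data-driven start ordering
  events by threshold divided by the biomarker's mean z, the rest uniform
  random interleavings).
* **C → C + 1** — each current cluster's hard-assigned subjects are split
  in two, each half fitted as a single trajectory, and all orderings and
  fractions jointly re-optimized by EM (exact responsibilities, fraction
  update, weighted greedy ascent per ordering) until the relative
  log-likelihood change is below 1e-6 or 100 iterations.  Split
  candidates: one 2-means split of the *shape-normalized* z rows (each
  row scaled to unit length, so the split follows the spatial pattern
  rather than overall severity) plus three random halves.  Random halves
  alone routinely converge to blended local optima when orderings overlap
  — in our experiments the shape split recovered the ground-truth pair
  where every random-half start stalled ~25 log-likelihood units short —
  so the data-driven candidate is always included; the best EM endpoint
  across candidates is kept.
* **Ordering uncertainty** — Metropolis MCMC at fixed fractions: one
  iteration proposes swapping two uniformly chosen event positions in one
  uniformly chosen subtype's ordering and rejects proposals that break
  the within-biomarker threshold order (the chain stays put, keeping the
  kernel symmetric on the constrained space; adjacent transpositions of
  different-biomarker events connect every valid interleaving, so the
  chain is ergodic).  Positional densities (event × position frequencies)
  are accumulated over all iterations; samples are thinned 1:10.
* **Number of subtypes** — ten-fold cross-validation.  Folds are a seeded
  stratified partition computed on sorted subject ids (hence invariant to
  row order); `CVIC(C) = −2 Σ_folds heldout-loglik(C)`.  The selected C
  is the *smallest* C whose CVIC lies within `parsimony_delta` of the
  minimum.  `parsimony_delta` defaults to 5.0: a CVIC gap is on the
  deviance scale, and a gap below ~5 is conventionally weak evidence for
  the more complex model, so complexity is only added when it buys a
  clearly larger gap.  Inside cross-validation the optimization surface
  is evaluated, not explored, so fewer greedy restarts suffice
  (`cv_n_starts`, `n_split_tries` configurable).

## Assignment

Stage-0 likelihood `L_0 = Π_b N(z_b; 0, σ_b)` is compared against each
subtype's likelihood summed over post-onset stages,
`L_c = f_c (1/E) Σ_{k=1..E} P(x | S_c, k)`.  Stage 0 is excluded from the
subtype sum because it *is* the alternative hypothesis; the comparison
would otherwise be biased toward subtypes.  Subjects with
`L_0 ≥ max_c L_c` are *normal-appearing* (NA); ties resolve to NA
(conservative).  The reported stage is the posterior-expected stage over
the full `(c, k)` grid, `k = 0..E`, averaging over subtypes (an
ML-subtype-only variant is available).  Follow-up visits are always
scored with the baseline-fitted model, never refitted, so longitudinal
stability reflects the subjects, not the fit.

Longitudinal stability reports (a) the proportion with the same
assignment at both visits or an NA→subtype transition, and (b) the
proportion with the same subtype among pairs subtypeable at both visits;
stage progression uses `|Δstage| < 0.5` as "same" (half an event is below
the resolution of the stage grid).

## Synthetic cohorts

The generator emulates a multi-scanner volumetric study: a healthy-control
cohort plus a patient cohort drawn from `C` latent subtypes.  Raw volumes
are built as `baseline · (1 + age, sex, TIV and scanner effects) + noise`,
with defaults on realistic scales (cortical GM ≈ 470 ml, cord area ≈ 72
mm², scanner offsets ±1%, residual SD 2% of baseline).  Patients invert
the z-score model: the expected z at the subject's true stage is mapped to
a volume deficit of `z · noise_sd`, so that after perfect adjustment the
observed z is the trajectory value plus unit-variance noise — the exact
regime the fitter assumes.

Defaults define the reference study conditions used throughout the tests:
600 patients, 8 biomarkers, thresholds 1/2/3 (E = 24), two subtypes with
fractions 0.6/0.4, true stages uniform on 1..E, unit z-noise.  The default
ground-truth orderings are *region-sequential*: each biomarker completes
its threshold ladder before the next region begins, with subtype 0
following the panel order (cortical-first) and subtype 1 the reverse
(cord-first).  This realizes strongly separated trajectories — the regime
the recovery experiments are meant to probe.  With heavily interleaved
orderings the subtypes' early stages become nearly indistinguishable and
even the generating model cannot assign early-stage subjects reliably;
that is a property of such configurations, not of the estimator, and the
generator accepts arbitrary valid orderings for studying it.

Clinical outcomes are stage-/subtype-linked: EDSS is a linear function of
stage plus noise, snapped to the real 0–10 half-point grid (so the ≥1.0 /
≥0.5 progression thresholds are exercised exactly); relapse counts are
Poisson with subtype-specific rates; progression times are exponential
with subtype- and stage-dependent hazards under administrative censoring;
follow-up EDSS is generated consistently with the progression flag.
Follow-up scans advance the true stage by a Poisson (hence non-negative)
increment — atrophy is irreversible in this model.  No published
cohort-level effect sizes link stage to these outcomes at generation
scale, so the defaults are free parameters chosen once at plausible
magnitudes (e.g. 0.12 EDSS points per stage), not estimates of any
cohort.

What the generator does *not* emulate: non-Gaussian measurement error,
site-by-covariate interactions, longitudinal within-subject correlation
of raw volumes, missing-data mechanisms, or lesion-driven segmentation
bias.  Passing recovery tests therefore show the estimator is correct
under its own assumptions at realistic sizes — not that real cohorts
satisfy those assumptions.

## Preprocessing

Batch/covariate adjustment fits, per biomarker, OLS on scanner indicators
+ centered covariates (age, sex, TIV) + group indicators, and subtracts
only the scanner and covariate contributions (limma-style
`removeBatchEffect` semantics): group effects survive harmonization.  If
diagnostic group is confounded with scanner the design is rank-deficient
and the fit refuses with the collinear columns named — silently adjusting
a confounded design would absorb genuine disease effects; an
`allow_confounded` override drops the group term instead.  TIV is used at
the adjustment step only, not again at the z-step.

Controls are matched 1:1 by greedy nearest-neighbour on standardized age
with exact sex match, in a seed-randomized patient order without
replacement (deterministic and testable; matching quality differences
versus optimal matching are negligible at the HC:patient ratios
simulated).  Z-scores come from per-biomarker OLS of the adjusted volumes
on age and sex in the matched controls (Gaussian identity-link — volumes
are continuous), standardized by the control residual SD (df = n − p) and
sign-flipped so positive z means atrophy.

## Characterization

Rank tests adjust for covariates by OLS residualization before ranking.
Kruskal–Wallis is followed by Dunn's pairwise test with tie correction;
chi-squared switches to Fisher's exact for 2×2 tables with any expected
cell below 5; a 2×2 table with an empty outcome margin carries no
evidence and reports p = 1.  Fisher's exact is the standard two-sided sum
of hypergeometric probabilities ≤ the observed table's; a mid-p variant
is available.  Stage correlations are partial Spearman (both variables
residualized), with education additionally included for cognitive scores.
Exact conditional tests on 2×2 lattices are conservative by construction:
the true type-I error of two-sided Fisher at α = 0.05, computed by full
binomial-lattice enumeration, is 0.035 with 100 subjects per group and
still 0.047 with 1000 — a property of the test, not of this
implementation, which the calibration suite verifies against the
enumerated level directly.  Cox models (lifelines) are reported
univariate, multivariate and after
backward elimination with retention threshold p < 0.10 — the conventional
liberal stepwise cutoff; one-vs-all regional contrasts are OLS
`z ~ subtype-indicator + weighted stage`, reporting the indicator's t.
Benjamini–Hochberg families are explicit: all pairwise contrasts of one
variable form one family; stage-correlation variables form one family per
subtype stratum; treatment-response pairwise tests one family per
endpoint.

## Numerical choices and problem sizes

All likelihood work is in log space with log-sum-exp reductions; candidate
orderings in the greedy pass are scored by one batched matrix product.
EM tolerance 1e-6 (relative), greedy improvement tolerance 1e-10, MCMC
marginal columns cached by ordering (bounded cache).  Exactness tests run
on event grids small enough to enumerate (E ≤ 6, 20 valid orderings);
recovery and model-selection experiments use the reference cohort
(n = 600, E = 24) with 5 replicate seeds, 2×10⁵ MCMC iterations for
posterior-exactness checks, and reduced greedy restarts inside
cross-validation.  These sizes were chosen so the full suite and the
acceptance script each complete comfortably on a single CPU while keeping
every Monte-Carlo tolerance at least three standard errors wide.

## Known limitations

* The z-score event model assumes monotone progression; regression of
  atrophy (e.g. pseudo-atrophy under therapy) is outside the model.
* σ is not estimated from data; miscalibrated input z-scores shift the
  NA boundary.
* CVIC compares fitted mixtures, not the truth; with strongly overlapping
  orderings the C = 2 advantage shrinks with separation, and the selector
  will (correctly) prefer C = 1 when subtypes are not distinguishable.
* Greedy + EM is a local optimizer; the shape-split initialization
  removes the dominant failure mode we observed, but global optimality is
  not guaranteed for large E.
* The stepwise Cox procedure inherits the usual caveats of stepwise
  selection; it is provided because the reference analysis uses it, with
  univariate and full multivariate tables always reported alongside.
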