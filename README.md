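# sustainz

Subtype-and-stage inference for brain and spinal cord atrophy z-scores.

Autoimmune demyelinating diseases such as neuromyelitis optica spectrum
disorder (NMOSD) and multiple sclerosis (MS) atrophy the CNS in
heterogeneous spatial patterns that evolve over the disease course.
`sustainz` is a reusable pipeline for identifying such *spatiotemporal
atrophy subtypes* from cross-sectional volumetric biomarkers (regional
grey-matter volumes, white matter, brainstem, mean upper cervical cord
area), written for imaging researchers who have per-subject volume tables
and want subtype labels, disease stages, and their clinical correlates.

## The model

An *event* is a biomarker's atrophy z-score crossing a threshold
(z = 1, 2, 3 by default).  A subtype is an ordering `S` of all `E` events;
a subject's stage `k ∈ {0..E}` counts the events that have occurred.
Expected z-scores follow a piecewise-linear trajectory `g_b(k; S)` through
the thresholds, and observations are Gaussian around it:

    P(x | S, k) = Π_b N(z_b ; g_b(k; S), σ_b),      σ_b = 1
    P(x | S)    = (1/(E+1)) Σ_k P(x | S, k)
    log L       = Σ_i log Σ_c f_c P(x_i | S_c)

The mixture over orderings `S_c` with fractions `f_c` is fitted by greedy
ascent + EM with hierarchical cluster splitting, ordering uncertainty is
sampled by constrained Metropolis MCMC, and the number of subtypes is
chosen by ten-fold cross-validation (CVIC = −2 × summed held-out
log-likelihood, smallest C within a parsimony margin of the minimum).
Subjects whose data are best explained by stage 0 are flagged
*normal-appearing* (NA); all others get a most-likely subtype and a
probability-weighted stage.  See `docs/methods.md` for the full account.

The package also ships the surrounding study machinery: batch/covariate
harmonization that preserves group effects, 1:1 age/sex control matching,
HC-referenced z-scoring (positive z = atrophy), a synthetic-cohort
generator with known ground truth, and the clinical characterization
toolbox (Kruskal–Wallis + Dunn, Fisher/chi-squared, partial Spearman,
Cox models with stepwise backward selection, treatment-response tables,
Benjamini–Hochberg FDR).

## Worked example

```python
import pandas as pd
from sustainz import SimConfig, generate_hc_cohort, generate_patient_cohort
from sustainz.preprocess import (adjust_batch_covariates, match_controls,
                                 compute_zscores, biomarker_columns)
from sustainz.fit import fit_sustain
from sustainz.assign import assign_table, subtype_prevalence

# a synthetic multi-scanner study: 400 controls, 300 patients from two
# latent subtypes (cortical-first vs cord-first), known ground truth
cfg = SimConfig(n_hc=400, n_patients=300, seed=42)
hc = generate_hc_cohort(cfg)
patients, truth = generate_patient_cohort(cfg)

table = pd.concat([hc, patients], ignore_index=True)
adjusted = adjust_batch_covariates(table)           # scanner + age/sex/TIV out
hcs  = adjusted[adjusted.group == "HC"]
pats = adjusted[adjusted.group != "HC"]
matches = match_controls(pats, hcs, seed=42)        # greedy 1:1, exact sex
matched = hcs.set_index("subject_id").loc[matches.hc_id].reset_index()
Z = compute_zscores(pats, matched, biomarker_columns(adjusted))

fit = fit_sustain(Z, cfg.event_set, c_max=3, seed=42, n_starts=8,
                  cv_n_starts=3, mcmc_iters=2000)
print("CVIC:", {c: round(v, 1) for c, v in fit.cvic.items()})
print("selected C =", fit.selected_c)
print("fractions:", [round(m.fraction, 3) for m in fit.selected_models])

assignments = assign_table(Z, fit)
print(subtype_prevalence(assignments).round(1))
print("mean weighted stage:", round(assignments.weighted_stage.mean(), 2))
```

Output:

```
CVIC: {1: 10718.3, 2: 8319.3, 3: 8332.5}
selected C = 2
fractions: [0.567, 0.433]
ml_subtype
subtype_0    54.7
subtype_1    38.0
NA            7.3
Name: percent, dtype: float64
mean weighted stage: 12.94
```

Reading this: cross-validation strongly prefers two subtypes over one
(CVIC drops by ~2400) and gains nothing from a third (+13, within the
parsimony margin's reach of neither), so `C = 2` is selected — matching
the generating truth.  The estimated mixing fractions (0.57/0.43) sit near
the generating 0.6/0.4; 7.3% of patients are normal-appearing (mostly
early-stage subjects whose z-scores are indistinguishable from noise), and
the mean posterior-weighted stage of ~13 of 24 reflects the uniform
generating stage distribution.

A command-line interface wraps the same pipeline for shell use:

```bash
sustainz simulate --seed 42 --out sim_out
sustainz run --config run.yaml     # preprocess -> fit -> assign -> characterize
```

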