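"""Shared fixtures: tiny event sets and simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

from sustainz.model import EventSet
from sustainz.simulate import SimConfig


@pytest.fixture
def es1():
    """Single biomarker, one threshold: E = 1."""
    return EventSet.from_biomarkers(["a"], [1.0], 2.0)


@pytest.fixture
def es4():
    """Two biomarkers x two thresholds: E = 4, 6 valid orderings."""
    return EventSet.from_biomarkers(["a", "b"], [1.0, 2.0], 5.0)


@pytest.fixture
def es6():
    """Two biomarkers x three thresholds: E = 6, 20 valid orderings."""
    return EventSet.from_biomarkers(["a", "b"], [1.0, 2.0, 3.0], 5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-subtype cohort with ground truth (session-cached)."""
    from sustainz.preprocess import (
        adjust_batch_covariates,
        biomarker_columns,
        compute_zscores,
        match_controls,
    )
    from sustainz.simulate import generate_hc_cohort, generate_patient_cohort

    cfg = SimConfig(n_hc=260, n_patients=240, seed=7)
    hc = generate_hc_cohort(cfg)
    pat, truth = generate_patient_cohort(cfg)
    full = pd.concat([hc, pat], ignore_index=True)
    adj = adjust_batch_covariates(full)
    hcs = adj[adj["group"] == "HC"]
    pats = adj[adj["group"] != "HC"]
    matches = match_controls(pats, hcs, seed=7)
    matched = hcs.set_index("subject_id").loc[matches["hc_id"]].reset_index()
    Z = compute_zscores(pats, matched, biomarker_columns(adj))
    return {"config": cfg, "Z": Z, "truth": truth, "patients": pats, "hcs": hcs}
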