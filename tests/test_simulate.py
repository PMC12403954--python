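"""Generator fidelity: seeded determinism, batch/covariate structure,
trajectory and mixing convergence, clinical nulls, follow-up monotonicity."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from sustainz.errors import InvalidConfigError
from sustainz.model import stage_z_matrix
from sustainz.simulate import (
    ClinicalModel,
    SimConfig,
    generate_clinical,
    generate_followup,
    generate_hc_cohort,
    generate_patient_cohort,
)


def test_seeded_determinism_byte_identical(tmp_path):
    cfg = SimConfig(n_hc=50, n_patients=40, seed=123)
    a1, a2 = generate_hc_cohort(cfg), generate_hc_cohort(cfg)
    p1, t1 = generate_patient_cohort(cfg)
    p2, t2 = generate_patient_cohort(cfg)
    c1, c2 = generate_clinical(t1, cfg), generate_clinical(t2, cfg)
    f1, f2 = (a1.to_csv(tmp_path / "a1.csv"), a2.to_csv(tmp_path / "a2.csv"))
    assert (tmp_path / "a1.csv").read_bytes() == (tmp_path / "a2.csv").read_bytes()
    pd.testing.assert_frame_equal(p1, p2)
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(c1, c2)


def test_invalid_configs_rejected():
    with pytest.raises(InvalidConfigError):
        SimConfig(noise_sd=0.0)
    with pytest.raises(InvalidConfigError):
        SimConfig(fractions=(0.7, 0.4))
    with pytest.raises(InvalidConfigError):
        SimConfig(clinical_model=ClinicalModel(relapse_rates=(-1.0, 1.0)))
    cfg = SimConfig()
    bad = [o.copy() for o in cfg.resolved_orderings()]
    bad[0][[0, 1]] = bad[0][[1, 0]]  # swap a biomarker's z1/z2 events
    with pytest.raises(InvalidConfigError):
        SimConfig(orderings=bad)


def test_hc_batch_offset_recovered_in_means():
    """Configured +1% scanner offset appears as the between-batch mean gap."""
    cfg = SimConfig(
        n_hc=10_000,
        batch_offsets={"A": 0.0, "B": 0.01},
        age_slope=0.0,
        sex_offset=0.0,
        tiv_slope=0.0,
        seed=5,
    )
    hc = generate_hc_cohort(cfg)
    b0 = cfg.baselines[0]
    gap = hc.groupby("scanner")["cortical_gm"].mean()
    expected = 0.01 * b0
    se = cfg.noise_sd * b0 / np.sqrt(len(hc) / 2)
    assert abs((gap["B"] - gap["A"]) - expected) < 4 * se


def test_zero_noise_single_batch_degenerates_to_baseline():
    cfg = SimConfig(
        n_hc=20,
        noise_sd=1e-12,
        batch_offsets={"A": 0.0},
        age_slope=0.0,
        sex_offset=0.0,
        tiv_slope=0.0,
        seed=2,
    )
    hc = generate_hc_cohort(cfg)
    for j, b in enumerate(cfg.biomarkers):
        np.testing.assert_allclose(hc[b], cfg.baselines[j], rtol=1e-9)


def test_patient_mixing_fractions_converge():
    cfg = SimConfig(n_patients=20_000, fractions=(0.6, 0.4), seed=11)
    _, truth = generate_patient_cohort(cfg)
    props = truth["true_subtype"].value_counts(normalize=True)
    assert abs(props[0] - 0.6) < 0.02
    assert abs(props[1] - 0.4) < 0.02


def test_per_stage_mean_z_matches_trajectory():
    """Empirical mean z per (subtype, stage) tracks g_b(k) within 3 SE."""
    cfg = SimConfig(n_patients=10_000, seed=13)
    pat, truth = generate_patient_cohort(cfg)
    es = cfg.event_set
    G = [stage_z_matrix(es, o) for o in cfg.resolved_orderings()]
    scale = cfg.noise_sd * cfg.baselines
    # invert the volume model exactly (known covariates, no estimation step)
    from sustainz.simulate import _expected_volumes

    expected = _expected_volumes(cfg, pat)
    z_obs = (expected - pat[list(cfg.biomarkers)].to_numpy()) / scale
    for c in range(cfg.n_subtypes):
        for k in (1, es.n_events // 2, es.n_events):
            m = (truth["true_subtype"] == c) & (truth["true_stage"] == k)
            if m.sum() < 30:
                continue
            mean_z = z_obs[m.to_numpy()].mean(axis=0)
            se = 1.0 / np.sqrt(m.sum())
            np.testing.assert_allclose(mean_z, G[c][:, k], atol=3 * se * np.sqrt(8))


def test_stage0_patients_have_zero_mean_z():
    p = np.zeros(SimConfig().event_set.n_events + 1)
    p[0] = 1.0
    cfg = SimConfig(n_patients=4000, stage_distribution=p, seed=17)
    pat, truth = generate_patient_cohort(cfg)
    from sustainz.simulate import _expected_volumes

    scale = cfg.noise_sd * cfg.baselines
    z_obs = (_expected_volumes(cfg, pat) - pat[list(cfg.biomarkers)].to_numpy()) / scale
    assert (truth["true_stage"] == 0).all()
    np.testing.assert_allclose(z_obs.mean(axis=0), 0.0, atol=3 / np.sqrt(len(pat)))


class TestClinical:
    def test_null_hazard_ratio_equal_event_rates(self):
        cm = ClinicalModel(hazard_subtype_hr=(1.0, 1.0), hazard_stage_hr=1.0)
        cfg = SimConfig(n_patients=4000, clinical_model=cm, seed=19)
        _, truth = generate_patient_cohort(cfg)
        clin = generate_clinical(truth, cfg)
        rates = clin.groupby(truth["true_subtype"].to_numpy())["progression_event"].mean()
        assert abs(rates[0] - rates[1]) < 4 * np.sqrt(0.25 / 1000)

    def test_hazard_ratio_two_doubles_early_event_rate(self):
        """Exponential closed form: P(T<t) ~ h*t for small t, so the
        event-rate ratio at a short horizon approaches the hazard ratio."""
        cm = ClinicalModel(
            hazard_subtype_hr=(1.0, 2.0), hazard_stage_hr=1.0, hazard_base=0.002, censor_time=600.0
        )
        cfg = SimConfig(n_patients=30_000, fractions=(0.5, 0.5), clinical_model=cm, seed=23)
        _, truth = generate_patient_cohort(cfg)
        clin = generate_clinical(truth, cfg)
        horizon = 10.0
        early = clin["followup_time"] <= horizon
        sub = truth["true_subtype"].to_numpy()
        r0 = (early & (clin["progression_event"] == 1))[sub == 0].mean()
        r1 = (early & (clin["progression_event"] == 1))[sub == 1].mean()
        assert r1 / r0 == pytest.approx(2.0, rel=0.25)

    def test_zero_stage_slope_kills_stage_edss_association(self):
        cm = ClinicalModel(edss_stage_slope=0.0)
        cfg = SimConfig(n_patients=3000, clinical_model=cm, seed=29)
        _, truth = generate_patient_cohort(cfg)
        clin = generate_clinical(truth, cfg)
        rho = spearmanr(truth["true_stage"], clin["edss"]).statistic
        assert abs(rho) < 0.05

    def test_edss_on_half_point_grid(self):
        cfg = SimConfig(n_patients=500, seed=31)
        _, truth = generate_patient_cohort(cfg)
        clin = generate_clinical(truth, cfg)
        for col in ("edss", "followup_edss"):
            v = clin[col].to_numpy()
            assert np.all(np.abs(v * 2 - np.round(v * 2)) < 1e-9)
            assert v.min() >= 0 and v.max() <= 10

    def test_followup_edss_consistent_with_progression_flag(self):
        from sustainz.characterize import flag_edss_progression

        cfg = SimConfig(n_patients=2000, seed=37)
        _, truth = generate_patient_cohort(cfg)
        clin = generate_clinical(truth, cfg)
        flags = flag_edss_progression(clin["edss"].to_numpy(), clin["followup_edss"].to_numpy())
        assert (np.asarray(flags) == clin["progression_event"].astype(bool).to_numpy()).all()

    def test_empty_truth_rejected(self):
        cfg = SimConfig(seed=1)
        with pytest.raises(InvalidConfigError):
            generate_clinical(pd.DataFrame(columns=["subject_id"]), cfg)


class TestFollowup:
    def test_stage_never_decreases(self):
        cfg = SimConfig(n_patients=2000, seed=41)
        _, truth = generate_patient_cohort(cfg)
        fu = generate_followup(truth, cfg)
        assert (fu["true_followup_stage"].to_numpy() >= truth["true_stage"].to_numpy()).all()

    def test_degenerate_increment_preserves_z_distribution(self):
        cfg = SimConfig(n_patients=3000, followup_stage_increment_mean=0.0, seed=43)
        pat, truth = generate_patient_cohort(cfg)
        fu = generate_followup(truth, cfg)
        assert (fu["true_followup_stage"].to_numpy() == truth["true_stage"].to_numpy()).all()
        from sustainz.simulate import _expected_volumes

        scale = cfg.noise_sd * cfg.baselines
        z_bl = (_expected_volumes(cfg, pat) - pat[list(cfg.biomarkers)].to_numpy()) / scale
        z_fu = (_expected_volumes(cfg, fu) - fu[list(cfg.biomarkers)].to_numpy()) / scale
        # same true z per subject: per-subject difference is pure noise (SD sqrt(2))
        diff = z_fu - z_bl
        assert abs(diff.mean()) < 0.05
        assert diff.std() == pytest.approx(np.sqrt(2.0), abs=0.05)

    def test_large_increment_raises_mean_z(self):
        cfg = SimConfig(n_patients=3000, followup_stage_increment_mean=10.0, seed=47)
        pat, truth = generate_patient_cohort(cfg)
        fu = generate_followup(truth, cfg)
        from sustainz.simulate import _expected_volumes

        scale = cfg.noise_sd * cfg.baselines
        z_bl = (_expected_volumes(cfg, pat) - pat[list(cfg.biomarkers)].to_numpy()) / scale
        z_fu = (_expected_volumes(cfg, fu) - fu[list(cfg.biomarkers)].to_numpy()) / scale
        assert z_fu.mean() > z_bl.mean() + 0.5
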