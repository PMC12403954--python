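"""Clinical statistics: progression rules, rank tests, exact tests,
FDR, Cox models and treatment-response arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sustainz.characterize import (
    adjusted_group_test,
    benjamini_hochberg,
    categorical_test,
    cox_models,
    dmt_response,
    dunn_test,
    flag_edss_progression,
    flag_spms_conversion,
    one_vs_all_contrast,
    stage_correlations,
)
from sustainz.errors import DegenerateDataError, InvalidConfigError


class TestProgressionRules:
    @pytest.mark.parametrize(
        "base, fu, expected",
        [
            (3.0, 4.0, True),  # >= 1.0 step at baseline <= 5.5
            (6.0, 6.5, True),  # >= 0.5 step at baseline > 5.5
            (3.0, 3.5, False),
            (5.5, 6.0, False),  # baseline 5.5 still needs a full point
            (5.5, 6.5, True),
            (0.0, 1.0, True),
        ],
    )
    def test_edss_thresholds(self, base, fu, expected):
        assert bool(flag_edss_progression(base, fu)) is expected

    def test_missing_followup_is_missing_not_false(self):
        res = flag_edss_progression(np.array([3.0, 3.0]), np.array([np.nan, 4.0]))
        assert res[0] is pd.NA
        assert bool(res[1]) is True

    def test_off_grid_rejected(self):
        with pytest.raises(InvalidConfigError):
            flag_edss_progression(3.2, 4.0)

    def _timeline(self, rows):
        return pd.DataFrame(rows, columns=["months", "edss", "relapse"])

    def test_spms_sustained_conversion(self):
        rec = self._timeline([(0, 3.0, 0), (6, 4.0, 0), (14, 4.5, 0)])
        assert flag_spms_conversion(rec) is True

    def test_spms_requires_edss_four(self):
        rec = self._timeline([(0, 2.0, 0), (6, 3.5, 0), (18, 3.5, 0)])
        assert flag_spms_conversion(rec) is False

    def test_spms_relapse_in_window_blocks(self):
        rec = self._timeline([(0, 3.0, 0), (6, 4.0, 0), (10, 4.5, 1), (14, 4.5, 0)])
        assert flag_spms_conversion(rec) is False

    def test_spms_short_followup_missing(self):
        rec = self._timeline([(0, 3.0, 0), (4, 4.0, 0)])
        assert flag_spms_conversion(rec) is pd.NA


class TestBenjaminiHochberg:
    def test_worked_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.3])[0] == 0.3

    def test_dominates_raw_and_capped(self, rng):
        p = rng.random(40)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(25)
        np.testing.assert_allclose(
            benjamini_hochberg(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_invalid_p_rejected(self):
        with pytest.raises(InvalidConfigError):
            benjamini_hochberg([0.5, 1.5])


class TestGroupTests:
    def test_kw_statistic_matches_rank_formula(self):
        """Toy 3-group data vs the textbook H statistic."""
        d = pd.DataFrame(
            {
                "y": [1.0, 3.0, 5.0, 2.0, 4.0, 6.0, 7.0, 8.0, 9.0],
                "g": ["a", "a", "a", "b", "b", "b", "c", "c", "c"],
            }
        )
        res = adjusted_group_test(d, "y", "g")
        ranks = stats.rankdata(d["y"] - d["y"].mean())
        N = 9
        H = 12 / (N * (N + 1)) * sum(
            len(r) * r.mean() ** 2 for r in (ranks[:3], ranks[3:6], ranks[6:])
        ) - 3 * (N + 1)
        assert res["H"] == pytest.approx(H, abs=1e-10)

    def test_shifted_groups_detected_with_correct_pairs(self, rng):
        n = 120
        g = np.repeat(["a", "b", "c"], n)
        age = rng.uniform(20, 60, 3 * n)
        y = 0.05 * age + rng.normal(0, 1, 3 * n)
        y[g == "b"] += 2.0  # only b is shifted
        d = pd.DataFrame({"y": y, "g": g, "age": age})
        res = adjusted_group_test(d, "y", "g", covariates=["age"])
        assert res["p"] < 1e-3
        ph = res["posthoc"].set_index(["group_a", "group_b"])
        assert ph.loc[("a", "b"), "p_fdr"] < 0.01
        assert ph.loc[("b", "c"), "p_fdr"] < 0.01
        assert ph.loc[("a", "c"), "p_fdr"] > 0.05

    def test_constant_variable_rejected(self):
        d = pd.DataFrame({"y": np.ones(30), "g": ["a", "b", "c"] * 10})
        with pytest.raises(DegenerateDataError):
            adjusted_group_test(d, "y", "g")

    def test_dunn_pairs_cover_all_groups(self, rng):
        out = dunn_test(rng.normal(0, 1, 60), np.repeat(["a", "b", "c"], 20))
        assert len(out) == 3


class TestCategorical:
    def test_proportional_table_null(self):
        res = categorical_test([[20, 40], [10, 20]])
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self, rng):
        """Two-sided Fisher p equals the exhaustive sum of hypergeometric
        probabilities no larger than the observed table's."""
        for _ in range(10):
            t = rng.integers(1, 12, (2, 2))
            res = categorical_test(t.tolist(), method="fisher")
            N, K, n = t.sum(), t[0].sum(), t[:, 0].sum()
            rv = stats.hypergeom(N, K, n)
            support = np.arange(max(0, K + n - N), min(K, n) + 1)
            pmf = rv.pmf(support)
            oracle = pmf[pmf <= rv.pmf(t[0, 0]) * (1 + 1e-9)].sum()
            assert res["p"] == pytest.approx(oracle, abs=1e-12)

    def test_treatment_table_conventions(self):
        """11/14 vs 10/26 responders: standard two-sided 0.0219, mid-p 0.0145."""
        t = [[11, 3], [10, 16]]
        assert categorical_test(t, method="fisher")["p"] == pytest.approx(0.0219, abs=5e-4)
        assert categorical_test(t, method="midp")["p"] == pytest.approx(0.0145, abs=5e-4)

    def test_sparse_2x2_falls_back_to_fisher(self):
        res = categorical_test([[2, 8], [7, 3]])
        assert res["method"] == "fisher"

    def test_large_table_uses_chi2(self):
        res = categorical_test([[30, 40, 30], [25, 45, 30]])
        assert res["method"] == "chi2"

    def test_empty_margin_rejected_beyond_2x2(self):
        with pytest.raises(DegenerateDataError):
            categorical_test([[0, 5, 3], [0, 4, 6]])

    def test_empty_margin_2x2_carries_no_evidence(self):
        assert categorical_test([[10, 0], [8, 0]])["p"] == 1.0


class TestStageCorrelations:
    def test_monotone_function_gives_rho_one(self):
        d = pd.DataFrame({"stage": np.arange(20.0), "y": np.arange(20.0) ** 2})
        out = stage_correlations(d, "stage", ["y"])
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_six_point_toy_matches_rank_formula(self):
        stage = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        out = stage_correlations(d := pd.DataFrame({"stage": stage, "y": y}), "stage", ["y"], min_n=6)
        # no ties: rho = 1 - 6*sum(d^2)/(n(n^2-1))
        dsq = ((stats.rankdata(stage) - stats.rankdata(y)) ** 2).sum()
        assert out.loc[0, "rho"] == pytest.approx(1 - 6 * dsq / (6 * 35), abs=1e-10)

    def test_partial_association_recovered(self, rng):
        n = 400
        age = rng.uniform(20, 60, n)
        stage = 0.3 * age + rng.normal(0, 3, n)
        y = 0.5 * stage + 0.2 * age + rng.normal(0, 2, n)
        d = pd.DataFrame({"stage": stage, "y": y, "age": age})
        out = stage_correlations(d, "stage", ["y"], covariates=["age"])
        # true partial correlation of stage and y given age
        r_true = 0.5 * 3 / np.sqrt((0.5 * 3) ** 2 + 4)
        assert out.loc[0, "rho"] == pytest.approx(r_true, abs=0.12)
        assert out.loc[0, "p_raw"] < 1e-6

    def test_constant_variable_yields_missing_with_warning(self):
        d = pd.DataFrame({"stage": np.arange(20.0), "y": np.ones(20)})
        with pytest.warns(UserWarning):
            out = stage_correlations(d, "stage", ["y"])
        assert np.isnan(out.loc[0, "rho"])


class TestCox:
    def _surv_frame(self, n, hr, seed, censor=15.0):
        rng = np.random.default_rng(seed)
        grp = rng.integers(0, 2, n)
        lam = 0.05 * hr**grp
        t = rng.exponential(1 / lam)
        obs = np.minimum(t, censor)
        return pd.DataFrame({"time": obs, "event": (t <= censor).astype(int), "grp": grp})

    def test_known_hazard_ratio_recovered(self):
        d = self._surv_frame(1000, 2.0, seed=1)
        res = cox_models(d, ["grp"])
        hr = res["univariate"].loc[0, "HR"]
        assert 1.7 <= hr <= 2.4

    def test_null_covariate_ci_contains_one(self):
        d = self._surv_frame(500, 1.0, seed=2)
        res = cox_models(d, ["grp"])
        row = res["univariate"].loc[0]
        assert row["HR_lower95"] <= 1.0 <= row["HR_upper95"]

    def test_stepwise_drops_noise_covariates(self):
        """One true predictor + 3 noise covariates: noise dropped in >= 80%
        of seeded replicates, true predictor retained."""
        kept_true, dropped_noise = 0, 0  # dropped counted per noise covariate
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            n = 150
            x = rng.integers(0, 2, n)
            noise = rng.normal(0, 1, (n, 3))
            lam = 0.05 * np.exp(1.0 * x)
            t = rng.exponential(1 / lam)
            obs = np.minimum(t, 20.0)
            d = pd.DataFrame(
                {"time": obs, "event": (t <= 20.0).astype(int), "x": x,
                 "n1": noise[:, 0], "n2": noise[:, 1], "n3": noise[:, 2]}
            )
            res = cox_models(d, ["x", "n1", "n2", "n3"])
            if "x" in res["final_covariates"]:
                kept_true += 1
            dropped_noise += 3 - len(set(res["final_covariates"]) - {"x"})
        assert kept_true / n_rep >= 0.95
        assert dropped_noise / (3 * n_rep) >= 0.80

    def test_too_few_events_rejected(self):
        d = self._surv_frame(20, 1.0, seed=3, censor=0.5)
        with pytest.raises(DegenerateDataError):
            cox_models(d, ["grp"])


class TestOneVsAll:
    def _setup(self, offset, rng, n=100):
        sub = np.repeat([0, 1], n)
        stage = rng.uniform(0, 10, 2 * n)
        z1 = 0.3 * stage + rng.normal(0, 1, 2 * n)
        z1[sub == 1] += offset
        z2 = 0.3 * stage + rng.normal(0, 1, 2 * n)
        Z = pd.DataFrame({"r1": z1, "r2": z2}, index=[f"S{i}" for i in range(2 * n)])
        asg = pd.DataFrame(
            {"ml_subtype": sub, "weighted_stage": stage, "is_na": False},
            index=Z.index,
        )
        return Z, asg

    def test_injected_offset_detected(self, rng):
        Z, asg = self._setup(1.0, rng)
        out = one_vs_all_contrast(Z, asg)
        row = out[(out["subtype"] == 1) & (out["region"] == "r1")].iloc[0]
        assert row["t"] > 0 and row["p"] < 0.01
        null_row = out[(out["subtype"] == 1) & (out["region"] == "r2")].iloc[0]
        assert abs(null_row["t"]) < 3.0

    def test_stage_mediated_difference_attenuated(self, rng):
        """A gap carried entirely by stage shrinks once stage is adjusted."""
        import statsmodels.api as sm

        n = 150
        sub = np.repeat([0, 1], n)
        stage = np.where(sub == 1, 8.0, 2.0) + rng.uniform(-1, 1, 2 * n)
        z = 0.5 * stage + rng.normal(0, 1, 2 * n)
        Z = pd.DataFrame({"r1": z}, index=[f"S{i}" for i in range(2 * n)])
        asg = pd.DataFrame({"ml_subtype": sub, "weighted_stage": stage, "is_na": False}, index=Z.index)
        adjusted_t = one_vs_all_contrast(Z, asg).iloc[1]["t"]
        X0 = sm.add_constant((sub == 1).astype(float))
        unadjusted_t = sm.OLS(z, X0).fit().tvalues[1]
        assert abs(adjusted_t) < abs(unadjusted_t) / 2

    def test_single_subtype_rejected(self, rng):
        Z, asg = self._setup(0.0, rng)
        asg["ml_subtype"] = 0
        with pytest.raises(DegenerateDataError):
            one_vs_all_contrast(Z, asg)


class TestDmtResponse:
    def _tables(self, counts):
        """counts: {class_label: (responders_relapse, total)}; EDSS mirrors."""
        rows_c, rows_a = [], []
        i = 0
        for lab, (resp, total) in counts.items():
            for j in range(total):
                sid = f"S{i}"
                relapsed = j >= resp
                rows_c.append(
                    {
                        "subject_id": sid,
                        "edss": 3.0,
                        "followup_edss": 4.0 if relapsed else 3.0,
                        "followup_relapses": 1 if relapsed else 0,
                        "followup_time": 24.0,
                        "treatment": "DMT",
                    }
                )
                rows_a.append({"subject_id": sid, "ml_subtype": lab, "weighted_stage": 1.0, "is_na": lab == -1})
                i += 1
        clinical = pd.DataFrame(rows_c)
        asg = pd.DataFrame(rows_a).set_index("subject_id")
        return clinical, asg

    def test_printed_count_arithmetic(self):
        clinical, asg = self._tables({-1: (11, 14), 0: (32, 60)})
        res = dmt_response(clinical, asg)
        rates = res["rates"]["relapse"].set_index("class")
        assert rates.loc["NA", "percent"] == pytest.approx(78.6, abs=0.05)
        assert rates.loc["subtype_0", "percent"] == pytest.approx(53.3, abs=0.05)

    def test_all_responders_fisher_p_one(self):
        clinical, asg = self._tables({0: (10, 10), 1: (8, 8)})
        res = dmt_response(clinical, asg)
        assert res["tests"]["relapse"].loc[0, "p_raw"] == pytest.approx(1.0)
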