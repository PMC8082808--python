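import numpy as np
import pandas as pd
import pytest
from scipy import stats

import microperm as mp
from microperm.models import (
    bh_fdr,
    fit_timecourse,
    lrt,
    pairwise_contrasts,
    per_feature_timecourse,
    rank_transform,
    timecourse_lrt,
)
from microperm.synth import SimScenario, simulate_cohort

COVS = ["delivery_mode", "breastfeeding_weeks"]


class TestRankTransform:
    def test_simple_ordering(self):
        np.testing.assert_array_equal(rank_transform([3.1, 1.2, 5.0]), [2, 1, 3])

    def test_ties_get_average_ranks(self):
        np.testing.assert_array_equal(rank_transform([2, 2, 9]), [1.5, 1.5, 3])

    def test_invariant_to_monotone_transform(self):
        x = np.array([0.3, 2.0, 1.1, 7.5])
        np.testing.assert_array_equal(rank_transform(x), rank_transform(np.exp(x)))

    def test_missing_stays_missing(self):
        out = rank_transform([1.0, np.nan, 3.0])
        assert np.isnan(out[1])
        np.testing.assert_array_equal(out[[0, 2]], [1, 2])

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            rank_transform([np.nan, np.nan])


def _bh_stepup_oracle(p):
    """Literal step-up definition: q_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank_pos in range(m, 0, -1):
        idx = order[rank_pos - 1]
        running = min(running, min(1.0, m * p[idx] / rank_pos))
        q[idx] = running
    return q


class TestBhFdr:
    def test_single_test_unchanged(self):
        np.testing.assert_array_equal(bh_fdr([0.01]), [0.01])

    def test_hand_stepup(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.9]), [0.03, 0.03, 0.9])

    def test_output_never_below_input(self):
        rng = np.random.default_rng(0)
        p = rng.random(25)
        assert (bh_fdr(p) >= p).all()

    def test_matches_brute_force_stepup_exactly(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_array_equal(bh_fdr(p), _bh_stepup_oracle(p))

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.random(50)
        np.testing.assert_allclose(
            bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_missing_entries_ignored(self):
        out = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], _bh_stepup_oracle([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])


class TestFitTimecourse:
    def test_constant_response_is_null(self, toy_design):
        y = np.full(len(toy_design), 7.0)
        full, res, _ = timecourse_lrt(y, toy_design)
        assert np.allclose(full.params.iloc[1:], 0.0)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_zero_subject_variance_recovered(self):
        # response with time effect but no subject-level shifts
        rng = np.random.default_rng(2)
        s = SimScenario(seed=2)
        _, design, _ = simulate_cohort(s)
        codes = design["time_point"].cat.codes.to_numpy()
        y = 2.0 * codes + rng.normal(0, 1, len(design))
        fit = fit_timecourse(y, design)
        assert fit.re_variance < 0.2 * fit.resid_variance

    def test_marker_trajectory_detected_across_seeds(self):
        # zonulin-like plateau trajectory should give LRT p < 0.01 nearly always
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            _, design, _ = simulate_cohort(SimScenario(seed=seed))
            y = rank_transform(design["zonulin"])
            _, res, _ = timecourse_lrt(y, design, COVS)
            hits += res.p < 0.01
        assert hits >= 0.95 * n_seeds

    def test_casewise_deletion_of_missing_response(self, toy_design):
        y = np.arange(len(toy_design), dtype=float)
        y[3] = np.nan
        fit = fit_timecourse(y, toy_design)
        assert fit.n_obs == len(toy_design) - 1


class TestLrt:
    def test_negative_statistic_clamped_to_zero(self, toy_design):
        y = np.arange(12.0)
        full = fit_timecourse(y, toy_design)
        null = fit_timecourse(y, toy_design, include_time=False)
        import dataclasses

        worse_full = dataclasses.replace(full, llf=null.llf - 1e-6)
        res = lrt(worse_full, null)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_chi_square_tail_value(self, toy_design):
        # statistic 27.0 on df=4: frozen chi-square tail 1.9879e-5
        import dataclasses

        y = np.arange(12.0)
        null = fit_timecourse(y, toy_design, include_time=False)
        full = fit_timecourse(y, toy_design)
        forced = dataclasses.replace(full, llf=null.llf + 13.5, n_fixed=null.n_fixed + 4)
        res = lrt(forced, null)
        assert res.statistic == pytest.approx(27.0)
        assert res.df == 4
        assert res.p == pytest.approx(1.9879e-5, rel=1e-3)

    def test_mismatched_rows_rejected(self, toy_design):
        y = np.arange(12.0)
        full = fit_timecourse(y, toy_design)
        y2 = y.copy()
        y2[0] = np.nan
        null = fit_timecourse(y2, toy_design, include_time=False)
        with pytest.raises(ValueError, match="identical rows"):
            lrt(full, null)

    def test_statistic_invariant_to_covariate_rescaling(self, pmu_cohort):
        _, design, _ = pmu_cohort
        rng = np.random.default_rng(3)
        y = rng.normal(size=len(design))
        design2 = design.copy()
        design2["breastfeeding_weeks"] = 10 * design2["breastfeeding_weeks"] + 3
        _, res1, _ = timecourse_lrt(y, design, ["breastfeeding_weeks"])
        _, res2, _ = timecourse_lrt(y, design2, ["breastfeeding_weeks"])
        assert res1.statistic == pytest.approx(res2.statistic, abs=1e-5)

    def test_null_simulation_p_uniform(self):
        # small null cohorts: LRT p-values should be close to uniform
        pvals = []
        tps = ("P2", "P3", "P4", "P5", "P6")
        for seed in range(300):
            rng = np.random.default_rng(seed)
            rows = []
            for subj in range(21):
                intercept = rng.normal(0, 1)
                for tp in tps:
                    rows.append(
                        {
                            "sample_id": f"S{subj}_{tp}",
                            "subject_id": f"S{subj}",
                            "time_point": tp,
                            "y": intercept + rng.normal(0, 1),
                        }
                    )
            df = pd.DataFrame(rows)
            df["time_point"] = pd.Categorical(df["time_point"], list(tps), ordered=True)
            df = df.set_index("sample_id", drop=False)
            _, res, _ = timecourse_lrt(df["y"].to_numpy(), df)
            pvals.append(res.p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPairwiseContrasts:
    def test_five_levels_give_ten_rows(self, pmu_cohort):
        _, design, _ = pmu_cohort
        y = rank_transform(design["zonulin"])
        full, _, contr = timecourse_lrt(y, design, COVS)
        assert len(contr) == 10

    def test_two_level_contrast_equals_mean_difference(self):
        rows = []
        rng = np.random.default_rng(4)
        for subj in range(8):
            for tp in ("P2", "P3"):
                rows.append(
                    {
                        "sample_id": f"S{subj}_{tp}",
                        "subject_id": f"S{subj}",
                        "time_point": tp,
                        "y": rng.normal(),
                    }
                )
        df = pd.DataFrame(rows)
        df["time_point"] = pd.Categorical(df["time_point"], ["P2", "P3"], ordered=True)
        df = df.set_index("sample_id", drop=False)
        fit = fit_timecourse(df["y"].to_numpy(), df)
        contr = pairwise_contrasts(fit)
        means = df.groupby("time_point", observed=True)["y"].mean()
        assert contr.loc[0, "estimate"] == pytest.approx(
            means["P2"] - means["P3"], abs=1e-6
        )

    def test_increasing_response_has_negative_t_ratio(self, toy_design):
        y = toy_design["time_point"].cat.codes.to_numpy().astype(float)
        y += np.random.default_rng(5).normal(0, 0.01, len(y))
        fit = fit_timecourse(y, toy_design)
        contr = pairwise_contrasts(fit)
        assert (contr["t_ratio"] < 0).all()  # earlier minus later

    def test_q_at_least_p(self, pmu_cohort):
        _, design, _ = pmu_cohort
        y = rank_transform(design["calprotectin"])
        _, _, contr = timecourse_lrt(y, design, COVS)
        assert (contr["q"] >= contr["p"] - 1e-12).all()


class TestPerFeatureTimecourse:
    def test_single_instance_equals_direct_analysis(self, prepared):
        _, _, clr, design = prepared
        single = mp.ClrInstanceSet(
            clr.sample_ids, clr.feature_ids, clr.values[:1], clr.prior
        )
        overall, _ = per_feature_timecourse(single, design, COVS)
        feat = clr.feature_ids[0]
        y = single.values[0, :, 0]
        _, res, _ = timecourse_lrt(y, design, COVS, response=feat)
        assert overall.loc[feat, "lrt_stat"] == pytest.approx(res.statistic, rel=1e-6)

    def test_trending_features_recovered(self, prepared, pmu_cohort):
        _, _, clr, design = prepared
        _, _, truth = pmu_cohort
        overall, contrasts = per_feature_timecourse(clr, design, COVS)
        flagged = set(overall[overall["significant"]].index)
        trending = set(truth.trending) & set(clr.feature_ids)
        sensitivity = len(flagged & trending) / len(trending)
        assert sensitivity >= 0.8
        assert set(contrasts["feature"]) == set(clr.feature_ids)
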