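import numpy as np
import pandas as pd
import pytest

import microperm as mp
from microperm.delta import build_deltas, fit_delta_model, interval_labels, interval_overlap
from microperm.synth import synthetic_delta_response


@pytest.fixture(scope="module")
def delta_table(prepared):
    retained, rare, clr, design = prepared
    return build_deltas(
        rare.canonical, clr, design, ["zonulin", "calprotectin"]
    ), design


class TestBuildDeltas:
    def test_pair_combinatorics(self, delta_table):
        dt, design = delta_table
        per_subject = dt.frame.groupby("subject_id").size()
        k = design.groupby("subject_id").size()
        for subj, rows in per_subject.items():
            assert rows == k[subj] * (k[subj] - 1) // 2

    def test_five_timepoints_give_ten_interval_labels(self):
        assert len(interval_labels(["P2", "P3", "P4", "P5", "P6"])) == 10
        assert len(interval_labels(["P2", "P3", "P4", "P5"])) == 6

    def test_changes_are_later_minus_earlier(self, delta_table, pmu_cohort):
        dt, design = delta_table
        _, full_design, _ = pmu_cohort
        row = dt.frame.iloc[0]
        earlier_id = f"{row.subject_id}_{row.earlier}"
        later_id = f"{row.subject_id}_{row.later}"
        expected = (
            full_design.loc[later_id, "zonulin"] - full_design.loc[earlier_id, "zonulin"]
        )
        assert row["d_zonulin"] == pytest.approx(expected)

    def test_single_timepoint_subject_contributes_no_rows(self, prepared):
        retained, rare, clr, design = prepared
        lone = design.groupby("subject_id").filter(lambda g: len(g) >= 2)
        # artificially restrict one subject to one sample
        keep = list(lone.index)
        victim = lone["subject_id"].iloc[0]
        keep = [s for s in keep if not s.startswith(victim)] + [
            lone[lone["subject_id"] == victim].index[0]
        ]
        sub_clr = mp.ClrInstanceSet(
            tuple(keep),
            clr.feature_ids,
            clr.values[:, [list(clr.sample_ids).index(s) for s in keep], :],
            clr.prior,
        )
        sub_rare = rare.canonical.select_samples(keep)
        with pytest.warns(UserWarning, match="<2 time points"):
            dt = build_deltas(sub_rare, sub_clr, design.loc[keep], ["zonulin"])
        assert victim not in set(dt.frame["subject_id"])

    def test_missing_marker_keeps_feature_columns(self, prepared):
        retained, rare, clr, design = prepared
        design = design.copy()
        subj = design["subject_id"].iloc[0]
        first = design[design["subject_id"] == subj].index[0]
        design.loc[first, "zonulin"] = np.nan
        dt = build_deltas(rare.canonical, clr, design, ["zonulin"])
        affected = dt.frame[
            (dt.frame["subject_id"] == subj)
            & ((dt.frame["earlier"] == first.split("_")[1]))
        ]
        assert affected["d_zonulin"].isna().all()
        idx = affected.index[0]
        assert np.isfinite(dt.feature_changes[0, idx, :]).all()

    def test_bray_curtis_column_in_unit_interval(self, delta_table):
        dt, _ = delta_table
        assert ((dt.frame["bray_curtis"] >= 0) & (dt.frame["bray_curtis"] <= 1)).all()


class TestFitDeltaModel:
    def test_known_common_slope_recovered(self, delta_table):
        dt, _ = delta_table
        j = dt.feature_ids.index("g12")
        dx = dt.feature_changes[0, :, j]
        dt.frame["constructed"] = synthetic_delta_response(
            dx, dt.frame["interval"], beta=3.0, noise_sd=1.0, seed=0
        )
        res = fit_delta_model(
            dt, "constructed", "g12", rank_response=False, n_instances=1
        )
        assert res.beta == pytest.approx(3.0, abs=1.0)
        assert res.lrt1_p < 0.01

    def test_null_predictor_not_selected(self, delta_table):
        dt, _ = delta_table
        rng = np.random.default_rng(1)
        dt.frame["noise_response"] = rng.normal(size=len(dt.frame))
        res = fit_delta_model(
            dt, "noise_response", "g01", rank_response=False, n_instances=1
        )
        assert res.decision == "none"

    def test_coupled_feature_association_detected(self, delta_table):
        dt, _ = delta_table
        res = fit_delta_model(dt, "calprotectin", "g12")
        assert res.lrt1_p < 0.05
        assert res.beta > 0

    def test_duplicated_predictor_covariate_rejected(self, delta_table):
        dt, _ = delta_table
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_delta_model(
                dt, "calprotectin", "bray_curtis", covariates=["bray_curtis"],
                n_instances=1,
            )

    def test_bray_curtis_predictor_variant(self, delta_table):
        dt, _ = delta_table
        res = fit_delta_model(dt, "calprotectin", "bray_curtis")
        assert np.isfinite(res.beta)
        assert res.interval_slopes is not None

    def test_marker_vs_marker_convenience(self, delta_table):
        dt, _ = delta_table
        res = fit_delta_model(dt, "calprotectin", "d_zonulin")
        assert np.isfinite(res.lrt1_p)

    def test_interval_slopes_have_bh_column(self, delta_table):
        dt, _ = delta_table
        res = fit_delta_model(dt, "calprotectin", "g12", n_instances=1)
        slopes = res.interval_slopes
        assert (slopes["q"] >= slopes["p"] - 1e-12).all()
        assert set(slopes["interval"]) <= set(dt.interval_levels)


class TestDeltaScreen:
    def test_single_feature_matches_fit_delta_model(self, delta_table):
        dt, _ = delta_table
        scr = mp.delta_screen(dt, "calprotectin", features=["g12"], n_instances=1)
        direct = fit_delta_model(dt, "calprotectin", "g12", n_instances=1)
        assert scr.loc["g12", "beta"] == pytest.approx(direct.beta)
        assert scr.loc["g12", "lrt1_q"] == pytest.approx(direct.lrt1_p)  # single test

    def test_coupled_feature_has_smallest_q(self, delta_table):
        dt, _ = delta_table
        scr = mp.delta_screen(dt, "calprotectin", n_instances=1)
        assert scr["lrt1_q"].idxmin() == "g12"


class TestIntervalOverlap:
    def _contrasts(self, rows, with_feature=True):
        df = pd.DataFrame(rows)
        return df

    def test_same_direction_label(self):
        marker = pd.DataFrame(
            {"pair": ["P2-P4", "P2-P5"], "estimate": [-1.0, -2.0], "q": [0.01, 0.01]}
        )
        feature = pd.DataFrame(
            {
                "feature": ["gX", "gX"],
                "pair": ["P2-P4", "P2-P5"],
                "estimate": [-0.5, -0.7],
                "q": [0.02, 0.01],
            }
        )
        out = interval_overlap(marker, feature)
        assert out.loc[0, "label"] == "same"

    def test_opposite_direction_label(self):
        marker = pd.DataFrame({"pair": ["P2-P4"], "estimate": [-1.0], "q": [0.01]})
        feature = pd.DataFrame(
            {"feature": ["gY"], "pair": ["P2-P4"], "estimate": [0.5], "q": [0.01]}
        )
        assert interval_overlap(marker, feature).loc[0, "label"] == "opposite"

    def test_no_significant_feature_intervals_gives_no_label(self):
        marker = pd.DataFrame({"pair": ["P2-P4"], "estimate": [-1.0], "q": [0.01]})
        feature = pd.DataFrame(
            {"feature": ["gZ"], "pair": ["P2-P4"], "estimate": [0.5], "q": [0.50]}
        )
        assert interval_overlap(marker, feature).loc[0, "label"] == ""

    def test_mismatched_interval_sets_rejected(self):
        marker = pd.DataFrame({"pair": ["P2-P4"], "estimate": [-1.0], "q": [0.01]})
        feature = pd.DataFrame(
            {"feature": ["gZ"], "pair": ["P9-P10"], "estimate": [0.5], "q": [0.01]}
        )
        with pytest.raises(ValueError, match="interval sets"):
            interval_overlap(marker, feature)
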