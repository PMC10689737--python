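"""Group comparison, forward-selection ranking, incremental AUROC and the
age/condition sub-analyses, on controlled synthetic feature matrices."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from ppgfeat.hrv import HRV_FEATURE_NAMES
from ppgfeat.stats import (
    age_trend,
    candidate_pool,
    cohens_d,
    condition_compare,
    evaluate_incremental,
    group_compare,
    rank_features,
)


def feature_frame(rng, n_per_group=100, effects=None, n_noise=3, n_subjects=None):
    """Two-group frame: features with given mean shifts plus pure-noise ones."""
    effects = effects or {}
    n = 2 * n_per_group
    rows = {
        "group": ["A"] * n_per_group + ["B"] * n_per_group,
    }
    if n_subjects:
        per = n_per_group // (n_subjects // 2)
        rows["subject"] = [f"{g}{i // per}" for g in ("A", "B") for i in range(n_per_group)]
    else:
        rows["subject"] = [f"s{i}" for i in range(n)]
    for name, shift in effects.items():
        rows[name] = np.concatenate(
            [rng.normal(0, 1, n_per_group), rng.normal(shift, 1, n_per_group)]
        )
    for j in range(n_noise):
        rows[f"noise{j}"] = rng.normal(0, 1, n)
    return pd.DataFrame(rows)


class TestGroupCompare:
    def test_identical_groups_null(self, rng):
        x = rng.normal(0, 1, 200)
        df = pd.DataFrame({"group": ["A"] * 100 + ["B"] * 100, "f": np.concatenate([x[:100], x[:100]])})
        res = group_compare(df, ["f"], n_boot=200)[0]
        assert res.cohens_d == pytest.approx(0.0, abs=1e-12)
        assert res.mann_whitney_p > 0.9

    def test_unit_shift_recovers_d_of_one(self, rng):
        df = feature_frame(rng, n_per_group=200, effects={"f": -1.0}, n_noise=0)
        res = group_compare(df, ["f"], n_boot=500, seed=3)[0]
        assert res.cohens_d == pytest.approx(1.0, abs=0.2)
        assert res.ci_low <= res.cohens_d <= res.ci_high
        assert res.mann_whitney_p < 1e-6

    def test_label_swap_flips_d_not_p(self, rng):
        df = feature_frame(rng, n_per_group=80, effects={"f": 0.8}, n_noise=0)
        a = group_compare(df, ["f"], groups=("A", "B"), n_boot=100)[0]
        b = group_compare(df, ["f"], groups=("B", "A"), n_boot=100)[0]
        assert a.cohens_d == pytest.approx(-b.cohens_d, abs=1e-12)
        assert a.mann_whitney_p == pytest.approx(b.mann_whitney_p, abs=1e-12)

    def test_zero_pooled_sd_missing(self):
        df = pd.DataFrame({"group": ["A", "A", "B", "B"], "f": [1.0, 1.0, 1.0, 1.0]})
        res = group_compare(df, ["f"], n_boot=10)[0]
        assert math.isnan(res.cohens_d)


class TestCandidatePools:
    def test_pool_sizes_and_pwd_exclusion(self):
        assert len(candidate_pool("hrv")) == 30
        assert len(candidate_pool("morph")) == 36
        assert len(candidate_pool("combined")) == 66
        assert "pwd" not in candidate_pool("morph")
        assert "pwd" not in candidate_pool("combined")
        assert set(candidate_pool("hrv")) == set(HRV_FEATURE_NAMES)


class TestRanking:
    def test_perfect_separator_always_ranked_first(self, rng):
        df = feature_frame(rng, n_per_group=60, n_noise=4)
        df["sep"] = np.where(df["group"] == "B", 1.0, -1.0) + rng.normal(0, 0.01, len(df))
        feats = ["sep"] + [f"noise{j}" for j in range(4)]
        res = rank_features(df, features=feats, depth=2, n_repeats=3, seed=1)
        assert all(r[0] == "sep" for r in res.rankings)
        assert res.top[0] == "sep"

    def test_identical_seed_identical_result(self, rng):
        df = feature_frame(rng, n_per_group=40, effects={"f": 0.7}, n_noise=3)
        feats = ["f", "noise0", "noise1", "noise2"]
        a = rank_features(df, features=feats, depth=3, n_repeats=3, seed=9)
        b = rank_features(df, features=feats, depth=3, n_repeats=3, seed=9)
        assert a.rankings == b.rankings
        assert a.top == b.top
        assert a.popularity == b.popularity

    def test_single_class_rejected(self, rng):
        df = feature_frame(rng, n_per_group=20, n_noise=1)
        df["group"] = "A"
        with pytest.raises(ValueError):
            rank_features(df, features=["noise0"], n_repeats=1)


class TestEvaluateIncremental:
    def test_noise_features_give_chance_auroc(self, rng):
        df = feature_frame(rng, n_per_group=100, n_noise=3)
        curve = evaluate_incremental(df, ["noise0", "noise1", "noise2"], seed=2)
        assert (curve["auroc_mean"].between(0.4, 0.6)).all()

    def test_flipped_labels_mirror_auroc(self, rng):
        df = feature_frame(rng, n_per_group=60, effects={"f": 1.0}, n_noise=0)
        a = evaluate_incremental(df, ["f"], pos_label="B", seed=4)
        flipped = df.copy()
        flipped["group"] = np.where(df["group"] == "A", "B", "A")
        b = evaluate_incremental(flipped, ["f"], pos_label="B", seed=4)
        assert a["auroc_mean"][0] == pytest.approx(1.0 - (1.0 - b["auroc_mean"][0]), abs=1e-9)
        assert a["auroc_mean"][0] == pytest.approx(b["auroc_mean"][0], abs=1e-6)

    def test_participant_grouping_inflates_dispersion(self, rng):
        # strong between-subject variance: segment-level folds see every
        # subject in training, participant-level folds do not
        df = feature_frame(rng, n_per_group=120, effects={"f": 1.0}, n_subjects=12)
        subj_effect = {s: rng.normal(0, 1.5) for s in df["subject"].unique()}
        df["f"] = df["f"] + df["subject"].map(subj_effect)
        seg = evaluate_incremental(df, ["f"], stratification="segment", seed=5)
        par = evaluate_incremental(df, ["f"], stratification="participant", seed=5)
        assert par["auroc_sd"][0] >= seg["auroc_sd"][0]

    def test_segments_of_one_subject_stay_in_one_fold(self, rng):
        from sklearn.model_selection import StratifiedGroupKFold

        df = feature_frame(rng, n_per_group=60, effects={"f": 1.0}, n_subjects=12)
        y = (df["group"] == "B").to_numpy(int)
        groups = df["subject"].to_numpy()
        for tr, te in StratifiedGroupKFold(n_splits=7, shuffle=True, random_state=0).split(
            df[["f"]], y, groups
        ):
            assert set(groups[tr]).isdisjoint(groups[te])


class TestAgeTrend:
    def test_slope_recovery(self, rng):
        ages = rng.uniform(20, 40, 30)
        df = pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(30)],
                "age": ages,
                "f": 2.0 * ages + rng.normal(0, 0.01, 30),
            }
        )
        res = age_trend(df, ["f"])
        assert res["slope"][0] == pytest.approx(2.0, abs=0.05)
        assert res["p"][0] < 1e-10

    def test_segments_averaged_per_subject(self, rng):
        df = pd.DataFrame(
            {
                "subject": ["s1", "s1", "s2", "s3"],
                "age": [30.0, 30.0, 25.0, 35.0],
                "f": [10.0, 14.0, 8.0, 20.0],
            }
        )
        res = age_trend(df, ["f"])
        oracle = sstats.linregress([30.0, 25.0, 35.0], [12.0, 8.0, 20.0])
        assert res["slope"][0] == pytest.approx(oracle.slope, abs=1e-12)
        assert res["p"][0] == pytest.approx(oracle.pvalue, abs=1e-12)

    def test_constant_ages_rejected(self):
        df = pd.DataFrame({"subject": list("abc"), "age": [30.0] * 3, "f": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            age_trend(df, ["f"])


class TestConditionCompare:
    def test_identical_conditions_null_and_schema(self, rng):
        df = feature_frame(rng, n_per_group=40, n_noise=1)
        res = condition_compare(df, df.copy(), ["noise0"], n_boot=50)
        assert res[0].cohens_d == pytest.approx(0.0, abs=1e-12)
        assert {f.feature for f in res} == {"noise0"}

    def test_shifted_second_condition_detected(self, rng):
        df1 = feature_frame(rng, n_per_group=60, n_noise=1)
        df2 = df1.copy()
        df2["noise0"] = df2["noise0"] - 1.0
        res = condition_compare(df1, df2, ["noise0"], n_boot=100)[0]
        assert res.cohens_d > 0.5
        assert res.mann_whitney_p < 1e-4
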