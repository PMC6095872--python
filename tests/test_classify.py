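"""Outcome dichotomization, nested CV, bootstrap summaries, importance tallies."""

import numpy as np
import pandas as pd
import pytest

from radiomix.classify import (
    CLASSIFIER_MENU,
    ClassifierSpec,
    bootstrap_summary,
    dichotomize_outcomes,
    nested_cv_auc,
    tally_feature_importance,
)

SMALL_EN = ClassifierSpec(
    "EN", "logistic", "ElasticNet", "saga", {"C": (1.0,), "l1_ratio": (0.5,)}
)


def _labeled_data(n=60, p=8, informative=2, seed=0, effect=1.8):
    rng = np.random.default_rng(seed)
    x = pd.DataFrame(
        rng.standard_normal((n, p)),
        columns=[f"f{i:02d}" for i in range(p)],
        index=[f"T{i:03d}" for i in range(n)],
    )
    beta = np.zeros(p)
    beta[:informative] = effect
    prob = 1 / (1 + np.exp(-(x.to_numpy() @ beta)))
    y = pd.Series((rng.random(n) < prob).astype(int), index=x.index, name="task")
    if y.nunique() < 2:
        y.iloc[0] = 1 - y.iloc[0]
    return x, y


class TestDichotomize:
    @pytest.fixture()
    def clinical(self):
        return pd.DataFrame(
            {
                "grade": [1, 2, 3, 4, np.nan],
                "recurrence_years": [1.5, np.nan, 0.4, 4.2, np.nan],
            },
            index=[f"P{i}" for i in range(5)],
        )

    def test_grade_rule(self, clinical):
        y = dichotomize_outcomes(clinical, "grade")
        assert y.tolist() == [0, 0, 1, 1]
        assert len(y) == 4  # missing grade dropped

    def test_rfs_cutoffs_from_recurrence_time(self, clinical):
        # recurrence at 1.5 y: still free at the 1-year cutoff, not at 2 years
        y1 = dichotomize_outcomes(clinical, "rfs1")
        y2 = dichotomize_outcomes(clinical, "rfs2")
        assert y1["P0"] == 1 and y2["P0"] == 0
        assert y1["P1"] == 1  # never recurred
        assert y1["P2"] == 0  # recurred within the first year

    def test_rfs_prefers_explicit_columns(self):
        clinical = pd.DataFrame(
            {"rfs_free_at_1": [1, 0, np.nan], "recurrence_years": [0.1, np.nan, 2.0]}
        )
        y = dichotomize_outcomes(clinical, "rfs1")
        assert y.tolist() == [1, 0]

    def test_class_counts_preserved(self):
        clinical = pd.DataFrame({"rfs_free_at_1": [1] * 75 + [0] * 10})
        y = dichotomize_outcomes(clinical, "rfs1")
        assert y.value_counts().to_dict() == {1: 75, 0: 10}

    @pytest.mark.parametrize("task", ["rfs0", "rfs6", "stage"])
    def test_invalid_tasks_rejected(self, task):
        with pytest.raises((ValueError, KeyError)):
            dichotomize_outcomes(pd.DataFrame({"grade": [1, 3]}), task)


class TestNestedCV:
    def test_auc_list_length_and_tally_cap(self):
        x, y = _labeled_data()
        res = nested_cv_auc(x, y, SMALL_EN, reps=7, seed=1)
        assert len(res.aucs) == 7 * 3
        assert res.max_cv_count == 21
        assert (res.tallies <= res.max_cv_count).all()
        assert np.all((res.aucs >= 0) & (res.aucs <= 1))

    def test_separable_feature_gives_high_auc(self):
        x, y = _labeled_data(informative=0)
        x["f00"] = y.astype(float)  # leak the label into one feature
        res = nested_cv_auc(x, y, SMALL_EN, reps=5, seed=2)
        assert res.mean_auc >= 0.99

    def test_same_seed_identical_results(self):
        x, y = _labeled_data(seed=4)
        a = nested_cv_auc(x, y, SMALL_EN, reps=5, seed=9)
        b = nested_cv_auc(x, y, SMALL_EN, reps=5, seed=9)
        np.testing.assert_array_equal(a.aucs, b.aucs)
        assert a.ci95 == b.ci95
        pd.testing.assert_series_equal(a.tallies, b.tallies)

    def test_outer_folds_are_stratified(self):
        x, y = _labeled_data(n=90, seed=5)
        from sklearn.model_selection import StratifiedKFold

        folds = list(
            StratifiedKFold(3, shuffle=True, random_state=0).split(x.to_numpy(), y)
        )
        global_prop = y.mean()
        for _, test_idx in folds:
            fold_pos = y.iloc[test_idx].sum()
            expected = global_prop * len(test_idx)
            assert abs(fold_pos - expected) <= 1.0

    def test_label_shuffle_destroys_signal(self):
        x, y = _labeled_data(n=90, p=10, effect=2.5, seed=6)
        res_signal = nested_cv_auc(x, y, SMALL_EN, reps=5, seed=3)
        rng = np.random.default_rng(0)
        means = []
        for s in range(4):
            y_null = pd.Series(rng.permutation(y.to_numpy()), index=y.index, name="null")
            means.append(nested_cv_auc(x, y_null, SMALL_EN, reps=5, seed=s).mean_auc)
        assert res_signal.mean_auc > 0.75
        assert abs(np.mean(means) - 0.5) < 0.1

    def test_single_class_rejected(self):
        x, y = _labeled_data()
        with pytest.raises(ValueError):
            nested_cv_auc(x, pd.Series(np.ones(len(x), int), index=x.index, name="t"), SMALL_EN)

    def test_inner_grid_search_runs_with_multipoint_grid(self):
        x, y = _labeled_data(n=45, p=5)
        spec = ClassifierSpec(
            "EN2", "logistic", "ElasticNet", "saga", {"C": (0.1, 1.0), "l1_ratio": (0.5,)}
        )
        res = nested_cv_auc(x, y, spec, reps=2, seed=8)
        assert all(p["C"] in (0.1, 1.0) for p in res.chosen_params)


class TestBootstrap:
    def test_constant_list_zero_width(self):
        mean, (lo, hi) = bootstrap_summary([0.7, 0.7, 0.7])
        assert mean == pytest.approx(0.7)
        assert lo == pytest.approx(0.7) and hi == pytest.approx(0.7)

    def test_extreme_list_bounds(self):
        mean, (lo, hi) = bootstrap_summary([0.0, 1.0], seed=1)
        assert mean == pytest.approx(0.5)
        assert 0.0 <= lo <= hi <= 1.0

    def test_coverage_on_known_distribution(self):
        # Beta(8, 4) has mean 2/3; the percentile CI should cover it ~95% of runs
        rng = np.random.default_rng(42)
        covered = 0
        n_runs = 200
        for i in range(n_runs):
            draws = rng.beta(8, 4, size=120)
            _, (lo, hi) = bootstrap_summary(draws, seed=i)
            covered += lo <= 2 / 3 <= hi
        assert 0.85 <= covered / n_runs <= 1.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_summary([0.5])


class TestImportance:
    def test_always_and_never_selected_extremes(self):
        x, y = _labeled_data(n=80, p=6, informative=1, effect=3.0, seed=10)
        res = nested_cv_auc(x, y, SMALL_EN, reps=10, seed=11)
        table = tally_feature_importance(res, top=6)
        assert table.loc["f00", "proportion"] >= 0.9
        assert (table["proportion"] <= 1.0).all()

    def test_planted_features_rank_top(self):
        x, y = _labeled_data(n=90, p=12, informative=2, effect=2.5, seed=12)
        res = nested_cv_auc(x, y, SMALL_EN, reps=15, seed=13)
        top = [name for name, _ in res.top_features]
        assert "f00" in top and "f01" in top

    def test_non_coefficient_model_errors(self):
        x, y = _labeled_data(n=40, p=4)
        spec = CLASSIFIER_MENU["RandomForest"]
        res = nested_cv_auc(x, y, spec, reps=2, seed=14)
        with pytest.raises(ValueError, match="permutation"):
            tally_feature_importance(res)

    def test_l2_rule_uses_coefficient_threshold(self):
        x, y = _labeled_data(n=60, p=6, informative=1, effect=3.0, seed=15)
        spec = ClassifierSpec("L2", "logistic", "L2", "lbfgs", {"C": (1.0,)})
        res = nested_cv_auc(x, y, spec, reps=4, seed=16)
        assert res.tallies["f00"] == res.max_cv_count
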