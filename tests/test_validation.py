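"""Split plans, hyperparameter optimization, importances, run_question."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from conftest import two_group_spec
from mrsdx.classifiers import DEFAULT_CONFIGS, ModelConfig
from mrsdx.cohort import METABOLITES, FeatureTable, generate_cohort
from mrsdx.validation import (
    TASKS,
    PipelineSettings,
    TaskDefinition,
    _fit_training_set,
    inner_cv_plan,
    optimize_hyperparameters,
    outer_split_plan,
    permutation_importance,
    run_question,
)

RR_VS_P = TASKS["RR_vs_P"]
MS_VS_HC = TASKS["MS_vs_HC"]


class TestTaskDefinition:
    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TaskDefinition("bad", frozenset({"HC"}), frozenset({"HC", "P-MS"}))

    def test_registry_polarity(self):
        assert "RR-MS" in RR_VS_P.positive_groups and "P-MS" in RR_VS_P.negative_groups
        assert MS_VS_HC.negative_groups == frozenset({"HC"})


class TestOuterPlan:
    def test_balanced_run_counts(self, prepared_table):
        assert len(outer_split_plan(prepared_table, RR_VS_P)) == 38
        assert len(outer_split_plan(prepared_table, MS_VS_HC)) == 48

    def test_balanced_truth_counts_equal_per_class(self, prepared_table):
        plan = outer_split_plan(prepared_table, RR_VS_P)
        groups = dict(zip(prepared_table.ids, prepared_table.groups))
        held_groups = [groups[h] for h, _ in plan]
        assert held_groups.count("RR-MS") == 19
        assert held_groups.count("P-MS") == 19

    def test_smaller_class_each_held_out_exactly_once(self, prepared_table):
        plan = outer_split_plan(prepared_table, MS_VS_HC)
        groups = dict(zip(prepared_table.ids, prepared_table.groups))
        hc_held = [h for h, _ in plan if groups[h] == "HC"]
        assert sorted(hc_held) == sorted(i for i, g in groups.items() if g == "HC")

    def test_exhaustive_counts_equal_cohort_class_sizes(self, prepared_table):
        plan = outer_split_plan(prepared_table, MS_VS_HC, mode="exhaustive")
        assert len(plan) == 68
        assert sorted(h for h, _ in plan) == sorted(prepared_table.ids)

    def test_heldout_never_in_training(self, prepared_table):
        for task in (RR_VS_P, MS_VS_HC):
            for held, training in outer_split_plan(prepared_table, task):
                assert held not in training

    def test_training_is_all_remaining_cases(self, prepared_table):
        plan = outer_split_plan(prepared_table, RR_VS_P)
        n_task = sum(g in {"RR-MS", "P-MS"} for g in prepared_table.groups)
        for held, training in plan:
            assert len(training) == n_task - 1

    def test_plan_invariant_to_row_order(self, prepared_table):
        shuffled = FeatureTable(
            prepared_table.data.sample(frac=1, random_state=3).reset_index(drop=True)
        )
        assert outer_split_plan(prepared_table, RR_VS_P, seed=5) == outer_split_plan(
            shuffled, RR_VS_P, seed=5
        )

    def test_tiny_class_rejected(self):
        table = generate_cohort(two_group_spec(n_a=6, n_b=2))
        task = TaskDefinition("t", frozenset({"RR-MS"}), frozenset({"P-MS"}))
        with pytest.raises(ValueError, match=">= 2"):
            # one P-MS held out leaves a single-case class in training
            plan = outer_split_plan(table, task)
            inner_cv_plan(table, plan[0][1], task)


class TestInnerPlan:
    def test_imbalanced_training_set_gives_n2_times_2(self, prepared_table):
        plan = outer_split_plan(prepared_table, MS_VS_HC)
        groups = dict(zip(prepared_table.ids, prepared_table.groups))
        for held, training in plan[:3]:
            n_hc = sum(groups[i] == "HC" for i in training)
            n_ms = len(training) - n_hc
            folds = inner_cv_plan(prepared_table, training, MS_VS_HC)
            assert len(folds) == 2 * min(n_hc, n_ms)

    def test_perfectly_balanced_training_is_plain_loocv(self):
        table = generate_cohort(two_group_spec(n_a=8, n_b=8))
        task = TaskDefinition("t", frozenset({"RR-MS"}), frozenset({"P-MS"}))
        folds = inner_cv_plan(table, list(table.ids), task)
        assert len(folds) == 16
        assert sorted(c for c, _ in folds) == sorted(table.ids)

    def test_cv_case_never_in_inner_training(self, prepared_table):
        plan = outer_split_plan(prepared_table, RR_VS_P)
        folds = inner_cv_plan(prepared_table, plan[0][1], RR_VS_P)
        for cv_id, inner_ids in folds:
            assert cv_id not in inner_ids


class TestSmoteBalanceInPipeline:
    def test_training_sets_entering_fits_are_exactly_balanced(self, prepared_table):
        from mrsdx.validation import _TaskData

        data = _TaskData(prepared_table, RR_VS_P)
        held, training = outer_split_plan(prepared_table, RR_VS_P)[0]
        idx = np.array([data.pos_of[i] for i in training])
        model, _ = _fit_training_set(
            data.X[idx], data.y[idx], np.arange(7), METABOLITES,
            ModelConfig("KNN", knn_k=3), smote_k=5, smote_seed=0,
        )
        y_train = model.params["y"]
        assert (y_train == 1).sum() == (y_train == -1).sum()


class TestOptimize:
    def test_grid_of_one_returned_unchanged(self, prepared_table):
        cfg = ModelConfig("QDA", qda_reg=0.3)
        assert optimize_hyperparameters(prepared_table, RR_VS_P, "QDA", (cfg,)) == cfg

    def test_wrong_family_config_rejected_before_fitting(self, prepared_table):
        grid = (ModelConfig("QDA"), ModelConfig("KNN"))
        with pytest.raises(ValueError, match="family"):
            optimize_hyperparameters(prepared_table, RR_VS_P, "QDA", grid)

    def test_strong_signal_all_configs_above_ninety_percent(self):
        table = generate_cohort(two_group_spec(n_a=16, n_b=16, shift={"GABA": 8.0}, seed=2))
        task = TaskDefinition("t", frozenset({"RR-MS"}), frozenset({"P-MS"}))
        grid = tuple(ModelConfig("QDA", qda_reg=r) for r in (0.1, 0.3, 0.5))
        st = PipelineSettings(seed=2)
        best, scores = optimize_hyperparameters(
            table, task, "QDA", grid, st, return_scores=True
        )
        assert all(acc > 0.9 for acc in scores.values())
        assert best in grid

    def test_label_permuted_data_scores_near_chance(self):
        # groups drawn from an identical distribution = permuted labels
        table = generate_cohort(two_group_spec(n_a=12, n_b=12, seed=7))
        task = TaskDefinition("t", frozenset({"RR-MS"}), frozenset({"P-MS"}))
        grid = tuple(ModelConfig("KNN", knn_k=k) for k in (3, 5))
        st = PipelineSettings(seed=7)
        best, scores = optimize_hyperparameters(table, task, "KNN", grid, st, return_scores=True)
        n_folds = 24 * 22  # outer runs x inner folds
        se = np.sqrt(0.25 / n_folds)
        assert max(scores.values()) == pytest.approx(0.5, abs=3 * se + 0.05)

    def test_tie_breaks_to_simplest_config(self):
        a = ModelConfig("KNN", knn_k=5)
        b = ModelConfig("KNN", knn_k=1)
        assert b.complexity_key() < a.complexity_key()
        a2 = ModelConfig("QDA", qda_reg=0.1)
        b2 = ModelConfig("QDA", qda_reg=0.5)
        assert b2.complexity_key() < a2.complexity_key()  # higher shrinkage is simpler


class TestPermutationImportance:
    def test_constant_feature_has_exactly_zero_importance(self):
        table = generate_cohort(two_group_spec(n_a=8, n_b=8, shift={"GABA": 4.0}, seed=1))
        values = table.feature_matrix()
        values[:, table.feature_order.index("tCho")] = 2.0
        table = table.replace_features(values)
        task = TaskDefinition("t", frozenset({"RR-MS"}), frozenset({"P-MS"}))
        imp, sd = permutation_importance(
            table, task, ModelConfig("KNN", knn_k=3), "tCho", repeats=5, seed=0
        )
        assert imp == 0.0
        assert sd == 0.0

    def test_single_determining_feature_importance_near_accuracy_drop(self):
        # GABA alone separates the classes; others are pure noise
        table = generate_cohort(two_group_spec(n_a=10, n_b=10, shift={"GABA": 10.0}, seed=4))
        task = TaskDefinition("t", frozenset({"RR-MS"}), frozenset({"P-MS"}))
        repeats = 30
        imp, sd = permutation_importance(
            table, task, ModelConfig("QDA", qda_reg=0.1), "GABA", repeats=repeats, seed=4
        )
        # permuting the only informative feature drops accuracy to chance
        assert imp == pytest.approx(1.0 - 0.5, abs=max(3 * sd / np.sqrt(repeats), 0.08))

    def test_importance_invariant_to_record_order(self):
        table = generate_cohort(two_group_spec(n_a=8, n_b=8, shift={"GABA": 3.0}, seed=5))
        shuffled = FeatureTable(table.data.sample(frac=1, random_state=9).reset_index(drop=True))
        task = TaskDefinition("t", frozenset({"RR-MS"}), frozenset({"P-MS"}))
        cfg = ModelConfig("KNN", knn_k=3)
        a = permutation_importance(table, task, cfg, "GABA", repeats=10, seed=6)
        b = permutation_importance(shuffled, task, cfg, "GABA", repeats=10, seed=6)
        assert a == b

    def test_unknown_feature_rejected(self, prepared_table):
        with pytest.raises(ValueError, match="retained"):
            permutation_importance(
                prepared_table, RR_VS_P, ModelConfig("KNN", knn_k=3), "Lac", repeats=1
            )


class TestRunQuestion:
    def test_toy_smoke_one_record_per_planned_run(self):
        df = pd.DataFrame(
            [
                ["a", "RR-MS", 40.0] + [1.0] * 7,
                ["b", "RR-MS", 45.0] + [1.2] * 7,
                ["c", "P-MS", 50.0] + [3.0] * 7,
                ["d", "P-MS", 55.0] + [3.2] * 7,
            ],
            columns=["id", "group", "age"] + list(METABOLITES),
        )
        table = FeatureTable(df)
        st = PipelineSettings(
            grid=(ModelConfig("KNN", knn_k=1),), feature_elimination=False, seed=0
        )
        res = run_question(table, RR_VS_P, "KNN", st)
        assert len(res.outer_records) == len(res.outer_plan) == 4
        assert all(r.loop == "outer_heldout" for r in res.outer_records)

    def test_no_leakage_heldout_features_do_not_touch_its_model(self):
        table = generate_cohort(two_group_spec(n_a=6, n_b=6, shift={"GABA": 2.0}, seed=3))
        task = TaskDefinition("t", frozenset({"RR-MS"}), frozenset({"P-MS"}))
        st = PipelineSettings(grid=(ModelConfig("KNN", knn_k=3),), feature_elimination=False, seed=3)
        res = run_question(table, task, "KNN", st)
        held0 = res.outer_plan[0][0]
        # corrupt the held-out case's features wildly
        df = table.data.copy()
        row = df.index[df["id"] == held0][0]
        df.loc[row, list(METABOLITES)] = 999.0
        res2 = run_question(FeatureTable(df), task, "KNN", st)
        assert res2.outer_plan[0][0] == held0
        assert np.array_equal(res.models[0].params["X"], res2.models[0].params["X"])

    def test_bitwise_reproducibility_under_same_master_seed(self, prepared_table):
        st = PipelineSettings(grid=(DEFAULT_CONFIGS["QDA"],), feature_elimination=False, seed=9)
        r1 = run_question(prepared_table, RR_VS_P, "QDA", st)
        r2 = run_question(prepared_table, RR_VS_P, "QDA", st)
        assert [r.score for r in r1.outer_records] == [r.score for r in r2.outer_records]

    def test_records_carry_config_and_features(self, prepared_table):
        cfg = ModelConfig("KNN", knn_k=3)
        st = PipelineSettings(grid=(cfg,), feature_elimination=False, seed=1)
        res = run_question(prepared_table, RR_VS_P, "KNN", st)
        assert all(r.config_used == cfg for r in res.outer_records)
        assert all(r.features_used == tuple(METABOLITES) for r in res.outer_records)
        assert all(r.prediction == (1 if r.score >= 0 else -1) for r in res.outer_records)

    def test_missing_values_rejected_in_paper_mode(self, default_table):
        st = PipelineSettings(grid=(ModelConfig("KNN", knn_k=3),), feature_elimination=False)
        with pytest.raises(ValueError, match="impute"):
            run_question(default_table, MS_VS_HC, "KNN", st)

    def test_train_only_imputation_accepts_missing(self, default_table):
        from mrsdx.preprocess import age_correct

        table = age_correct(default_table)  # leave the 2 GABA cells missing
        st = PipelineSettings(
            grid=(ModelConfig("KNN", knn_k=3),), feature_elimination=False,
            imputation="train_only", seed=2,
        )
        res = run_question(table, MS_VS_HC, "KNN", st)
        assert len(res.outer_records) == 48

    def test_pooled_cv_truths_balanced_by_class(self, prepared_table):
        from mrsdx.validation import _TaskData, _pooled_cv

        data = _TaskData(prepared_table, RR_VS_P)
        plan = outer_split_plan(prepared_table, RR_VS_P)
        st = PipelineSettings(seed=0)
        records, _ = _pooled_cv(data, plan, tuple(METABOLITES), ModelConfig("KNN", knn_k=3), st)
        truths = [r.truth for r in records]
        assert truths.count(1) == truths.count(-1)
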