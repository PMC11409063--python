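"""Fold planning, leakage guards, metric oracles, factorial consistency."""

import json
import math

import numpy as np
import pytest

import lncbench as lb
from lncbench.cv_engine import LeakageError, pooled_sd

from conftest import brute_force_auroc, toy_dataset


def balanced_dataset(n=100, seed=1):
    rng = np.random.default_rng(seed)
    labels = np.tile([0, 1], n // 2)
    cnrci = np.where(labels == 1, 1.0, -1.0) * rng.uniform(0.2, 3.0, n)
    return toy_dataset(labels, cnrci)


class TestFoldPlan:
    def test_partition_arithmetic_5x2(self):
        plan = lb.make_fold_plan(balanced_dataset(100), n_folds=5, n_repeats=2, seed=0)
        assert len(plan.folds) == 10
        for train_ids, eval_ids in plan.folds:
            assert len(eval_ids) in (19, 20, 21)
            assert len(train_ids) + len(eval_ids) == 100
            assert not set(train_ids) & set(eval_ids)

    def test_eval_folds_partition_working_set_per_repeat(self):
        plan = lb.make_fold_plan(balanced_dataset(60), n_folds=5, n_repeats=2, seed=3)
        for rep in range(2):
            evals = [set(e) for _, e in plan.folds[rep * 5: (rep + 1) * 5]]
            assert sum(len(e) for e in evals) == 60
            assert set.union(*evals) == set(balanced_dataset(60).df.index)

    def test_records_sharing_a_gene_never_straddle_a_split(self):
        # transcript-style records: 2 records per gene
        labels = [0, 0, 1, 1] * 5
        cnrci = [-2.0, -1.8, 1.5, 2.1] * 5
        genes = [f"g{i // 2}" for i in range(20)]
        ids = [f"r{i}" for i in range(20)]
        ds = toy_dataset(labels, cnrci, genes=genes, record_ids=ids)
        plan = lb.make_fold_plan(ds, n_folds=2, n_repeats=3, seed=5)
        gene_of = dict(zip(ids, genes))
        for train_ids, eval_ids in plan.folds:
            train_genes = {gene_of[r] for r in train_ids}
            eval_genes = {gene_of[r] for r in eval_ids}
            assert not train_genes & eval_genes

    def test_same_seed_identical_plan(self):
        a = lb.make_fold_plan(balanced_dataset(80), seed=9)
        b = lb.make_fold_plan(balanced_dataset(80), seed=9)
        for (ta, ea), (tb, eb) in zip(a.folds, b.folds):
            assert list(ta) == list(tb) and list(ea) == list(eb)

    def test_holdout_fraction_shrinks_working_set(self):
        plan = lb.make_fold_plan(
            balanced_dataset(100), n_folds=5, n_repeats=1, holdout_fraction=0.1, seed=2
        )
        assert len(plan.holdout_ids) == 10
        working = set(plan.folds[0][0]) | set(plan.folds[0][1])
        assert len(working) == 90
        assert not working & set(plan.holdout_ids)

    def test_class_smaller_than_fold_count_is_an_error(self):
        ds = toy_dataset([0, 0, 0, 0, 1], [-1, -2, -3, -4, 2.0])
        with pytest.raises(ValueError, match="n_folds"):
            lb.make_fold_plan(ds, n_folds=5)


class TestComputeMetrics:
    def test_perfect_separation(self):
        m = lb.compute_metrics([1, 0, 1, 0], [1.0, 0.0, 1.0, 0.0])
        assert m["accuracy"] == 100 and m["f1"] == 100 and m["mcc"] == 1.0
        assert m["auprc"] == 100 and m["auroc"] == 100

    def test_constant_half_score_is_uninformative(self):
        # ties at the threshold go to the negative class
        m = lb.compute_metrics([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert m["auroc"] == 50.0 and m["accuracy"] == 50.0

    def test_hand_worked_pairwise_auroc(self):
        m = lb.compute_metrics([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.1])
        assert m["auroc"] == pytest.approx(75.0)

    def test_auroc_equals_all_pairs_statistic_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 20))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            m = lb.compute_metrics(labels, scores)
            assert m["auroc"] == pytest.approx(100 * brute_force_auroc(labels, scores))

    def test_mcc_recomputable_from_confusion_matrix(self):
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 2, 50)
        scores = rng.random(50)
        m = lb.compute_metrics(labels, scores)
        c = m["confusion"]
        num = c["tp"] * c["tn"] - c["fp"] * c["fn"]
        den = math.sqrt(
            (c["tp"] + c["fp"]) * (c["tp"] + c["fn"]) * (c["tn"] + c["fp"]) * (c["tn"] + c["fn"])
        )
        assert m["mcc"] == pytest.approx(num / den if den else 0.0)

    def test_single_class_labels_leave_rank_metrics_undefined(self):
        m = lb.compute_metrics([1, 1, 1], [0.2, 0.6, 0.9])
        assert math.isnan(m["auroc"]) and math.isnan(m["auprc"])
        assert m["accuracy"] == pytest.approx(100 * 2 / 3)


class TestLeakageAudit:
    def test_probe_reading_eval_fold_raises(self, small_dataset):
        ids = small_dataset.df.index.to_numpy()
        audited = lb.AuditedDataset(small_dataset, forbidden_ids=ids[:10])
        with pytest.raises(LeakageError):
            audited.take(ids[5:20])

    def test_training_side_access_is_allowed_and_recorded(self, small_dataset):
        ids = small_dataset.df.index.to_numpy()
        audited = lb.AuditedDataset(small_dataset, forbidden_ids=ids[:10])
        x, y = audited.take(ids[10:30])
        assert x.shape == (20, 1344) and len(y) == 20
        assert audited.accessed == set(ids[10:30])

    def test_unfeaturized_dataset_rejected(self):
        with pytest.raises(ValueError, match="featurized"):
            lb.AuditedDataset(balanced_dataset(10), forbidden_ids=[])


FAST_RF = lb.ModelSpec("random_forest", seed=0, overrides=(("n_estimators", 20),))


class TestRunCondition:
    def test_filter_outside_value_range_is_identity(self, small_dataset):
        # shift CNRCI values clear of the interval: none == all
        df = small_dataset.df.copy()
        df["cnrci"] = np.where(df["label"] == 1, 5.0, -5.0)
        ds = lb.LabeledDataset(df, small_dataset.features, small_dataset.feature_names)
        plan = lb.make_fold_plan(ds, n_folds=3, n_repeats=1, seed=4)
        rep_none = lb.run_condition(ds, FAST_RF, plan, lb.FilterSpec(-1, 1, "none"))
        rep_all = lb.run_condition(ds, FAST_RF, plan, lb.FilterSpec(-1, 1, "all"))
        assert rep_none.per_fold == rep_all.per_fold

    def test_eval_fold_reduced_to_one_class_records_nan_rank_metrics(self):
        # every cytoplasmic record sits inside the interval: eval_only folds
        # retain only nuclear records
        labels = [0, 1] * 10
        cnrci = [(-3.0 if l == 0 else 0.5) for l in labels]
        ds = toy_dataset(labels, cnrci)
        rng = np.random.default_rng(0)
        feats = rng.random((20, 4))
        ds = lb.LabeledDataset(ds.df, feats, ("a", "b", "c", "d"))
        plan = lb.make_fold_plan(ds, n_folds=2, n_repeats=1, seed=1)
        rep = lb.run_condition(ds, FAST_RF, plan, lb.FilterSpec(-1, 1, "eval_only"))
        assert rep.n_defined("auroc") == 0
        assert rep.n_defined("accuracy") == 2
        assert math.isnan(rep.mean("auroc"))


class TestFactorial:
    def test_exactly_four_reports_keyed_by_mode(self, small_dataset):
        plan = lb.make_fold_plan(small_dataset, n_folds=3, n_repeats=1, seed=2)
        reports = lb.run_factorial(small_dataset, FAST_RF, plan)
        assert set(reports) == {"all", "none", "train_only", "eval_only"}

    def test_factorial_matches_independent_condition_runs(self, small_dataset):
        plan = lb.make_fold_plan(small_dataset, n_folds=3, n_repeats=1, seed=2)
        reports = lb.run_factorial(small_dataset, FAST_RF, plan, (-1.0, 1.0))
        for mode in ("all", "none", "train_only", "eval_only"):
            single = lb.run_condition(
                small_dataset, FAST_RF, plan, lb.FilterSpec(-1.0, 1.0, mode)
            )
            assert single.to_json() == reports[mode].to_json()

    def test_eval_side_prefilter_folds_identical_across_modes(self, small_dataset):
        plan = lb.make_fold_plan(small_dataset, n_folds=3, n_repeats=2, seed=6)
        reports = lb.run_factorial(small_dataset, FAST_RF, plan)
        # same plan object: train sizes agree pairwise where training is shared
        for i in range(len(plan.folds)):
            assert reports["none"].per_fold[i]["n_train"] == \
                reports["eval_only"].per_fold[i]["n_train"]
            assert reports["all"].per_fold[i]["n_eval"] == \
                reports["eval_only"].per_fold[i]["n_eval"]

    def test_sweep_returns_one_quadruple_per_width(self, small_dataset):
        plan = lb.make_fold_plan(small_dataset, n_folds=3, n_repeats=1, seed=2)
        sweep = lb.run_interval_sweep(small_dataset, FAST_RF, plan, (0.5, 1.0))
        assert set(sweep) == {0.5, 1.0}
        for quad in sweep.values():
            assert set(quad) == {"all", "none", "train_only", "eval_only"}

    def test_sweep_width_one_equals_factorial(self, small_dataset):
        plan = lb.make_fold_plan(small_dataset, n_folds=3, n_repeats=1, seed=2)
        sweep = lb.run_interval_sweep(small_dataset, FAST_RF, plan, (1.0,))
        factorial = lb.run_factorial(small_dataset, FAST_RF, plan, (-1.0, 1.0))
        for mode in factorial:
            assert sweep[1.0][mode].to_json() == factorial[mode].to_json()


class TestDeterminism:
    @pytest.mark.parametrize("family", ["gbdt_default", "random_forest"])
    def test_identical_seeds_give_byte_identical_reports(self, small_dataset, family):
        spec = lb.ModelSpec(family, seed=0)
        plan = lb.make_fold_plan(small_dataset, n_folds=3, n_repeats=1, seed=8)
        a = lb.run_condition(small_dataset, spec, plan, lb.FilterSpec(mode="none"))
        b = lb.run_condition(small_dataset, spec, plan, lb.FilterSpec(mode="none"))
        assert a.to_json() == b.to_json()

    def test_report_json_round_trips(self, small_dataset):
        plan = lb.make_fold_plan(small_dataset, n_folds=3, n_repeats=1, seed=8)
        rep = lb.run_condition(small_dataset, FAST_RF, plan, lb.FilterSpec(mode="none"))
        payload = json.loads(rep.to_json())
        assert payload["condition"] == "none"
        assert len(payload["per_fold"]) == 3


class TestModelFamilies:
    @pytest.mark.parametrize("family", ["gradient_boosting", "svm_rbf", "mlp3"])
    def test_other_architectures_run_end_to_end(self, small_dataset, family):
        overrides = ()
        if family == "gradient_boosting":
            overrides = (("n_estimators", 10),)
        elif family == "mlp3":
            overrides = (("max_iter", 10),)
        spec = lb.ModelSpec(family, seed=0, overrides=overrides)
        plan = lb.make_fold_plan(small_dataset, n_folds=2, n_repeats=1, seed=3)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = lb.run_condition(small_dataset, spec, plan, lb.FilterSpec(mode="none"))
        assert 0 <= rep.mean("auroc") <= 100

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            lb.ModelSpec("deep_thought")

    def test_pooled_sd_is_rms_of_fold_sds(self, small_dataset):
        plan = lb.make_fold_plan(small_dataset, n_folds=3, n_repeats=1, seed=8)
        rep = lb.run_condition(small_dataset, FAST_RF, plan, lb.FilterSpec(mode="none"))
        expected = math.sqrt((rep.sd("auroc") ** 2 + rep.sd("auroc") ** 2) / 2)
        assert pooled_sd(rep, rep) == pytest.approx(expected)
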