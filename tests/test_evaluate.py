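"""Validation protocol: folds, metrics, aggregation, fusion, ablation axes."""

import numpy as np
import pytest

from drawkin.architecture import ModelConfig
from drawkin.evaluate import (
    ablation_variants,
    classify,
    compute_metrics,
    cross_validate,
    fuse_tasks,
    make_subject_folds,
    paired_comparison,
)
from drawkin.model import TrainConfig
from drawkin.records import Label


def _subjects(n_pd, n_hc):
    return [(f"P{i}", Label.PD) for i in range(n_pd)] + [
        (f"H{i}", Label.HC) for i in range(n_hc)
    ]


class TestFolds:
    def test_perfectly_divisible_stratification(self):
        fa = make_subject_folds(_subjects(10, 10), k=5, seed=0)
        for f in range(5):
            ids = fa.fold_subjects(f)
            assert sum(i.startswith("P") for i in ids) == 2
            assert sum(i.startswith("H") for i in ids) == 2

    def test_study_cohort_shape_28_30_k10(self):
        fa = make_subject_folds(_subjects(28, 30), k=10, seed=1)
        sizes, pds = [], []
        for f in range(10):
            ids = fa.fold_subjects(f)
            sizes.append(len(ids))
            pds.append(sum(i.startswith("P") for i in ids))
        assert set(pds) <= {2, 3} and sum(pds) == 28
        assert all(3 == len(ids) - p for ids, p in zip([fa.fold_subjects(f) for f in range(10)], pds))
        assert set(sizes) <= {5, 6}

    def test_partition_disjoint_exhaustive_deterministic(self):
        subs = _subjects(7, 9)
        fa1 = make_subject_folds(subs, k=4, seed=9)
        fa2 = make_subject_folds(subs, k=4, seed=9)
        assert fa1.mapping == fa2.mapping
        assert sorted(fa1.mapping) == sorted(s for s, _ in subs)
        assert set(fa1.mapping.values()) == set(range(4))

    def test_k_larger_than_cohort_rejected(self):
        with pytest.raises(ValueError):
            make_subject_folds(_subjects(2, 2), k=5, seed=0)

    def test_stratification_matches_sklearn_balance(self):
        # independent oracle: sklearn's StratifiedKFold class counts per fold
        from collections import Counter

        from sklearn.model_selection import StratifiedKFold

        subs = _subjects(28, 30)
        y = [0 if l is Label.HC else 1 for _, l in subs]
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        sk_counts = sorted(
            Counter(np.asarray(y)[test].tolist()).get(1, 0) for _, test in skf.split(y, y)
        )
        fa = make_subject_folds(subs, k=10, seed=0)
        our_counts = sorted(
            sum(i.startswith("P") for i in fa.fold_subjects(f)) for f in range(10)
        )
        assert our_counts == sk_counts


class TestMetrics:
    def test_confusion_matrix_hand_oracle(self):
        # TP=25, FN=3, TN=27, FP=3
        y = np.array([1] * 28 + [0] * 30)
        yp = np.array([1] * 25 + [0] * 3 + [0] * 27 + [1] * 3)
        m = compute_metrics(y, yp)
        assert m.sen == pytest.approx(89.29, abs=0.005)
        assert m.spe == pytest.approx(90.00, abs=0.005)
        assert m.acc == pytest.approx(89.66, abs=0.005)
        assert m.f1 == pytest.approx(89.29, abs=0.005)

    def test_perfect_prediction(self):
        y = np.array([1, 1, 0, 0])
        m = compute_metrics(y, y, scores=np.array([0.9, 0.8, 0.1, 0.2]))
        assert (m.acc, m.sen, m.spe, m.f1) == (100.0, 100.0, 100.0, 100.0)
        assert m.auc == 1.0

    def test_all_tied_scores_give_half_auc(self):
        y = np.array([1, 0, 1, 0])
        m = compute_metrics(y, np.zeros(4), scores=np.full(4, 0.5))
        assert m.auc == 0.5

    def test_single_class_truth_reports_nan(self):
        m = compute_metrics(np.ones(4), np.ones(4), scores=np.ones(4))
        assert np.isnan(m.spe) and np.isnan(m.auc) and m.sen == 100.0

    def test_auc_matches_sklearn_on_random_scores(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        for _ in range(10):
            y = rng.integers(0, 2, size=30)
            if y.min() == y.max():
                continue
            s = rng.random(30).round(1)  # force ties
            m = compute_metrics(y, (s > 0.5).astype(int), scores=s)
            assert m.auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestDecisionRules:
    def test_threshold_is_strict(self):
        assert classify(0.6) is Label.PD
        assert classify(0.5) is Label.HC

    def test_fusion_arithmetic(self):
        assert fuse_tasks(0.7, 0.4) == pytest.approx(0.55)
        assert classify(fuse_tasks(0.7, 0.4)) is Label.PD
        assert classify(fuse_tasks(0.5, 0.5)) is Label.HC
        assert fuse_tasks(0.3, 0.3) == 0.3

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fuse_tasks(1.2, 0.5)
        with pytest.raises(ValueError):
            classify(-0.1)


class TestPairedComparison:
    def test_identical_vectors_degenerate(self):
        r = paired_comparison([1, 2, 3], [1, 2, 3])
        assert r.degenerate and r.p_value == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        r = paired_comparison([1, 2, 3, 4], [0, 1, 2, 3])
        assert r.degenerate and r.mean_difference == 1.0

    def test_matches_closed_form_t(self):
        a, b = np.array([2.0, 4.0, 6.0]), np.array([1.0, 3.0, 8.0])
        d = a - b  # [1, 1, -2]: mean 0, sd sqrt(3)
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        r = paired_comparison(a, b)
        assert r.statistic == pytest.approx(t_hand, abs=1e-12)
        assert not r.degenerate

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_comparison([1, 2], [1, 2, 3])


@pytest.fixture(scope="module")
def mini_report(small_cohort):
    return cross_validate(
        small_cohort,
        k=2,
        repetitions=2,
        seed=5,
        model_config=ModelConfig.small(n_channels=4),
        train_config=TrainConfig(epochs=2, batch_size=4),
    )


class TestCrossValidation:

    def test_no_leakage_and_full_coverage(self, mini_report, small_cohort):
        assert mini_report.leakage_overlaps == 0
        for rep in mini_report.repetitions:
            assert sorted(rep.subject_probs) == sorted(s.subject_id for s in small_cohort)
            assert rep.metrics["fused"].n == len(small_cohort)

    def test_fresh_folds_per_repetition(self, mini_report):
        maps = [rep.fold_assignment.mapping for rep in mini_report.repetitions]
        assert maps[0] != maps[1]

    def test_fusion_is_mean_of_task_probs(self, mini_report):
        for rep in mini_report.repetitions:
            for sid, p in rep.subject_probs.items():
                assert p["fused"] == pytest.approx((p["spiral"] + p["wave"]) / 2)

    def test_report_json_schema(self, mini_report, tmp_path):
        import json

        path = mini_report.to_json(tmp_path / "report.json")
        payload = json.loads(path.read_text())
        assert payload["protocol"]["k"] == 2
        assert payload["leakage_overlaps"] == 0
        assert "fused" in payload["aggregate"]
        assert len(payload["repetitions"]) == 2

    def test_fusion_identity_when_tasks_agree(self, mini_report):
        # recomputing fused metrics from identical per-task probabilities
        rep = mini_report.repetitions[0]
        y = np.array([int(rep.subject_probs[s]["label"]) for s in rep.subject_probs])
        ps = np.array([rep.subject_probs[s]["spiral"] for s in rep.subject_probs])
        same = compute_metrics(y, (ps > 0.5).astype(int), ps)
        fused_same = compute_metrics(
            y, (np.vectorize(fuse_tasks)(ps, ps) > 0.5).astype(int), ps
        )
        assert same == fused_same


class TestAblationAxes:
    def test_window_axis_five_variants(self):
        vs = ablation_variants("window_size")
        assert len(vs) == 5
        assert [v["window_samples"] for v in vs] == [8, 16, 32, 64, 128]

    def test_branch_axis_baseline_plus_five(self):
        base = ModelConfig(n_channels=4)
        vs = ablation_variants("branch", base)
        assert len(vs) == 6
        assert vs[0]["name"] == "baseline"
        from drawkin.architecture import count_parameters

        counts = [count_parameters(v["model_config"]) for v in vs]
        assert len(set(counts)) == 6  # all parameter counts distinct

    def test_feature_axis_six_variants(self):
        assert len(ablation_variants("features")) == 6

    def test_depth_and_cell_axes(self):
        assert len(ablation_variants("depth")) == 4
        assert [v["name"] for v in ablation_variants("cell")] == ["BiRNN", "BiLSTM", "BiGRU"]

    def test_unknown_axis_rejected(self):
        with pytest.raises(ValueError):
            ablation_variants("optimizer")

    def test_suite_emits_long_format_table(self, small_cohort):
        from drawkin.evaluate import ablation_suite

        table = ablation_suite(
            small_cohort,
            axes=["cell"],
            base=ModelConfig.small(n_channels=4),
            k=2,
            repetitions=1,
            seed=0,
            train_config=TrainConfig(epochs=1, batch_size=4),
        )
        assert set(table.columns) == {"axis", "variant", "scope", "metric", "mean", "sd"}
        assert sorted(table["variant"].unique()) == ["BiGRU", "BiLSTM", "BiRNN"]
        accs = table[(table.metric == "acc") & (table.scope == "fused")]
        assert len(accs) == 3 and accs["mean"].between(0, 100).all()
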