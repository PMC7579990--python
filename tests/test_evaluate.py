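import numpy as np
import pytest
from hypothesis import given, strategies as st

from tnfpred import (
    ClassifierSpec,
    MetricSet,
    PipelineConfig,
    RunReport,
    TrainingConfig,
    confusion,
    cross_validate,
    make_splits,
    metrics_from_counts,
    roc_auc,
    run_protocol,
    write_report_table,
)
from tnfpred.evaluate import ConfusionCounts


class TestConfusion:
    def test_enumerated_example(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.TP, c.FN, c.TN, c.FP) == (1, 1, 1, 1)

    def test_perfect_predictions(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.FP == 0 and c.FN == 0 and c.total == 3

    def test_empty_vectors_rejected(self):
        with pytest.raises(ValueError):
            confusion([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestMetricFormulas:
    def test_perfect_classifier(self):
        m = metrics_from_counts(ConfusionCounts(TP=4, TN=30, FP=0, FN=0))
        assert (m.sensitivity, m.specificity, m.accuracy, m.mcc) == (1, 1, 1, 1)

    def test_hand_computed_case(self):
        # Sen = 3/4, Spec = 29/30, Acc = 32/34,
        # MCC = (3*29 - 1*1)/sqrt(4*4*30*30) = 86/120
        m = metrics_from_counts(ConfusionCounts(TP=3, FN=1, TN=29, FP=1))
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(29 / 30)
        assert m.accuracy == pytest.approx(32 / 34)
        assert m.mcc == pytest.approx(86 / 120)

    def test_all_negative_predictor_mcc_zero_by_convention(self):
        m = metrics_from_counts(ConfusionCounts(TP=0, FN=4, TN=30, FP=0))
        assert m.sensitivity == 0.0 and m.mcc == 0.0

    @given(tp=st.integers(0, 50), tn=st.integers(0, 50),
           fp=st.integers(0, 50), fn=st.integers(0, 50))
    def test_metric_bounds_on_random_counts(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        m = metrics_from_counts(ConfusionCounts(tp, tn, fp, fn))
        assert 0 <= m.sensitivity <= 1 and 0 <= m.specificity <= 1
        assert 0 <= m.accuracy <= 1 and -1 <= m.mcc <= 1


def pairwise_concordance(labels, scores):
    """Brute-force AUC: concordant positive-negative pairs, ties count half."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_known_example(self):
        assert roc_auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([1, 1, 0], [2.0, 1.5, -1.0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([1, 0, 1, 0], [0.3, 0.3, 0.3, 0.3]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.2, 0.3])

    @given(st.integers(0, 10_000))
    def test_matches_pairwise_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.normal(size=n), 1)  # rounding forces some ties
        assert roc_auc(labels, scores) == pytest.approx(pairwise_concordance(labels, scores))

    @given(st.integers(0, 10_000))
    def test_complement_under_score_negation(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.array([1] * 5 + [0] * 7)
        scores = rng.permutation(12).astype(float)  # tie-free
        assert roc_auc(labels, scores) + roc_auc(labels, -scores) == pytest.approx(1.0)


FAST_PIPELINE = PipelineConfig(
    grams=(2,),
    embed_config=TrainingConfig(min_count=2, epochs=2),
    classifier=ClassifierSpec("svm", {"C": 1.0, "gamma": "scale"}),
)


class TestProtocol:
    def test_every_cv_sequence_scored_exactly_once(self, small_dataset):
        counts = small_dataset.label_counts()
        design = {1: (counts[1] - 2, 2), 0: (counts[0] - 6, 6)}
        (split,) = make_splits(small_dataset, n_runs=1, design=design, base_seed=0)
        _, scored = cross_validate(small_dataset, split, FAST_PIPELINE)
        assert sorted(scored) == sorted(split.cv_ids)

    def test_run_protocol_aggregates_over_all_runs(self, small_dataset, tmp_path):
        counts = small_dataset.label_counts()
        design = {1: (counts[1] - 2, 2), 0: (counts[0] - 6, 6)}
        splits = make_splits(small_dataset, n_runs=2, design=design, base_seed=1)
        reports = run_protocol(
            small_dataset, splits, {"2g/svm": FAST_PIPELINE}, audit_path=tmp_path / "audit.jsonl"
        )
        rep = reports["2g/svm"]
        assert len(rep.cv) == 2 and len(rep.independent) == 2 and not rep.errors
        assert (tmp_path / "audit.jsonl").read_text().count("\n") == 2
        write_report_table(reports, tmp_path / "report.tsv")
        text = (tmp_path / "report.tsv").read_text()
        assert "2g/svm\tcv\t" in text and "±" in text

    def test_cell_failure_is_recorded_not_fatal(self, small_dataset):
        counts = small_dataset.label_counts()
        design = {1: (counts[1] - 2, 2), 0: (counts[0] - 6, 6)}
        splits = make_splits(small_dataset, n_runs=1, design=design, base_seed=1)
        bad = PipelineConfig(grams=(5,), embed_config=TrainingConfig(min_count=10_000))
        reports = run_protocol(small_dataset, splits, {"bad": bad, "ok": FAST_PIPELINE})
        assert reports["bad"].errors and not reports["bad"].cv
        assert reports["ok"].cv

    def test_no_splits_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            run_protocol(small_dataset, [], {"x": FAST_PIPELINE})


class TestRunReport:
    def test_identical_per_run_values_give_zero_std(self):
        rep = RunReport("cell", cv=[MetricSet(1, 1, 1, 1, 0.9)] * 3)
        mean, sd = rep.aggregate("cv", "auc")
        assert mean == pytest.approx(0.9) and sd == 0.0

    def test_sample_standard_deviation_used(self):
        rep = RunReport("cell", cv=[
            MetricSet(0, 0, 0.8, 0, None), MetricSet(0, 0, 1.0, 0, None)])
        mean, sd = rep.aggregate("cv", "accuracy")
        assert mean == pytest.approx(0.9)
        assert sd == pytest.approx(np.std([0.8, 1.0], ddof=1))
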