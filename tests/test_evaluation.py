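from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from cmic.embedding import EmbeddingConfig
from cmic.evaluation import (
    CmicPipeline,
    compute_metrics,
    cross_validate,
    evaluate_long,
    make_embedding_table,
    stratified_folds,
    sweep,
)
from cmic.gru_model import PredictionResult, TrainConfig
from cmic.sequence_ops import DnaSequence, SegmentationConfig


def toy_dataset(n0=6, n1=6, length=60, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for label, n in ((0, n0), (1, n1)):
        for i in range(n):
            seq = "".join(rng.choice(list("ACGT"), length))
            out.append(DnaSequence(f"c{label}_{i}", seq, label))
    return out


@dataclass
class OracleFitted:
    train_ids: frozenset
    prob_fn: object

    def predict(self, seqs):
        out = []
        for s in seqs:
            p = float(self.prob_fn(s))
            out.append(PredictionResult(s.id, np.array([p, p]), p,
                                        1 if p > 0.5 else 0))
        return out


@dataclass
class OraclePipeline:
    prob_fn: object

    def fit(self, train_seqs, seed=0):
        return OracleFitted(frozenset(s.id for s in train_seqs), self.prob_fn)


class LeakyPipeline:
    """Pretends to have trained on every CGI, including held-out ones."""

    def __init__(self, ids):
        self.ids = frozenset(ids)

    def fit(self, train_seqs, seed=0):
        return OracleFitted(self.ids, lambda s: 0.9)


class TestStratifiedFolds:
    def test_exact_divisibility_one_per_class_per_fold(self):
        ds = toy_dataset(3, 3)
        folds = stratified_folds(ds, k=3, seed=0)
        for f in range(3):
            members = [s for s in ds if folds[s.id] == f]
            assert sorted(s.label for s in members) == [0, 1]

    def test_imbalanced_150_60_splits_into_50_20_folds(self):
        ds = toy_dataset(150, 60, length=30)
        folds = stratified_folds(ds, k=3, seed=1)
        for f in range(3):
            members = [s for s in ds if folds[s.id] == f]
            labels = [s.label for s in members]
            assert labels.count(0) == 50 and labels.count(1) == 20

    def test_deterministic_given_seed(self):
        ds = toy_dataset()
        assert stratified_folds(ds, 3, 7) == stratified_folds(ds, 3, 7)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(toy_dataset(2, 6), k=3)


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1])
        rep = compute_metrics(y, y, probs=y.astype(float))
        assert rep.balanced_accuracy == rep.f_measure == rep.mcc == rep.auc == 1.0

    def test_one_of_each_confusion_cell(self):
        # TP=FP=TN=FN=1 -> balanced accuracy 0.5, F 0.5, MCC 0
        y_true = np.array([1, 0, 0, 1])
        y_pred = np.array([1, 1, 0, 0])
        rep = compute_metrics(y_true, y_pred)
        assert rep.balanced_accuracy == pytest.approx(0.5)
        assert rep.f_measure == pytest.approx(0.5)
        assert rep.mcc == pytest.approx(0.0)

    def test_all_predicted_positive_mcc_zero_convention(self):
        rep = compute_metrics(np.array([0, 1, 1]), np.array([1, 1, 1]))
        assert rep.mcc == 0.0

    def test_single_class_auc_missing(self):
        rep = compute_metrics(np.array([1, 1]), np.array([1, 0]),
                              probs=np.array([0.9, 0.2]))
        assert rep.auc is None

    def test_auc_invariant_under_monotone_transform(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        p = np.array([0.1, 0.8, 0.4, 0.6, 0.9, 0.2])
        a1 = compute_metrics(y, (p > 0.5).astype(int), p).auc
        a2 = compute_metrics(y, (p > 0.5).astype(int), np.log(p / (1 - p))).auc
        assert a1 == pytest.approx(a2)


class TestCrossValidate:
    def test_truth_oracle_scores_one_everywhere(self):
        ds = toy_dataset()
        pipe = OraclePipeline(lambda s: 0.99 if s.label == 1 else 0.01)
        cv = cross_validate(ds, pipe, k=3, seed=0)
        for rep in cv.fold_reports["per_cgi"]:
            assert rep.balanced_accuracy == rep.f_measure == rep.mcc == 1.0
        assert cv.summary["per_cgi"].auc == 1.0

    def test_constant_half_probability_gives_chance_balanced_accuracy(self):
        ds = toy_dataset()
        cv = cross_validate(ds, OraclePipeline(lambda s: 0.5), k=3, seed=0)
        assert cv.summary["per_cgi"].balanced_accuracy == pytest.approx(0.5)

    def test_leaky_pipeline_triggers_audit(self):
        ds = toy_dataset()
        with pytest.raises(AssertionError, match="test CGIs"):
            cross_validate(ds, LeakyPipeline([s.id for s in ds]), k=3, seed=0)

    def test_standard_error_uses_k_minus_one(self):
        ds = toy_dataset(9, 9)
        # oracle correct only on class 1 -> per-fold metrics identical, SE 0
        cv = cross_validate(ds, OraclePipeline(lambda s: 0.9), k=3, seed=0)
        assert cv.summary["per_cgi"].balanced_accuracy_se == pytest.approx(0.0)


def tiny_configs():
    seg = SegmentationConfig(k_min=2, k_max=4, n_replicates=1, seed=0)
    emb = EmbeddingConfig(dim=4, window=3, corpus_replicates=1, epochs=1,
                          batch_size=32, seed=0)
    tr = TrainConfig(epochs=1, batch_size=4, hidden_dim=2, dropout=0.0)
    return seg, emb, tr


class TestSweep:
    def test_n_replicates_grid_one_row_per_point(self):
        ds = toy_dataset(3, 3, length=30)
        seg, emb, tr = tiny_configs()
        table = sweep(ds, "n_replicates", [1, 2], seg, emb, tr, k=3)
        assert list(table["n"]) == [1, 2]
        assert len(table) == 2

    def test_invalid_k_pair_rejected(self):
        ds = toy_dataset(3, 3, length=30)
        seg, emb, tr = tiny_configs()
        with pytest.raises(ValueError, match="k_max-k_min"):
            sweep(ds, "k_range", [(4, 4)], seg, emb, tr)

    def test_embedding_scheme_grid_covers_eight_methods(self):
        ds = toy_dataset(3, 3, length=30)
        seg, emb, tr = tiny_configs()
        grid = [(s, m) for s in ("splitDNA2vec", "splitDNA2vec-sh", "dna2vec",
                                 "dna2vec-N1000") for m in ("C", "V")]
        table = sweep(ds, "embedding_scheme", grid, seg, emb, tr, k=3)
        assert len(table) == 8
        assert set(table["scheme"]) == {s for s, _ in grid}


class TestEvaluateLong:
    def make_fitted(self):
        return OracleFitted(frozenset(),
                            lambda s: 0.9 if s.label == 1 else 0.1)

    def test_six_bins_with_expected_labels(self):
        seqs = [DnaSequence(f"l{i}", "ACGT" * (150 + 50 * i), i % 2)
                for i in range(8)]  # lengths 600..2000
        out = evaluate_long(self.make_fitted(), seqs)
        assert list(out) == ["501-600", "601-700", "701-800", "801-900",
                             "901-1000", "1001-"]

    def test_empty_long_set_all_bins_missing(self):
        out = evaluate_long(self.make_fitted(), [])
        assert all(v is None for v in out.values())

    def test_populated_bin_scores_oracle_perfectly(self):
        seqs = [DnaSequence("a", "A" * 550, 0), DnaSequence("b", "C" * 560, 1)]
        out = evaluate_long(self.make_fitted(), seqs)
        assert out["501-600"].f_measure == 1.0
        assert out["1001-"] is None
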