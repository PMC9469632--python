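import numpy as np
import pytest

from cmic.embedding import EmbeddingTable
from cmic.gru_model import (
    GruCellWeights,
    GruModel,
    TrainConfig,
    batch_loss_and_grads,
    bigru_forward,
    gru_step,
    loss,
    predict_cgi,
    predict_sentence,
    predict_sentences,
    train,
)
from cmic.sequence_ops import DnaSequence, SegmentationConfig
from oracles import scalar_bigru, scalar_gru_step


def zero_cell(dim, hidden):
    z = lambda *s: np.zeros(s)
    return GruCellWeights(
        W_r=z(hidden, dim), U_r=z(hidden, hidden), b_r=z(hidden),
        W_z=z(hidden, dim), U_z=z(hidden, hidden), b_z=z(hidden),
        W=z(hidden, dim), U=z(hidden, hidden), b_h=z(hidden),
    )


def random_cell(dim, hidden, rng):
    return GruCellWeights.initialize(dim, hidden, rng)


def small_model(rng, hidden=3, dim=4, mode="C", seed=0):
    vocab = ["AA", "AC", "AG", "AT", "CA", "CC", "GG", "GT", "TT"]
    table = EmbeddingTable({t: rng.normal(size=dim) for t in vocab}, dim)
    return GruModel.from_embedding(table, hidden=hidden,
                                   embedding_trainable=mode, seed=seed)


class TestGruStep:
    def test_zero_weights_halve_previous_state(self):
        # sigma(0)=0.5 and tanh(0)=0 make h_t = 0.5 * h_{t-1} exactly
        cell = zero_cell(3, 4)
        h_prev = np.array([0.4, -0.8, 1.0, 0.0])
        np.testing.assert_allclose(
            gru_step(np.ones(3), h_prev, cell), 0.5 * h_prev, rtol=0, atol=0
        )

    def test_zero_state_zero_bias_closed_form(self, rng):
        cell = zero_cell(3, 2)
        cell.W_z[:] = rng.normal(size=(2, 3))
        cell.W[:] = rng.normal(size=(2, 3))
        x = rng.normal(size=3)
        expected = (1 - 1 / (1 + np.exp(-cell.W_z @ x))) * np.tanh(cell.W @ x)
        np.testing.assert_allclose(gru_step(x, np.zeros(2), cell), expected,
                                   atol=1e-12)

    def test_matches_scalar_oracle(self, rng):
        for _ in range(30):
            cell = random_cell(3, 2, rng)
            x, h = rng.normal(size=3), rng.normal(size=2)
            np.testing.assert_allclose(
                gru_step(x, h, cell), scalar_gru_step(x, h, cell), atol=1e-6
            )

    def test_affine_bound_property(self, rng):
        # each component of h_t lies between h_{t-1} and the candidate
        for _ in range(20):
            cell = random_cell(4, 3, rng)
            x, h = rng.normal(size=4), rng.normal(size=3)
            r = 1 / (1 + np.exp(-(cell.W_r @ x + cell.U_r @ h + cell.b_r)))
            hc = np.tanh(cell.W @ x + cell.U @ (r * h) + cell.b_h)
            h_new = gru_step(x, h, cell)
            lo, hi = np.minimum(h, hc), np.maximum(h, hc)
            assert np.all(h_new >= lo - 1e-12) and np.all(h_new <= hi + 1e-12)


class TestBigru:
    def test_length_one_equals_single_step(self, rng):
        m = small_model(rng, hidden=3, dim=4)
        x = rng.normal(size=(1, 4))
        out = bigru_forward(x, m)
        np.testing.assert_allclose(out[:3], gru_step(x[0], np.zeros(3),
                                                     m.forward_cell), atol=1e-12)
        np.testing.assert_allclose(out[3:], gru_step(x[0], np.zeros(3),
                                                     m.backward_cell), atol=1e-12)

    def test_palindrome_with_tied_cells(self, rng):
        m = small_model(rng, hidden=2, dim=3)
        for k in ("W_r", "U_r", "b_r", "W_z", "U_z", "b_z", "W", "U", "b_h"):
            m.params[f"b_{k}"] = m.params[f"f_{k}"].copy()
        seq = rng.normal(size=(3, 3))
        pal = np.vstack([seq, seq[::-1]])
        out = bigru_forward(pal, m)
        np.testing.assert_allclose(out[:2], out[2:], atol=1e-12)

    def test_matches_scalar_oracle_many_instances(self, rng):
        m = small_model(rng, hidden=2, dim=3)
        for _ in range(30):
            xs = rng.normal(size=(int(rng.integers(1, 6)), 3))
            np.testing.assert_allclose(
                bigru_forward(xs, m),
                scalar_bigru(xs, m.forward_cell, m.backward_cell),
                atol=1e-6,
            )

    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(ValueError):
            bigru_forward(np.zeros((0, 4)), small_model(rng))


class TestPadding:
    def test_padded_positions_do_not_affect_output(self, rng):
        """A sentence scored alone equals the same sentence inside a padded
        batch next to a much longer one."""
        m = small_model(rng, hidden=3, dim=4)
        short = ["AA", "GT"]
        long_ = ["CC"] * 9
        alone = predict_sentences([short], m)[0]
        batched = predict_sentences([short, long_], m)[0]
        assert alone == pytest.approx(batched, abs=1e-12)


class TestPredict:
    def test_zero_head_gives_half(self, rng):
        m = small_model(rng)
        m.params["head_w"][:] = 0.0
        m.params["head_b"][:] = 0.0
        assert predict_sentence(["AA", "GT", "CC"], m) == 0.5

    def test_probability_strictly_inside_unit_interval(self, rng):
        m = small_model(rng)
        p = predict_sentence(["AA", "GT", "CC", "TT"], m)
        assert 0.0 < p < 1.0

    def test_inference_deterministic(self, rng):
        m = small_model(rng)
        s = ["AC", "GG", "TT"]
        assert predict_sentence(s, m) == predict_sentence(s, m)

    def test_cgi_tie_called_methylated(self, rng):
        m = small_model(rng)
        m.params["head_w"][:] = 0.0
        m.params["head_b"][:] = 0.0
        seq = DnaSequence("x", "ACGTACGTACGT", label=0)
        r = predict_cgi(seq, m, SegmentationConfig(k_min=2, k_max=2,
                                                   n_replicates=2))
        assert r.probability == 0.5 and r.label == 0  # strict > 0.5 rule

    def test_cgi_aggregates_over_2n_sentences(self, rng):
        m = small_model(rng)
        seq = DnaSequence("x", "ACGTACGTACGT")
        r = predict_cgi(seq, m, SegmentationConfig(k_min=2, k_max=2,
                                                   n_replicates=1))
        assert len(r.sentence_probs) == 2
        assert r.probability == pytest.approx(float(r.sentence_probs.mean()))


class TestLoss:
    def test_uninformative_predictions_give_m_log2(self):
        m_ = 7
        assert loss(np.full(m_, 0.5), np.ones(m_)) == pytest.approx(m_ * np.log(2))

    def test_perfect_predictions_near_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        assert loss(np.array([1.0, 0.0, 1.0]), y) == pytest.approx(0.0, abs=1e-5)

    def test_decay_term_is_alpha_times_l2_norm(self):
        # zero data term; hand-set weights with global norm 3
        w = [np.array([3.0, 0.0]), np.zeros(4)]
        val = loss(np.array([1.0]), np.array([1.0]), weights=w, alpha=0.01)
        assert val == pytest.approx(0.03, abs=1e-6)

    def test_squared_variant(self):
        w = [np.array([2.0])]
        val = loss(np.array([1.0]), np.array([1.0]), weights=w, alpha=0.5,
                   squared=True)
        assert val == pytest.approx(2.0, abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            loss(np.array([0.5]), np.array([1.0, 0.0]))


class TestGradients:
    @pytest.mark.parametrize("mode,squared", [("C", False), ("V", False),
                                              ("C", True)])
    def test_analytic_gradients_match_central_differences(self, rng, mode,
                                                          squared):
        m = small_model(rng, hidden=2, dim=2, mode=mode, seed=3)
        cfg = TrainConfig(dropout=0.0, weight_decay=0.01, hidden_dim=2,
                          decay_squared=squared)
        ids = [m.token_ids(["AA", "AC", "GG"]), m.token_ids(["GT", "TT"])]
        y = [1.0, 0.0]
        _, g = batch_loss_and_grads(m, ids, y, cfg)
        max_rel = 0.0
        for k in m.trainable_keys():
            p = m.params[k]
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                old = p[idx]
                h = 1e-6
                p[idx] = old + h
                lp, _ = batch_loss_and_grads(m, ids, y, cfg)
                p[idx] = old - h
                lm, _ = batch_loss_and_grads(m, ids, y, cfg)
                p[idx] = old
                num = (lp - lm) / (2 * h)
                denom = max(abs(num), abs(g[k][idx]), 1e-8)
                if denom > 1e-8:
                    max_rel = max(max_rel, abs(num - g[k][idx]) / denom)
        assert max_rel <= 1e-4


class TestTrain:
    def toy_dataset(self):
        return [(["AA", "AA", "AA"], 0), (["GG", "GG", "GG"], 1)] * 8

    def test_loss_descends_on_separable_toy(self, rng):
        m = small_model(rng, hidden=4, dim=4, seed=1)
        cfg = TrainConfig(epochs=8, learning_rate=0.01, batch_size=4,
                          dropout=0.0, weight_decay=0.0, hidden_dim=4)
        _, trace = train(self.toy_dataset(), m, cfg)
        assert trace[-1] < trace[0]

    def test_frozen_embedding_unchanged_and_trainable_changes(self, rng):
        for mode, should_change in (("C", False), ("V", True)):
            m = small_model(rng, hidden=4, dim=4, mode=mode, seed=1)
            before = m.params["emb"].copy()
            cfg = TrainConfig(epochs=2, learning_rate=0.01, batch_size=4,
                              dropout=0.0, hidden_dim=4)
            train(self.toy_dataset(), m, cfg)
            changed = not np.array_equal(before, m.params["emb"])
            assert changed == should_change

    def test_training_reproducible_for_fixed_seed(self, rng):
        results = []
        for _ in range(2):
            m = small_model(np.random.default_rng(7), hidden=3, dim=4, seed=2)
            cfg = TrainConfig(epochs=2, learning_rate=0.01, batch_size=4,
                              hidden_dim=3, seed=11)
            m, _ = train(self.toy_dataset(), m, cfg)
            results.append({k: v.copy() for k, v in m.params.items()})
        for k in results[0]:
            np.testing.assert_array_equal(results[0][k], results[1][k])

    def test_single_class_dataset_warns(self, rng):
        m = small_model(rng, hidden=2, dim=4)
        cfg = TrainConfig(epochs=1, batch_size=4, hidden_dim=2)
        with pytest.warns(UserWarning, match="single class"):
            train([(["AA", "AA"], 0)] * 4, m, cfg)

    def test_empty_dataset_rejected(self, rng):
        with pytest.raises(ValueError):
            train([], small_model(rng), TrainConfig())


def test_checkpoint_roundtrip_bit_exact(rng, tmp_path):
    m = small_model(rng, hidden=3, dim=4, mode="V", seed=5)
    path = tmp_path / "model.npz"
    m.save(path)
    back = GruModel.load(path)
    assert back.vocab == m.vocab
    assert back.hidden == m.hidden and back.dim == m.dim
    assert back.embedding_trainable == m.embedding_trainable
    for k in m.params:
        np.testing.assert_array_equal(back.params[k], m.params[k])
    s = ["AA", "GT", "CC"]
    assert predict_sentence(s, back) == predict_sentence(s, m)
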