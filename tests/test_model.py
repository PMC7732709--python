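"""Encoder forward pass, task heads, objectives, and their gradients."""
import numpy as np
import pytest

from clinsts.autodiff import tensor
from clinsts.model import (PackedBatch, class_probabilities,
                           cross_entropy_loss, encode, mse_loss,
                           pair_similarity_score, task_loss,
                           token_class_probabilities)
from clinsts.tokenizer import PackedInput, pack_pair, pack_single


def _batch(vocab, *texts, pair=False):
    packed = [pack_pair(t, t[::-1], vocab, 32) if pair
              else pack_single(t, vocab, 32) for t in texts]
    return PackedBatch.from_packed(packed, vocab)


class TestEncode:
    def test_deterministic(self, tiny_state, tiny_vocab):
        batch = _batch(tiny_vocab, "alpha beta gamma")
        one = encode(batch, tiny_state).h_tokens.data
        two = encode(batch, tiny_state).h_tokens.data
        np.testing.assert_array_equal(one, two)

    def test_position_sensitive(self, tiny_state, tiny_vocab):
        a = _batch(tiny_vocab, "alpha beta")
        b = _batch(tiny_vocab, "beta alpha")
        ea = encode(a, tiny_state).h_cls.data
        eb = encode(b, tiny_state).h_cls.data
        assert np.abs(ea - eb).max() > 1e-9

    def test_h_cls_is_first_position(self, tiny_state, tiny_vocab):
        batch = _batch(tiny_vocab, "alpha beta gamma")
        enc = encode(batch, tiny_state)
        np.testing.assert_array_equal(enc.h_cls.data, enc.h_tokens.data[:, 0, :])

    def test_out_of_range_id_rejected(self, tiny_state, tiny_vocab):
        packed = PackedInput([tiny_vocab.cls_id, 10 ** 6, tiny_vocab.sep_id],
                             [0, 0, 0])
        batch = PackedBatch.from_packed([packed], tiny_vocab)
        with pytest.raises(ValueError, match="out of range"):
            encode(batch, tiny_state)


class TestHeads:
    def test_zero_head_scores_zero(self):
        h = tensor([[1.0, 2.0], [3.0, -1.0]])
        w = tensor(np.zeros((2, 1)))
        assert np.allclose(pair_similarity_score(h, w).data, 0.0)

    def test_dot_product_example(self):
        h = tensor([[1.0, 2.0]])
        w = tensor([[0.5], [0.25]])
        assert pair_similarity_score(h, w).data == pytest.approx(1.0)

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(0)
        h = tensor(rng.normal(size=(3, 4)))
        w = tensor(rng.normal(size=(4, 1)))
        one = pair_similarity_score(h, w).data
        two = pair_similarity_score(h, tensor(2 * w.data)).data
        np.testing.assert_allclose(two, 2 * one)

    def test_width_mismatch_raises(self):
        with pytest.raises(ValueError, match="width"):
            pair_similarity_score(tensor([[1.0, 2.0]]), tensor(np.ones((3, 1))))


class TestObjectives:
    def test_mse(self):
        assert mse_loss(tensor([3.0]), np.array([3.0])).item() == 0.0
        assert mse_loss(tensor([3.0]), np.array([1.0])).item() == pytest.approx(4.0)
        batch = mse_loss(tensor([0.0, 2.0]), np.array([1.0, 0.0]))
        assert batch.item() == pytest.approx(2.5)

    def test_softmax_probabilities(self):
        K = 4
        probs = class_probabilities(tensor([[0.0] * K]), tensor(np.eye(K)))
        np.testing.assert_allclose(probs.data, 1 / K)
        # logits [ln 2, 0] -> [2/3, 1/3]
        h = tensor([[np.log(2.0), 0.0]])
        probs = class_probabilities(h, tensor(np.eye(2)))
        np.testing.assert_allclose(probs.data, [[2 / 3, 1 / 3]])
        shifted = class_probabilities(tensor(h.data + 10.0), tensor(np.eye(2)))
        np.testing.assert_allclose(shifted.data, probs.data)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        h = tensor(rng.normal(size=(5, 6)))
        w = tensor(rng.normal(size=(6, 3)))
        p = class_probabilities(h, w).data
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-6)

    def test_cross_entropy(self):
        assert cross_entropy_loss(np.array([[0.0, 1.0]]), 1) == pytest.approx(0.0)
        K = 5
        assert cross_entropy_loss(np.full((1, K), 1 / K), 0) == pytest.approx(np.log(K))
        assert cross_entropy_loss(np.array([[2 / 3, 1 / 3]]), 1) == pytest.approx(np.log(3))

    def test_cross_entropy_floor(self):
        value = cross_entropy_loss(np.array([[1.0, 0.0]]), 1)
        assert np.isfinite(value)

    def test_token_probabilities_match_per_position(self, tiny_state, tiny_vocab):
        batch = _batch(tiny_vocab, "alpha beta gamma")
        enc = encode(batch, tiny_state)
        w = tensor(np.random.default_rng(2).normal(size=(8, 3)))
        full = token_class_probabilities(enc, w).data
        for pos in range(enc.h_tokens.shape[1]):
            single = class_probabilities(
                tensor(enc.h_tokens.data[:, pos, :]), w).data
            np.testing.assert_allclose(full[:, pos, :], single, atol=1e-12)


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_state, tiny_vocab, tmp_path):
        from clinsts.model import ModelState

        path = tmp_path / "model.zip"
        tiny_state.save(path, tiny_vocab)
        loaded, vocab = ModelState.load(path)
        assert vocab.units == tiny_vocab.units
        assert set(loaded.tasks) == set(tiny_state.tasks)
        for name, p in tiny_state.params.items():
            np.testing.assert_array_equal(loaded.params[name].data, p.data)
        batch = _batch(tiny_vocab, "alpha beta")
        np.testing.assert_array_equal(encode(batch, tiny_state).h_cls.data,
                                      encode(batch, loaded).h_cls.data)


class TestGradients:
    """Analytic gradients vs central finite differences on width-8 toys."""

    @pytest.mark.parametrize("task_name,make_targets", [
        ("sts", lambda B, T: np.linspace(0, 5, B)),
        ("topic", lambda B, T: np.arange(B) % 3),
        ("nli", lambda B, T: (np.arange(B) + 1) % 3),
        ("ner", lambda B, T: (np.arange(B * T).reshape(B, T)) % 2),
    ])
    def test_objective_gradients(self, tiny_state, tiny_vocab, task_name,
                                 make_targets):
        texts = ["alpha beta gamma", "delta epsilon"]
        pair = tiny_state.tasks[task_name].head_type in (
            "pair_similarity", "pair_classification")
        batch = _batch(tiny_vocab, *texts, pair=pair)
        B, T = batch.token_ids.shape
        targets = make_targets(B, T)
        task = tiny_state.tasks[task_name]

        tiny_state.zero_grad()
        loss = task_loss(tiny_state, task, batch, targets)
        loss.backward()
        rng = np.random.default_rng(7)
        worst = 0.0
        for name in tiny_state.trainable_for(task_name):
            p = tiny_state.params[name]
            grad = np.zeros_like(p.data) if p.grad is None else np.asarray(p.grad)
            flat = p.data.reshape(-1)
            gflat = grad.reshape(-1)
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                eps = 1e-5
                flat[i] = orig + eps
                up = task_loss(tiny_state, task, batch, targets).item()
                flat[i] = orig - eps
                down = task_loss(tiny_state, task, batch, targets).item()
                flat[i] = orig
                numeric = (up - down) / (2 * eps)
                denom = max(abs(numeric), 1e-3)
                worst = max(worst, abs(numeric - gflat[i]) / denom)
        assert worst < 1e-4
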