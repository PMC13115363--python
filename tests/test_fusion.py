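"""Decision-level fusion: fixed weights, self-learning module, dropout."""

import numpy as np
import pytest

from msdafuse import harness, nn
from msdafuse.fusion import (DecisionPair, FusionConfig, MLPExpand,
                             SelfLearningFusion, concat_decisions, fuse_fixed,
                             grid_search_fixed_weight, modality_dropout)
from msdafuse.nn import Tensor
from msdafuse.synthetic import generate_decisions


@pytest.fixture()
def pair(rng):
    p_eeg = rng.dirichlet([1, 1], size=50)
    p_face = rng.dirichlet([1, 1], size=50)
    labels = rng.integers(0, 2, 50)
    return DecisionPair(p_eeg=p_eeg, p_face=p_face, labels=labels)


class TestDecisionPair:
    def test_negative_probabilities_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            DecisionPair(np.array([[1.2, -0.2]]), np.array([[0.5, 0.5]]))

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            DecisionPair(np.array([[0.5, 0.4]]), np.array([[0.5, 0.5]]))


class TestFixedFusion:
    def test_endpoints_reproduce_single_modalities(self, pair):
        np.testing.assert_array_equal(fuse_fixed(pair, 1.0), pair.p_eeg)
        np.testing.assert_array_equal(fuse_fixed(pair, 0.0), pair.p_face)

    def test_midpoint_arithmetic(self):
        pair = DecisionPair(np.array([[0.8, 0.2]]), np.array([[0.4, 0.6]]))
        np.testing.assert_allclose(fuse_fixed(pair, 0.5), [[0.6, 0.4]])

    def test_rows_stay_on_simplex_and_monotone_in_k(self, pair):
        prev = fuse_fixed(pair, 0.0)
        direction = pair.p_eeg - pair.p_face
        for k in np.linspace(0.1, 1.0, 10):
            cur = fuse_fixed(pair, float(k))
            np.testing.assert_allclose(cur.sum(axis=1), 1.0, atol=1e-9)
            np.testing.assert_allclose(cur - prev, 0.1 * direction, atol=1e-9)
            prev = cur

    @pytest.mark.parametrize("k", [-0.1, 1.1])
    def test_out_of_range_weight_rejected(self, pair, k):
        with pytest.raises(ValueError, match="outside"):
            fuse_fixed(pair, k)

    def test_grid_search_recovers_informative_modality(self):
        pair, labels, _ = generate_decisions(400, complementarity=0.0, seed=0)
        # EEG is uniform noise: the best fixed weight leans to the face
        assert grid_search_fixed_weight(pair) <= 0.5


class TestConcat:
    def test_shape_rowsums_roundtrip(self, pair):
        cat = concat_decisions(pair)
        assert cat.shape == (50, 4)
        np.testing.assert_allclose(cat.sum(axis=1), 2.0, atol=1e-9)
        np.testing.assert_array_equal(cat[:, :2], pair.p_eeg)
        np.testing.assert_array_equal(cat[:, 2:], pair.p_face)


class TestMLPExpand:
    def test_output_width_is_seq_len_times_embed(self, rng):
        cfg = FusionConfig()
        mlp = MLPExpand(4, cfg, rng)
        out = mlp(Tensor(rng.random((7, 4))))
        assert out.shape == (7, cfg.seq_len * cfg.embed)

    def test_zero_input_equals_stacked_gelu_of_biases(self, rng):
        cfg = FusionConfig()
        mlp = MLPExpand(4, cfg, rng)
        h = np.zeros((1, 4))
        for block in mlp.blocks.layers:
            lin = block.layers[0]
            h = h @ lin.weight.data + lin.bias.data
            # tanh-approximation GELU, same as the forward pass
            c = np.sqrt(2 / np.pi)
            h = 0.5 * h * (1 + np.tanh(c * (h + 0.044715 * h ** 3)))
        np.testing.assert_allclose(mlp(Tensor(np.zeros((1, 4)))).data, h,
                                   atol=1e-12)

    def test_rows_processed_independently(self, rng):
        mlp = MLPExpand(4, FusionConfig(), rng)
        x = rng.random((5, 4))
        together = mlp(Tensor(x)).data
        separate = np.vstack([mlp(Tensor(x[i:i + 1])).data for i in range(5)])
        np.testing.assert_allclose(together, separate, atol=1e-12)

    def test_mismatched_widths_rejected(self):
        with pytest.raises(ValueError, match="seq_len"):
            FusionConfig(hidden_widths=(16, 32, 64, 60))
        with pytest.raises(ValueError, match="non-decreasing"):
            FusionConfig(hidden_widths=(32, 16, 64, 64))


class TestAttentionCore:
    def test_single_token_attention_is_identity_weight(self, rng):
        mha = nn.MultiHeadSelfAttention(4, 2, rng)
        x = rng.standard_normal((3, 1, 4))
        out = mha(Tensor(x))
        np.testing.assert_allclose(mha.last_attention, 1.0, atol=1e-12)
        # with a [[1]] attention matrix the map reduces to out_proj(v_proj(x))
        expected = mha.out_proj(mha.v_proj(Tensor(x))).data
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_rows_sum_to_one_per_head(self, rng):
        mha = nn.MultiHeadSelfAttention(8, 4, rng)
        mha(Tensor(rng.standard_normal((2, 8, 8))))
        np.testing.assert_allclose(mha.last_attention.sum(axis=-1), 1.0,
                                   atol=1e-6)


class TestSelfLearningFusion:
    def test_rows_on_simplex(self, pair):
        model = SelfLearningFusion(rng=np.random.default_rng(0))
        probs = model.predict_proba(pair)
        assert probs.shape == (50, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (probs >= 0).all()

    def test_sample_permutation_equivariance(self, pair):
        model = SelfLearningFusion(rng=np.random.default_rng(1))
        perm = np.random.default_rng(2).permutation(pair.n)
        probs = model.predict_proba(pair)
        permuted = model.predict_proba(
            DecisionPair(pair.p_eeg[perm], pair.p_face[perm]))
        np.testing.assert_allclose(permuted, probs[perm], atol=1e-12)


class TestFeatureLevelFusion:
    def test_head_trains_on_concatenated_branch_features(self, rng):
        from msdafuse.fusion import FeatureLevelFusionHead
        # toy penultimate features: class signal split across the two blocks
        y = np.repeat([0, 1], 60)
        feat_eeg = rng.normal(0, 0.3, (120, 6)) + y[:, None]
        feat_face = rng.normal(0, 0.3, (120, 4)) - y[:, None]
        X = np.concatenate([feat_eeg, feat_face], axis=1)
        head = FeatureLevelFusionHead(6, 4, rng=np.random.default_rng(0))
        probs = head(Tensor(X)).data
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        harness.train(head, X, y, lr=1e-2, batch_size=32, epochs=10, seed=0)
        head.eval()
        acc = harness.accuracy(head(Tensor(X)).data.argmax(axis=1), y)
        assert acc > 0.95


class TestModalityDropout:
    def test_p_zero_is_identity(self, pair, rng):
        out = modality_dropout(pair, 0.0, rng)
        np.testing.assert_array_equal(out.p_eeg, pair.p_eeg)
        np.testing.assert_array_equal(out.p_face, pair.p_face)

    def test_p_one_rejected(self, pair, rng):
        with pytest.raises(ValueError, match=r"\[0,1\)"):
            modality_dropout(pair, 1.0, rng)

    def test_empirical_rate_and_never_both(self):
        n = 10_000
        rng_data = np.random.default_rng(3)
        pair = DecisionPair(rng_data.dirichlet([1, 1], n),
                            rng_data.dirichlet([1, 1], n))
        out = modality_dropout(pair, 0.1, np.random.default_rng(4))
        dropped_e = np.all(out.p_eeg == 0.5, axis=1)
        dropped_f = np.all(out.p_face == 0.5, axis=1)
        assert abs(dropped_e.mean() - 0.1) <= 0.01
        assert abs(dropped_f.mean() - 0.1) <= 0.01
        assert not np.any(dropped_e & dropped_f)


@pytest.fixture(scope="module")
def trained_fusion():
    pair, labels, _ = generate_decisions(1200, 0.5, seed=20)
    model = SelfLearningFusion(rng=np.random.default_rng(21))
    harness.train_fusion(model, pair, epochs=20, dropout_p=0.1, seed=20)
    test_pair, test_labels, _ = generate_decisions(800, 0.5, seed=21)
    return model, test_pair, test_labels


class TestTrainedFusion:
    def test_beats_both_single_modalities(self, trained_fusion):
        model, test_pair, labels = trained_fusion
        acc_self = harness.accuracy(
            model.predict_proba(test_pair).argmax(axis=1), labels)
        acc_eeg = harness.accuracy(test_pair.p_eeg.argmax(axis=1), labels)
        acc_face = harness.accuracy(test_pair.p_face.argmax(axis=1), labels)
        assert acc_self > max(acc_eeg, acc_face)

    def test_degrades_gracefully_with_one_modality_uniform(self, trained_fusion):
        model, test_pair, labels = trained_fusion
        uniform = np.full_like(test_pair.p_eeg, 0.5)
        crippled = DecisionPair(uniform, test_pair.p_face)
        probs = model.predict_proba(crippled)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        acc = harness.accuracy(probs.argmax(axis=1), labels)
        assert acc > 0.55  # clearly above the chance-only baseline
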