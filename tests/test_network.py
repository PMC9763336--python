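import numpy as np
import pytest

import acpkit as a
from acpkit.network import AttentionParams, SelfAttentionParams

RNG = np.random.default_rng(77)


def tiny_config(**over):
    base = dict(
        scheme="mix", architecture="basic", n_units=4, dense_units=6,
        epochs=1, seed=3, attention_hidden=3,
    )
    base.update(over)
    return a.ModelConfig(**base)


def encoded(n=3, seed=0):
    ds = a.make_benchmark(a.GeneratorSpec(n_pos=n, n_neg=n, seed=seed))
    return a.encode_dataset(ds, "mix"), ds


class TestConfig:
    def test_field_validation(self):
        with pytest.raises(ValueError):
            tiny_config(epochs=0)
        with pytest.raises(ValueError):
            tiny_config(architecture="transformer")
        with pytest.raises(ValueError):
            tiny_config(learning_rate=0)

    def test_embedding_input_scheme(self):
        cfg = tiny_config(scheme="embedding")
        assert cfg.input_scheme == "bpf"
        assert cfg.lstm_input_dim == 36


class TestBuild:
    def test_seeded_builds_identical(self):
        m1 = a.build_model(tiny_config())
        m2 = a.build_model(tiny_config())
        for k in m1.params:
            assert np.array_equal(m1.params[k].data, m2.params[k].data)

    def test_basic_has_no_attention_stack(self):
        m = a.build_model(tiny_config())
        assert not any(k.startswith(("sa_", "att_")) for k in m.params)
        assert m.params["d2_W"].shape == (6, 2)

    def test_selfatt_attention_param_shapes(self):
        n = 4
        m = a.build_model(tiny_config(architecture="selfatt", n_units=n))
        ap = m.attention_params
        assert ap.W.shape == (2 * n,)
        assert ap.b.shape == (50,)


class TestAttentionPool:
    def test_uniform_weights_give_column_means(self):
        h = RNG.normal(size=(5, 8))
        params = AttentionParams(W=np.zeros(8), b=np.zeros(5))
        pooled, alpha = a.attention_pool(h, params)
        assert np.allclose(alpha, 1 / 5)
        assert np.allclose(pooled, h.mean(axis=0))

    def test_selection_limit(self):
        h = RNG.normal(size=(4, 6))
        b = np.array([0.0, 1e4, 0.0, 0.0])  # e_1 dominates
        pooled, alpha = a.attention_pool(h, AttentionParams(W=np.zeros(6), b=b))
        assert alpha[1] == pytest.approx(1.0)
        assert np.allclose(pooled, h[1])

    def test_matches_direct_summation_oracle(self):
        for trial in range(100):
            rng = np.random.default_rng(trial)
            L, width = rng.integers(2, 9), rng.integers(2, 7)
            h = rng.normal(size=(L, width))
            W, b = rng.normal(size=width), rng.normal(size=L)
            pooled, alpha = a.attention_pool(h, AttentionParams(W, b))
            e = np.array([h[j] @ W + b[j] for j in range(L)])
            weights = np.exp(e) / np.exp(e).sum()
            oracle = sum(weights[j] * h[j] for j in range(L))
            assert np.allclose(pooled, oracle, atol=1e-9)
            assert alpha.sum() == pytest.approx(1.0, abs=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="attention params"):
            a.attention_pool(np.zeros((5, 8)), AttentionParams(np.zeros(7), np.zeros(5)))


class TestSelfAttention:
    @staticmethod
    def params(width, k, rng):
        return SelfAttentionParams(
            W_t=rng.normal(size=(width, k)),
            W_x=rng.normal(size=(width, k)),
            b_t=rng.normal(size=k),
            W_a=rng.normal(size=k),
            b_a=float(rng.normal()),
        )

    def test_identical_positions_uniform(self):
        c = RNG.normal(size=6)
        x = np.tile(c, (4, 1))
        out, A = a.self_attention(x, self.params(6, 3, np.random.default_rng(1)))
        assert np.allclose(A, 1 / 4)
        assert np.allclose(out, x)

    def test_length_two_hand_expansion(self):
        """Four-term enumeration over (t, t') for a length-2 sequence."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=(2, 4))
        p = self.params(4, 3, rng)
        sigmoid = lambda v: 1 / (1 + np.exp(-v))
        e = np.empty((2, 2))
        for t in range(2):
            for tp in range(2):
                h = np.tanh(x[t] @ p.W_t + x[tp] @ p.W_x + p.b_t)
                e[t, tp] = sigmoid(h @ p.W_a + p.b_a)
        expected = np.empty_like(x)
        for t in range(2):
            w = np.exp(e[t]) / np.exp(e[t]).sum()
            expected[t] = w[0] * x[0] + w[1] * x[1]
        out, A = a.self_attention(x, p)
        assert np.allclose(out, expected, atol=1e-12)
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-6)

    def test_rows_sum_to_one_random(self):
        x = RNG.normal(size=(7, 6))
        _, A = a.self_attention(x, self.params(6, 4, RNG))
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="self-attention"):
            a.self_attention(np.zeros((3, 5)), self.params(6, 2, RNG))


class TestForward:
    @pytest.mark.parametrize("architecture", ["basic", "selfatt"])
    def test_probability_rows(self, architecture):
        X, _ = encoded(4)
        m = a.build_model(tiny_config(architecture=architecture))
        probs = m.forward(X)
        assert probs.shape == (8, 2)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_peptide_identical_rows(self):
        X, _ = encoded(2)
        batch = np.concatenate([X, X[:1]])
        probs = a.build_model(tiny_config()).forward(batch)
        assert np.array_equal(probs[0], probs[-1])

    def test_batching_invariance(self):
        X, _ = encoded(5)
        m = a.build_model(tiny_config())
        alone = m.forward(X[2:3])
        together = m.forward(X)[2:3]
        assert np.allclose(alone, together, atol=1e-6)

    def test_scheme_mismatch_rejected(self):
        m = a.build_model(tiny_config(scheme="mix"))
        ds = a.make_benchmark(a.GeneratorSpec(n_pos=2, n_neg=2, seed=1))
        bad = [a.encode_sequence(p, "bpf") for p in ds]
        with pytest.raises(ValueError, match="scheme mismatch"):
            m.forward(bad)

    def test_penultimate_width_and_determinism(self):
        X, _ = encoded(3)
        m = a.build_model(tiny_config(dense_units=6))
        f1 = m.penultimate_features(X)
        f2 = m.penultimate_features(X)
        assert f1.shape == (6, 6)
        assert np.array_equal(f1, f2)

    def test_embedding_model_runs(self):
        ds = a.make_benchmark(a.GeneratorSpec(n_pos=3, n_neg=3, seed=2))
        X = a.encode_dataset(ds, "bpf")
        m = a.build_model(tiny_config(scheme="embedding"))
        assert m.forward(X).shape == (6, 2)

    def test_mask_padding_switch_runs(self):
        ds = a.make_benchmark(a.GeneratorSpec(n_pos=3, n_neg=3, seed=2))
        cfg = tiny_config(mask_padding=True, epochs=1)
        model = a.train(cfg, ds)
        assert model.forward(a.encode_dataset(ds, "mix")).shape == (6, 2)


class TestSerialization:
    def test_round_trip_bit_identical(self, tmp_path):
        X, ds = encoded(3)
        cfg = tiny_config(epochs=2)
        model = a.train(cfg, ds)
        path = tmp_path / "model.npz"
        model.save(path)
        reloaded = a.TrainedModel.load(path)
        assert np.array_equal(model.forward(X), reloaded.forward(X))
        assert reloaded.config == model.config
        assert reloaded.channel_names == model.channel_names
        assert reloaded.training_log == model.training_log
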