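"""Multimodal network: branch contracts, attention normalisation, splits
and a small end-to-end training run."""

import numpy as np
import pytest

from acidmap.nn import Tensor
from acidmap.phnet import (
    MultimodalPHRegressor,
    PHNet,
    PHNetConfig,
    SpectrumDataset,
    _split_by_specimen,
    load_results,
)
from acidmap.simulate import generate_dataset

SMALL = PHNetConfig(
    image_side=32,
    seq_len=64,
    d_1d=16,
    d_attn=16,
    conv_widths=(4, 8, 8, 8),
    head_hidden=16,
    epochs=4,
    batch_size=16,
    seed=7,
)


@pytest.fixture(scope="module")
def small_dataset():
    spectra = generate_dataset(120, "uniform", seed=3)
    ids = [f"spec{i // 12}" for i in range(120)]  # 10 specimens
    return SpectrumDataset.from_spectra(spectra, ids, SMALL)


@pytest.fixture(scope="module")
def fitted(small_dataset):
    return PHNet(small_dataset, SMALL).fit()


class TestBranches:
    def test_features_1d_deterministic_and_length_checked(self):
        rng = np.random.default_rng(0)
        net = MultimodalPHRegressor(SMALL, rng)
        x = Tensor(rng.normal(0, 1, (2, SMALL.seq_len)))
        a = net.features_1d(x).data
        b = net.features_1d(x).data
        assert np.array_equal(a, b)
        with pytest.raises(ValueError, match="length"):
            net.features_1d(Tensor(np.zeros((2, 10))))

    def test_features_1d_zero_input_zero_preactivation(self):
        rng = np.random.default_rng(1)
        net = MultimodalPHRegressor(SMALL, rng)
        out = net.fc1(Tensor(np.zeros((1, SMALL.seq_len))))
        np.testing.assert_allclose(out.data, 0.0, atol=0)  # biases init to 0

    def test_features_2d_shape_and_finiteness(self):
        rng = np.random.default_rng(2)
        net = MultimodalPHRegressor(SMALL, rng)
        tokens = net.features_2d(Tensor(np.zeros((1, 3, 32, 32))))
        assert tokens.data.shape == (1, 4, SMALL.conv_widths[-1])  # 2x2 grid
        assert np.all(np.isfinite(tokens.data))
        with pytest.raises(ValueError, match=r"\(N, 3, L, L\)"):
            net.features_2d(Tensor(np.zeros((1, 2, 32, 32))))

    def test_channel_permutation_changes_output(self):
        rng = np.random.default_rng(3)
        net = MultimodalPHRegressor(SMALL, rng)
        img = rng.normal(0, 1, (1, 3, 32, 32)).astype(np.float32)
        base = net.features_2d(Tensor(img)).data
        permuted = net.features_2d(Tensor(img[:, [1, 2, 0]])).data
        assert not np.allclose(base, permuted)


class TestCoAttention:
    def _net(self, heads=2):
        cfg = PHNetConfig(
            image_side=32, seq_len=64, d_1d=16, d_attn=16, n_heads=heads,
            conv_widths=(4, 8, 8, 8), seed=0,
        )
        return MultimodalPHRegressor(cfg, np.random.default_rng(4)), cfg

    def test_weights_sum_to_one_per_head(self):
        net, cfg = self._net()
        rng = np.random.default_rng(5)
        q = Tensor(rng.normal(0, 1, (3, cfg.d_1d)))
        tokens = Tensor(rng.normal(0, 1, (3, 9, cfg.conv_widths[-1])))
        fused, weights = net.co_attention(q, tokens)
        assert weights.shape == (3, cfg.n_heads, 9)
        assert np.all(weights >= 0)
        np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-6)
        assert fused.data.shape == (3, cfg.d_attn + cfg.d_1d)

    def test_single_token_receives_full_weight(self):
        net, cfg = self._net(heads=1)
        rng = np.random.default_rng(6)
        q = Tensor(rng.normal(0, 1, (2, cfg.d_1d)))
        tokens = Tensor(rng.normal(0, 1, (2, 1, cfg.conv_widths[-1])))
        _, weights = net.co_attention(q, tokens)
        np.testing.assert_allclose(weights, 1.0, atol=0)

    def test_identical_tokens_uniform_weights(self):
        net, cfg = self._net(heads=1)
        rng = np.random.default_rng(7)
        one = rng.normal(0, 1, (1, 1, cfg.conv_widths[-1]))
        tokens = Tensor(np.repeat(one, 5, axis=1))
        q = Tensor(rng.normal(0, 1, (1, cfg.d_1d)))
        _, weights = net.co_attention(q, tokens)
        np.testing.assert_allclose(weights, 0.2, atol=1e-6)


class TestSplitting:
    def test_no_specimen_in_two_partitions(self, small_dataset):
        rng = np.random.default_rng(8)
        split = _split_by_specimen(
            small_dataset.specimen_ids, (0.6, 0.2, 0.2), rng
        )
        seen = {}
        for name, idx in split.items():
            for sid in np.unique(small_dataset.specimen_ids[idx]):
                assert sid not in seen, f"{sid} in {seen.get(sid)} and {name}"
                seen[sid] = name
        total = sum(len(idx) for idx in split.values())
        assert total == len(small_dataset)

    def test_single_specimen_rejected(self):
        with pytest.raises(ValueError, match=">= 2 specimens"):
            _split_by_specimen(
                np.array(["a", "a", "a"]), (0.6, 0.2, 0.2),
                np.random.default_rng(0),
            )


class TestTraining:
    def test_loss_decreases(self, fitted):
        hist = fitted.history
        assert hist["train_loss"].iloc[-1] <= hist["train_loss"].iloc[0]

    def test_identical_seed_identical_weights_digest(self, small_dataset):
        a = PHNet(small_dataset, SMALL).fit().weights_digest()
        b = PHNet(small_dataset, SMALL).fit().weights_digest()
        assert a == b

    def test_prediction_deterministic(self, fitted, small_dataset):
        p1 = fitted.predict_dataset()
        p2 = fitted.predict_dataset()
        np.testing.assert_allclose(p1, p2, atol=1e-6)
        assert np.std(p1) > 0  # non-degenerate predictions

    def test_untrained_model_refuses_to_predict(self, small_dataset):
        model = PHNet(small_dataset, SMALL)
        with pytest.raises(RuntimeError, match="not trained"):
            model.predict_ph(None)

    def test_save_load_roundtrip(self, fitted, small_dataset, tmp_path):
        fitted.save(tmp_path / "model")
        back = load_results(tmp_path / "model")
        orig = fitted.predict_arrays(
            small_dataset.sequences[:5], small_dataset.images[:5]
        )
        loaded = back.predict_arrays(
            small_dataset.sequences[:5], small_dataset.images[:5]
        )
        np.testing.assert_allclose(orig, loaded, atol=1e-6)
        assert back.weights_digest() == fitted.weights_digest()

    def test_full_predict_pipeline_runs(self, fitted):
        from acidmap.simulate import SpectrumModelParams, generate_spectrum

        spec = generate_spectrum(6.5, SpectrumModelParams(noise_sd=0.0))
        ph = fitted.predict_ph(spec)
        assert np.isfinite(ph)
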