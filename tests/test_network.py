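"""Architecture arithmetic and the NumPy implementation of the 3D CNN."""

import numpy as np
import pytest

from ern.network import ERN, ERNConfig, _Conv3D, _TemporalMaxPool, \
    build_ern, conv_output_size, pooled_size


class TestShapeArithmetic:
    @pytest.mark.parametrize(
        "I,K,P,S,expected",
        [(9, 3, 1, 1, 9), (128, 4, 1, 1, 127), (128, 5, 1, 1, 126),
         (128, 2, 0, 2, 64)],
    )
    def test_conv_output_size(self, I, K, P, S, expected):
        assert conv_output_size(I, K, P, S) == expected

    def test_matches_enumeration(self):
        """The closed form equals counting valid kernel placements."""
        for I in (5, 9, 16, 33):
            for K in (1, 2, 3, 5):
                for P in (0, 1, 2):
                    for S in (1, 2, 3):
                        span = I - K + 2 * P
                        count = len(range(0, span + 1, S))
                        if span < 0 or span % S:
                            with pytest.raises(ValueError):
                                conv_output_size(I, K, P, S)
                        else:
                            assert conv_output_size(I, K, P, S) == count

    @pytest.mark.parametrize("T,expected", [(127, 63), (126, 63), (2, 1),
                                            (128, 64)])
    def test_pooled_size(self, T, expected):
        assert pooled_size(T, 2, 2) == expected

    def test_pooled_size_matches_enumeration(self):
        for T in range(2, 40):
            for pool in (2, 3):
                for stride in (1, 2, 3):
                    if T < pool:
                        continue
                    count = len(range(0, T - pool + 1, stride))
                    assert pooled_size(T, pool, stride) == count

    def test_pool_longer_than_input_rejected(self):
        with pytest.raises(ValueError):
            pooled_size(1, 2, 2)

    def test_branch_temporal_lengths_agree_after_pooling(self):
        """floor(127/2) == floor(126/2) == 63: the 3x3x4 and 3x3x5 branches
        concatenate without cropping for 128-sample inputs."""
        a = pooled_size(conv_output_size(128, 4, 1, 1), 2, 2)
        b = pooled_size(conv_output_size(128, 5, 1, 1), 2, 2)
        assert a == b == 63


class TestConfig:
    def test_defaults_match_published_architecture(self):
        cfg = ERNConfig()
        assert cfg.branch_a_kernel == (3, 3, 4)
        assert cfg.branch_b_kernel == (3, 3, 5)
        assert cfg.pool_kernel == (1, 1, 2)
        assert cfg.head_maps == 64 and cfg.dropout_p == 0.6

    def test_same_scale_variant_uses_branch_a_kernel(self):
        cfg = ERNConfig(variant="same_scale")
        assert cfg.effective_branch_b_kernel == (3, 3, 4)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ERNConfig(dropout_p=1.0)
        with pytest.raises(ValueError):
            ERNConfig(n_classes=1)
        with pytest.raises(ValueError):
            ERNConfig(variant="huge")


SMALL = ERNConfig(branch_maps=2, head_maps=4, dropout_p=0.0)


class TestLayers:
    def test_conv_matches_brute_force(self, rng):
        conv = _Conv3D(3, 5, (3, 3, 4), 1, rng)
        x = rng.standard_normal((2, 9, 9, 12, 3)).astype(np.float32)
        out = conv.forward(x).copy()
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
        ref = np.zeros_like(out)
        for i in range(3):
            for j in range(3):
                for k in range(4):
                    for c in range(3):
                        ref += (xp[:, i:i + 9, j:j + 9, k:k + 11, c][..., None]
                                * conv.W[i, j, k, c, :])
        ref += conv.b
        np.testing.assert_allclose(out, ref, atol=1e-4)

    def test_pool_forward_and_backward(self, rng):
        pool = _TemporalMaxPool(2)
        x = rng.standard_normal((2, 3, 3, 7, 2)).astype(np.float32)
        out = pool.forward(x).copy()
        ref = np.maximum(x[:, :, :, 0:6:2, :], x[:, :, :, 1:6:2, :])
        np.testing.assert_array_equal(out, ref)
        dout = rng.standard_normal(out.shape).astype(np.float32)
        dx = pool.backward(dout)
        # gradient routes to the argmax sample only; trailing sample unused
        np.testing.assert_allclose(dx.sum(), dout.sum(), rtol=1e-5)
        assert not dx[:, :, :, 6, :].any()


class TestNetwork:
    def test_probabilities_normalised(self, rng):
        net = build_ern(SMALL, input_shape=(9, 9, 32), seed=0)
        for _ in range(20):
            p = net.predict_proba(
                rng.standard_normal((5, 9, 9, 32)).astype(np.float32)
            )
            assert p.shape == (5, 4)
            assert (p >= 0).all()
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_full_size_forward_shape(self):
        net = build_ern(ERNConfig(), input_shape=(9, 9, 128), seed=0)
        p = net.predict_proba(np.zeros((2, 9, 9, 128), dtype=np.float32))
        assert p.shape == (2, 4)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_same_scale_variant_same_interface(self):
        net = build_ern(ERNConfig(variant="same_scale", branch_maps=2,
                                  head_maps=4), input_shape=(9, 9, 32), seed=0)
        assert net.predict_proba(np.zeros((3, 9, 9, 32), np.float32)).shape == (3, 4)

    def test_eval_forward_deterministic(self, rng):
        net = build_ern(SMALL, input_shape=(9, 9, 32), seed=1)
        x = rng.standard_normal((4, 9, 9, 32)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x), net.forward(x))

    def test_input_too_short_rejected(self):
        with pytest.raises(ValueError):
            build_ern(ERNConfig(), input_shape=(9, 9, 3), seed=0)

    def test_parameter_count_properties(self):
        base = build_ern(ERNConfig(), input_shape=(9, 9, 128)).parameter_count()
        assert base > 0
        wide = build_ern(ERNConfig(branch_maps=64),
                         input_shape=(9, 9, 128)).parameter_count()
        assert wide > base

    def test_variants_differ_by_branch_kernel_parameters(self):
        """Multiscale minus same-scale = branch_maps * in_ch * 3*3*(5-4)."""
        cfg = ERNConfig()
        multi = build_ern(cfg, input_shape=(9, 9, 128)).parameter_count()
        same = build_ern(ERNConfig(variant="same_scale"),
                         input_shape=(9, 9, 128)).parameter_count()
        assert multi - same == cfg.branch_maps * 1 * 3 * 3 * (5 - 4)

    def test_gradients_match_finite_differences(self, rng):
        """Analytic backprop against central differences (float32, so the
        comparison is on relative error of sampled coordinates)."""
        net = build_ern(SMALL, input_shape=(9, 9, 12), seed=3)
        x = rng.standard_normal((3, 9, 9, 12)).astype(np.float32)
        y = np.array([0, 2, 3])
        _, grads = net.loss_and_grads(x, y, train=False)

        def loss_at():
            logits = net.forward(x, train=False).astype(np.float64)
            z = logits - logits.max(1, keepdims=True)
            p = np.exp(z) / np.exp(z).sum(1, keepdims=True)
            return float(-np.log(p[np.arange(3), y]).mean())

        errs = []
        for param, grad in zip(net.params, grads):
            flat = param.ravel()
            for i in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[i]
                eps = 1e-2
                flat[i] = orig + eps
                lp = loss_at()
                flat[i] = orig - eps
                lm = loss_at()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                an = float(grad.ravel()[i])
                errs.append(abs(num - an) / max(1.0, abs(num), abs(an)))
        errs = np.array(errs)
        assert np.median(errs) < 0.01
        assert errs.max() < 0.25  # float32 finite-difference noise floor

    def test_dropout_requires_rng_and_scales_in_training(self, rng):
        net = build_ern(ERNConfig(branch_maps=2, head_maps=4, dropout_p=0.6),
                        input_shape=(9, 9, 16), seed=0)
        x = rng.standard_normal((2, 9, 9, 16)).astype(np.float32)
        with pytest.raises(ValueError, match="rng"):
            net.forward(x, train=True)
        r = np.random.default_rng(0)
        a = net.forward(x, train=True, rng=r)
        b = net.forward(x, train=True, rng=r)
        assert not np.array_equal(a, b)  # different dropout masks

    def test_checkpoint_round_trip(self, tmp_path, rng):
        net = build_ern(SMALL, input_shape=(9, 9, 16), seed=5)
        x = rng.standard_normal((3, 9, 9, 16)).astype(np.float32)
        before = net.predict_proba(x)
        path = net.save(tmp_path / "model.npz")
        back = ERN.load(path)
        assert back.cfg == net.cfg
        np.testing.assert_array_equal(back.predict_proba(x), before)
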