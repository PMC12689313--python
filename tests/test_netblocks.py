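"""Classifier blocks against brute-force oracles on toy tensors, plus
architecture parameter accounting."""

import numpy as np
import pytest

from snoreacoustics.nn import (AKConv, AKConvConfig, CBAM, CBAMConfig,
                               ConvMod, ConvModConfig, ModelSpec, Tensor,
                               akconv_init_coords, bilinear_sample,
                               build_model, conv2d, count_params, zoo)


class TestAutogradNumerics:
    """Spot-check backward passes against central differences."""

    @staticmethod
    def _numgrad(f, arr, eps=1e-6):
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            old = arr[i]
            arr[i] = old + eps
            fp = f()
            arr[i] = old - eps
            fm = f()
            arr[i] = old
            g[i] = (fp - fm) / (2 * eps)
        return g

    def test_grouped_strided_conv_gradients(self, rng):
        x = Tensor(rng.normal(size=(2, 4, 6, 6)), requires_grad=True)
        w = Tensor(rng.normal(size=(6, 2, 3, 3)), requires_grad=True)

        def run():
            return float((conv2d(Tensor(x.data), Tensor(w.data),
                                 stride=2, padding=1, groups=2).data ** 2).sum())

        out = conv2d(x, w, stride=2, padding=1, groups=2)
        (out * out).sum().backward()
        assert np.abs(x.grad - self._numgrad(run, x.data)).max() < 1e-5
        assert np.abs(w.grad - self._numgrad(run, w.data)).max() < 1e-5

    def test_bilinear_sample_gradients(self, rng):
        x = Tensor(rng.normal(size=(1, 2, 5, 5)), requires_grad=True)
        pos = Tensor(rng.uniform(0.1, 3.8, size=(1, 2, 3, 3, 2)),
                     requires_grad=True)

        def run():
            return float((bilinear_sample(Tensor(x.data),
                                          Tensor(pos.data)).data ** 2).sum())

        out = bilinear_sample(x, pos)
        (out * out).sum().backward()
        assert np.abs(x.grad - self._numgrad(run, x.data)).max() < 1e-6
        assert np.abs(pos.grad - self._numgrad(run, pos.data)).max() < 1e-6


class TestAKConvCoords:
    def test_perfect_square_grid(self):
        coords = akconv_init_coords(4)
        assert {tuple(c) for c in coords} == {(0, 0), (0, 1), (1, 0), (1, 1)}

    def test_single_point_is_origin(self):
        np.testing.assert_array_equal(akconv_init_coords(1), [[0, 0]])

    def test_three_points_base_grid_plus_remainder(self):
        # base = floor(sqrt(3)) = 1 -> one 1-wide column of 3 rows, no remainder
        coords = akconv_init_coords(3)
        np.testing.assert_array_equal(coords, [[0, 0], [1, 0], [2, 0]])

    @pytest.mark.parametrize("n", [2, 5, 6, 7, 9, 11])
    def test_counts_and_anchor(self, n):
        coords = akconv_init_coords(n)
        assert len(coords) == n
        assert (coords[0] == [0, 0]).all()
        assert len({tuple(c) for c in coords}) == n   # no duplicates

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            akconv_init_coords(0)


class TestAKConv:
    def test_zero_offsets_equal_fixed_grid_gather(self, rng):
        ak = AKConv(3, 4, AKConvConfig(num_param=3), rng=rng)
        x = rng.normal(size=(1, 3, 6, 6))
        out = ak(Tensor(x))
        # oracle: gather at integer init coords (zero padding), mix, norm, silu
        coords = akconv_init_coords(3).astype(int)
        gathered = np.zeros((1, 3, 3, 6, 6))
        for k, (dr, dc) in enumerate(coords):
            shifted = np.zeros((1, 3, 6, 6))
            shifted[:, :, :6 - dr if dr else 6, :6 - dc if dc else 6] = \
                x[:, :, dr:, dc:]
            gathered[:, :, k] = shifted
        mixed = np.einsum("bcnxy,ocn->boxy", gathered,
                          ak.mix.weight.data.reshape(4, 3, 3))
        mu = mixed.mean(axis=1, keepdims=True)
        var = ((mixed - mu) ** 2).mean(axis=1, keepdims=True)
        ref = (mixed - mu) / np.sqrt(var + 1e-6)
        ref = ref / (1 + np.exp(-ref))   # SiLU after unit-gain LayerNorm
        np.testing.assert_allclose(out.data, ref, atol=1e-10)

    def test_bilinear_midpoint(self):
        x = Tensor(np.array([[[[0.0, 1.0]]]]))          # 1x1x1x2
        pos = Tensor(np.array([0.0, 0.5]).reshape(1, 1, 1, 1, 2))
        out = bilinear_sample(x, pos)
        assert out.data.flatten()[0] == pytest.approx(0.5)

    def test_matches_bruteforce_loop(self, rng):
        """Full AKConv forward vs a per-pixel gather-and-weight loop."""
        ak = AKConv(4, 2, AKConvConfig(num_param=3), rng=rng)
        # give the offset predictor nonzero weights so offsets participate
        ak.offset_conv.weight.data = 0.1 * rng.normal(
            size=ak.offset_conv.weight.data.shape)
        x = rng.normal(size=(1, 4, 6, 6))
        out = ak(Tensor(x)).data

        off = conv2d(Tensor(x), ak.offset_conv.weight, ak.offset_conv.bias,
                     padding=1).data.reshape(1, 3, 2, 6, 6)
        coords = akconv_init_coords(3)
        sampled = np.zeros((1, 4, 3, 6, 6))
        for i in range(6):
            for j in range(6):
                for k in range(3):
                    r = i + coords[k, 0] + off[0, k, 0, i, j]
                    c = j + coords[k, 1] + off[0, k, 1, i, j]
                    r0, c0 = int(np.floor(r)), int(np.floor(c))
                    for ch in range(4):
                        v = 0.0
                        for (ri, ci, wgt) in ((r0, c0, (1 - (r - r0)) * (1 - (c - c0))),
                                              (r0, c0 + 1, (1 - (r - r0)) * (c - c0)),
                                              (r0 + 1, c0, (r - r0) * (1 - (c - c0))),
                                              (r0 + 1, c0 + 1, (r - r0) * (c - c0))):
                            if 0 <= ri < 6 and 0 <= ci < 6:
                                v += wgt * x[0, ch, ri, ci]
                        sampled[0, ch, k, i, j] = v
        mixed = np.einsum("bcnxy,ocn->boxy", sampled,
                          ak.mix.weight.data.reshape(2, 4, 3))
        mu = mixed.mean(axis=1, keepdims=True)
        var = ((mixed - mu) ** 2).mean(axis=1, keepdims=True)
        ref = (mixed - mu) / np.sqrt(var + 1e-6)
        ref = ref / (1 + np.exp(-ref))
        np.testing.assert_allclose(out, ref, rtol=1e-6, atol=1e-9)


def cbam_transcription(x, fc0, fc1, spatial_w):
    """Direct element-wise transcription of the channel+spatial attention
    equations."""
    sigmoid = lambda v: 1 / (1 + np.exp(-v))
    B, C, H, W = x.shape
    f_avg = x.mean(axis=(2, 3))
    f_max = x.max(axis=(2, 3))
    mlp = lambda v: np.maximum(v @ fc0.T, 0.0) @ fc1.T
    mc = sigmoid(mlp(f_avg) + mlp(f_max))
    f1 = x * mc[:, :, None, None]
    s = np.stack([f1.mean(axis=1), f1.max(axis=1)], axis=1)   # B,2,H,W
    k = spatial_w.shape[-1]
    pad = k // 2
    sp = np.pad(s, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ms = np.zeros((B, 1, H, W))
    for b in range(B):
        for i in range(H):
            for j in range(W):
                ms[b, 0, i, j] = np.sum(sp[b, :, i:i + k, j:j + k]
                                        * spatial_w[0])
    return f1 * sigmoid(ms)


class TestCBAM:
    def test_zero_weights_quarter_passthrough(self, rng):
        cb = CBAM(16, CBAMConfig(reduction=16), rng=rng)
        cb.fc0.weight.data[:] = 0
        cb.fc1.weight.data[:] = 0
        cb.spatial.weight.data[:] = 0
        x = rng.normal(size=(2, 16, 5, 5))
        out = cb(Tensor(x))
        np.testing.assert_allclose(out.data, 0.25 * x, rtol=1e-12)

    def test_single_channel_constant_input_pools_collapse(self, rng):
        cb = CBAM(1, CBAMConfig(reduction=1), rng=rng)
        x = np.full((1, 1, 8, 8), 3.0)
        out = cb(Tensor(x))
        # avg-pool == max-pool, so channel gate is sigma(2 * MLP(c))
        mlp = lambda v: np.maximum(v * cb.fc0.weight.data[0, 0], 0.0) \
            * cb.fc1.weight.data[0, 0]
        gate = 1 / (1 + np.exp(-2 * mlp(3.0)))
        f1 = 3.0 * gate
        ref = cbam_transcription(x, cb.fc0.weight.data, cb.fc1.weight.data,
                                 cb.spatial.weight.data)
        np.testing.assert_allclose(out.data, ref, rtol=1e-6)
        # at an interior pixel the 7x7 window sees no zero padding, so the
        # spatial gate reduces to sigma(sum(w) * f1) on the constant map
        assert out.data[0, 0, 3, 3] == pytest.approx(
            f1 * (1 / (1 + np.exp(-np.sum(cb.spatial.weight.data) * f1))),
            rel=1e-6)

    def test_random_input_matches_equation_transcription(self, rng):
        cb = CBAM(16, CBAMConfig(reduction=16), rng=rng)
        x = rng.normal(size=(1, 16, 5, 5))
        out = cb(Tensor(x))
        ref = cbam_transcription(x, cb.fc0.weight.data, cb.fc1.weight.data,
                                 cb.spatial.weight.data)
        np.testing.assert_allclose(out.data, ref, rtol=1e-6, atol=1e-12)

    def test_attention_bounds_and_contraction(self, rng):
        cb = CBAM(8, CBAMConfig(reduction=8), rng=rng)
        x = rng.normal(size=(2, 8, 6, 6))
        out = cb(Tensor(x)).data
        assert np.all(np.abs(out) <= np.abs(x) + 1e-12)
        nz = x != 0
        assert np.all(np.abs(out[nz]) < np.abs(x[nz]))   # weights in (0,1)

    def test_incompatible_reduction_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            CBAM(10, CBAMConfig(reduction=16), rng=rng)


class TestConvMod:
    def test_zero_value_branch_gives_residual_identity(self, rng):
        cm = ConvMod(ConvModConfig(dim=8, dw_kernel=3, dw_padding=1), rng=rng)
        cm.v.weight.data[:] = 0
        cm.v.bias.data[:] = 0
        x = rng.normal(size=(1, 8, 4, 4))
        out = cm(Tensor(x))
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_single_pixel_input_finite_and_shape_preserving(self, rng):
        cm = ConvMod(ConvModConfig(dim=4, dw_kernel=11, dw_padding=5), rng=rng)
        x = rng.normal(size=(1, 4, 1, 1))
        out = cm(Tensor(x))
        assert out.data.shape == (1, 4, 1, 1)
        assert np.isfinite(out.data).all()

    def test_matches_hand_composition(self, rng):
        cfg = ConvModConfig(dim=8, dw_kernel=3, dw_padding=1)
        cm = ConvMod(cfg, rng=rng)
        x = rng.normal(size=(1, 8, 7, 7))
        out = cm(Tensor(x)).data

        h = cm.norm(Tensor(x)).data
        a = conv2d(Tensor(h), cm.a_pw.weight, cm.a_pw.bias).data
        from scipy.special import erf
        a = a * 0.5 * (1 + erf(a / np.sqrt(2)))
        a = conv2d(Tensor(a), cm.a_dw.weight, cm.a_dw.bias,
                   padding=1, groups=8).data
        v = conv2d(Tensor(h), cm.v.weight, cm.v.bias).data
        ref = x + conv2d(Tensor(a * v), cm.proj.weight, cm.proj.bias).data
        np.testing.assert_allclose(out, ref, rtol=1e-6, atol=1e-12)

    def test_dim_mismatch_rejected(self, rng):
        cm = ConvMod(ConvModConfig(dim=8, dw_kernel=3, dw_padding=1), rng=rng)
        with pytest.raises(ValueError, match="dim"):
            cm(Tensor(np.zeros((1, 4, 4, 4))))


class TestModelAssembly:
    def test_toy_forward_shape(self, rng):
        model = build_model(ModelSpec.toy(seed=0))
        x = rng.normal(size=(2, 3, 32, 32))
        out = model(Tensor(x))
        assert out.data.shape == (2, 2)
        assert np.isfinite(out.data).all()

    def test_baseline_matches_inventory(self):
        model = build_model(ModelSpec.convnext_tiny())
        assert count_params(model) == zoo.count_inventory(
            zoo.convnext_tiny_inventory(2))

    def test_improved_has_more_params_than_baseline(self):
        base = count_params(build_model(ModelSpec.convnext_tiny()))
        imp = count_params(build_model(ModelSpec.improved_tiny()))
        assert imp > base

    def test_invalid_placements_rejected(self):
        from snoreacoustics.nn import BackboneSpec
        with pytest.raises(ValueError):
            build_model(ModelSpec(backbone=BackboneSpec(dims=(8, 16, 30, 64)),
                                  cbam=CBAMConfig(reduction=16)))
        with pytest.raises(ValueError):
            build_model(ModelSpec(backbone=BackboneSpec(dims=(8, 16, 32, 64)),
                                  convmod=ConvModConfig(dim=768)))

    def test_tiny_linear_param_count(self):
        from snoreacoustics.nn import Linear
        assert Linear(10, 2).num_params() == 22


class TestZooAccounting:
    """The printed parameter budgets of the comparison-model zoo."""

    @pytest.mark.parametrize("inventory,expected_millions", [
        (zoo.convnext_tiny_inventory, 27.82),
        (zoo.resnet50_inventory, 23.51),
        (zoo.swin_tiny_inventory, 27.52),
        (zoo.mobilenet_v3_large_inventory, 4.20),
    ])
    def test_two_class_head_counts(self, inventory, expected_millions):
        assert zoo.millions(zoo.count_inventory(inventory(2))) == expected_millions

    def test_exact_convnext_count(self):
        assert zoo.count_inventory(zoo.convnext_tiny_inventory(2)) == 27_821_666

    @pytest.mark.parametrize("inventory,imagenet_total", [
        (zoo.convnext_tiny_inventory, 28_589_128),
        (zoo.resnet50_inventory, 25_557_032),
        (zoo.swin_tiny_inventory, 28_288_354),
        (zoo.mobilenet_v3_large_inventory, 5_483_032),
    ])
    def test_thousand_class_reference_totals(self, inventory, imagenet_total):
        """Cross-check against the canonical ImageNet-head totals."""
        assert zoo.count_inventory(inventory(1000)) == imagenet_total
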