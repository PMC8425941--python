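import numpy as np
import pytest

from dwiseg.unet3d import (
    Conv3d,
    LayerCensus,
    NoExactMatchError,
    UNetConfig,
    WidthSearchSpace,
    _Head,
    build_unet,
    closed_form_param_count,
    count_parameters,
    feature_map_shape,
    find_width_config,
    layer_census,
)
from dwiseg.volume_io import ShapeError


class TestConfig:
    def test_widths_length_must_match_levels(self):
        with pytest.raises(ValueError):
            UNetConfig(levels=3, widths=(8, 16))

    def test_out_channels_restricted(self):
        with pytest.raises(ValueError):
            UNetConfig(out_channels=3)

    def test_extra_convs_validated(self):
        with pytest.raises(ValueError):
            UNetConfig(levels=2, widths=(4, 8), decoder_extra_convs=(1,))

    def test_json_round_trip(self, tmp_path):
        cfg = UNetConfig(levels=2, widths=(4, 8), head_kernel=(1, 1, 1))
        p = tmp_path / "cfg.json"
        cfg.to_json(p)
        assert UNetConfig.from_json(p) == cfg

    def test_json_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.json"
        p.write_text('{"levels": 2, "widths": [4, 8], "depth": 9}')
        with pytest.raises(ValueError):
            UNetConfig.from_json(p)


class TestForward:
    def test_shape_contract_toy(self, rng):
        net = build_unet(UNetConfig(levels=2, widths=(4, 8)))
        p = net.forward(rng.normal(size=(8, 8, 8)))
        assert p.shape == (8, 8, 8)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_indivisible_shape_error_names_axis(self, rng):
        net = build_unet(UNetConfig())
        with pytest.raises(ShapeError, match="axis 0"):
            net.forward(rng.normal(size=(100, 64, 16)))

    def test_deterministic_given_fixed_weights(self, rng):
        net = build_unet(UNetConfig(levels=2, widths=(4, 8)), seed=3)
        x = rng.normal(size=(8, 8, 8))
        np.testing.assert_array_equal(net.forward(x), net.forward(x))

    def test_seeded_build_reproducible(self, rng):
        x = rng.normal(size=(8, 8, 8))
        a = build_unet(UNetConfig(levels=2, widths=(4, 8)), seed=5).forward(x)
        b = build_unet(UNetConfig(levels=2, widths=(4, 8)), seed=5).forward(x)
        np.testing.assert_array_equal(a, b)

    def test_two_channel_head_probabilities_sum_to_one(self, rng):
        head = _Head(2)
        z = rng.normal(size=(2, 4, 4, 4)).astype(np.float32)
        p = head.forward(z)
        np.testing.assert_allclose(p.sum(axis=0), 1.0, atol=1e-6)

    def test_internal_shapes_match_feature_map_arithmetic(self, rng):
        cfg = UNetConfig(levels=3, widths=(2, 4, 6))
        net = build_unet(cfg)
        x = rng.normal(size=(16, 16, 8)).astype(np.float32)
        h = x[None]
        for lev in range(cfg.levels - 1):
            for layer in net.enc_blocks[lev]:
                h = layer.forward(h)
            assert h.shape[1:] == feature_map_shape((16, 16, 8), lev)
            h = net.pools[lev].forward(h)
        assert h.shape[1:] == feature_map_shape((16, 16, 8), 2)


class TestCensusAndCount:
    def test_default_census_matches_published_architecture(self):
        cen = layer_census(build_unet(UNetConfig()))
        assert cen == LayerCensus(21, 4, 4, 4)

    def test_toy_two_level_census_by_hand(self):
        # encoder 2 blocks x 2 convs + decoder 1 block x 2 + 3x3x3 head = 7
        cen = layer_census(build_unet(UNetConfig(levels=2, widths=(4, 8))))
        assert cen == LayerCensus(7, 1, 1, 1)

    def test_single_level_has_no_down_up_path(self):
        cen = layer_census(build_unet(UNetConfig(levels=1, widths=(4,))))
        assert (cen.n_pool, cen.n_transpose, cen.n_concat) == (0, 0, 0)

    def test_one_by_one_head_not_counted_as_conv3(self):
        cfg = UNetConfig(levels=2, widths=(4, 8), head_kernel=(1, 1, 1))
        assert layer_census(build_unet(cfg)).n_conv3 == 6

    def test_single_conv_counts_by_hand(self, rng):
        # 3x3x3 conv 1->16 with bias: 27*16 + 16 = 448
        conv = Conv3d(1, 16, (3, 3, 3), True, rng)
        assert sum(p.value.size for p in conv.params()) == 448
        # 1x1x1 conv 16->1 with bias: 16 + 1 = 17
        conv = Conv3d(16, 1, (1, 1, 1), True, rng)
        assert sum(p.value.size for p in conv.params()) == 17

    @pytest.mark.parametrize("seed", range(5))
    def test_count_matches_closed_form_random_configs(self, seed):
        r = np.random.default_rng(seed)
        levels = int(r.integers(1, 4))
        cfg = UNetConfig(
            levels=levels,
            widths=tuple(int(r.integers(2, 8)) for _ in range(levels)),
            convs_per_block=int(r.integers(1, 4)),
            decoder_extra_convs=tuple(
                lev for lev in range(levels - 1) if r.random() < 0.3
            ),
            transpose_mode=["halve", "keep"][int(r.integers(2))],
            out_channels=[1, 2][int(r.integers(2))],
            head_kernel=[(1, 1, 1), (3, 3, 3)][int(r.integers(2))],
            use_bias=bool(r.integers(2)),
            use_norm=bool(r.integers(2)),
        )
        assert count_parameters(build_unet(cfg)) == closed_form_param_count(cfg)


class TestFeatureMapShape:
    def test_published_bottleneck_shape(self):
        assert feature_map_shape((256, 256, 32), 4) == (16, 16, 2)

    def test_level_zero_identity(self):
        assert feature_map_shape((20, 12, 8), 0) == (20, 12, 8)

    def test_repeated_halving(self):
        assert feature_map_shape((64, 64, 16), 2) == (16, 16, 4)

    def test_indivisible_rejected(self):
        with pytest.raises(ShapeError):
            feature_map_shape((100, 64, 16), 4)


class TestGradients:
    def test_directional_derivatives_agree(self, rng):
        """Analytic backprop vs central differences on a tiny net."""
        from dwiseg.training import _soft_dice_and_grad

        net = build_unet(UNetConfig(levels=2, widths=(3, 5)), seed=1)
        x = rng.normal(size=(8, 8, 8))
        a = (rng.random((8, 8, 8)) > 0.7).astype(np.uint8)

        def loss():
            p = net.forward(x).astype(np.float64)
            num = 2 * float((p * a).sum()) + 1e-6
            den = float(p.sum()) + float(a.sum()) + 1e-6
            return 1 - num / den

        net.zero_grad()
        p = net.forward(x, train=True)
        _, gp = _soft_dice_and_grad(p, a, 1e-6)
        net.backward(gp)
        checked = 0
        for prm in net.parameters():
            d = rng.normal(size=prm.value.shape).astype(np.float32)
            d /= np.linalg.norm(d)
            h = 1e-2
            prm.value += h * d
            lp = loss()
            prm.value -= 2 * h * d
            lm = loss()
            prm.value += h * d
            num = (lp - lm) / (2 * h)
            ana = float((prm.grad * d).sum())
            if abs(num) + abs(ana) > 1e-4:  # skip noise-dominated directions
                assert abs(num - ana) / (abs(num) + abs(ana)) < 0.15
                checked += 1
        assert checked >= 5


class TestWidthSearch:
    def test_plant_and_recover(self):
        toy = UNetConfig(levels=2, widths=(8, 16))
        target = closed_form_param_count(toy)
        census = layer_census(build_unet(toy))
        found = find_width_config(census, target)
        assert closed_form_param_count(found) == target
        assert layer_census(build_unet(found)) == census

    def test_infeasible_target_reports_nearest(self):
        with pytest.raises(NoExactMatchError) as exc:
            find_width_config(LayerCensus(7, 1, 1, 1), 1)
        assert exc.value.nearest  # diagnostics included

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            find_width_config(LayerCensus(7, 1, 1, 1), 0)

    def test_asymmetric_census_rejected(self):
        with pytest.raises(ValueError):
            find_width_config(LayerCensus(21, 4, 3, 4), 100)
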