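"""MBFFNet architecture contracts: shapes, attention fusion, gradients."""

import numpy as np
import pytest

import mbffnet as mb
from mbffnet.model import DimensionError, FusionBlock, MBFFNet, ModelConfig, ShapeError
from mbffnet.nn import Var


def _image(side, seed=0):
    return np.random.default_rng(seed).uniform(0, 1, size=(side, side, 3)).astype(np.float32)


class TestEncoder:
    def test_stage_shapes_default_widths(self, tiny_model):
        stages = tiny_model.encode(_image(64))
        sides = [s.shape[-1] for s in stages]
        chans = [s.shape[1] for s in stages]
        assert sides == [64, 32, 16, 8, 4]
        assert chans == [8, 16, 32, 64, 64]

    def test_full_width_stage_channels(self):
        # channel arithmetic only needs the config, not a heavy forward
        cfg = ModelConfig()
        assert tuple(cfg.encoder_widths) == (64, 128, 256, 512, 512)
        m = MBFFNet(mb.tiny_config(128))
        sides = [s.shape[-1] for s in m.encode(_image(128))]
        assert sides == [128, 64, 32, 16, 8]

    @pytest.mark.parametrize("bad_side", [250, 100])
    def test_indivisible_input_rejected(self, tiny_model, bad_side):
        with pytest.raises(DimensionError, match="divisible"):
            tiny_model.encode(_image(bad_side) if bad_side % 2 == 0 else _image(bad_side))

    def test_non_square_rejected(self, tiny_model):
        img = np.zeros((64, 48, 3), dtype=np.float32)
        with pytest.raises(DimensionError, match="height 64 != width 48"):
            tiny_model.encode(img)


class TestFusion:
    def _block(self, seed=0):
        rng = np.random.default_rng(seed)
        return FusionBlock(4, 6, 5, rng)

    def test_output_shape(self):
        blk = self._block()
        deep = Var(np.random.default_rng(0).normal(size=(1, 4, 8, 8)).astype(np.float32))
        skip = Var(np.random.default_rng(1).normal(size=(1, 6, 16, 16)).astype(np.float32))
        out = blk(deep, skip)
        assert out.shape == (1, 5, 16, 16)

    def test_spatial_mismatch_rejected(self):
        blk = self._block()
        deep = Var(np.zeros((1, 4, 8, 8), dtype=np.float32))
        skip = Var(np.zeros((1, 6, 17, 17), dtype=np.float32))
        with pytest.raises(ShapeError):
            blk(deep, skip)

    def test_attention_identity_and_annihilation(self):
        blk = self._block()
        deep = Var(np.random.default_rng(0).normal(size=(1, 4, 8, 8)).astype(np.float32))
        skip = Var(np.random.default_rng(1).normal(size=(1, 6, 16, 16)).astype(np.float32))
        ones = np.ones((1, 6, 16, 16), dtype=np.float32)
        out_identity = blk(deep, skip, attention=ones)
        ref = blk.refine2(blk.refine(skip))
        assert np.allclose(out_identity.data, ref.data, atol=1e-6)
        product = blk.product(deep, skip, attention=np.zeros_like(ones))
        assert np.all(product.data == 0.0)

    def test_attention_weights_bounded(self):
        blk = self._block()
        deep = Var(np.random.default_rng(2).normal(size=(1, 4, 8, 8)).astype(np.float32) * 10)
        skip = Var(np.zeros((1, 6, 16, 16), dtype=np.float32))
        w = blk.weights(deep, skip)
        assert w.data.min() >= 0.0 and w.data.max() <= 1.0

    def test_softmax_attention_sums_to_one(self):
        rng = np.random.default_rng(3)
        blk = FusionBlock(4, 6, 5, rng, attention="softmax")
        deep = Var(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        skip = Var(rng.normal(size=(1, 6, 16, 16)).astype(np.float32))
        w = blk.weights(deep, skip)
        assert np.allclose(w.data.sum(axis=(2, 3)), 1.0, atol=1e-5)


class TestDecoderAndPyramid:
    def test_decode_main_full_resolution(self, tiny_model):
        stages = tiny_model.encode(_image(64))
        out = tiny_model.decode_main(stages)
        assert out.shape == (1, tiny_model.config.decoder_widths[-1], 64, 64)

    def test_missing_stage_rejected(self, tiny_model):
        stages = tiny_model.encode(_image(64))
        with pytest.raises(ShapeError):
            tiny_model.decode_main(stages[:4])

    def test_pyramid_reference_resolution(self, tiny_model):
        stages = tiny_model.encode(_image(64))
        out = tiny_model.pyramid_branch(stages)
        assert out.shape == (1, tiny_model.config.pyramid_channels, 32, 32)

    def test_pyramid_concat_width_default_config(self):
        assert sum(ModelConfig().encoder_widths) == 1472

    def test_pyramid_constant_maps_stay_constant(self, tiny_model):
        """Resize + concat + conv is linear, so constant stages give a
        per-channel constant pyramid output."""
        stages = [
            Var(np.full((1, c, s, s), 0.5, dtype=np.float32))
            for c, s in zip((8, 16, 32, 64, 64), (64, 32, 16, 8, 4))
        ]
        interior = tiny_model.pyramid_branch(stages).data[:, :, 2:-2, 2:-2]
        spread = interior.max(axis=(2, 3)) - interior.min(axis=(2, 3))
        assert spread.max() < 1e-4  # zero padding perturbs only the border


class TestForward:
    @pytest.mark.parametrize("side", [64, 128])
    def test_shape_conservation_and_range(self, side):
        m = MBFFNet(mb.tiny_config(side))
        out = m.forward(_image(side))
        assert out.shape == (1, 1, side, side)
        assert out.data.min() > 0.0 and out.data.max() < 1.0

    def test_shape_conservation_full_model_256(self):
        """The default (full-width) network maps 256x256x3 to a 256x256
        probability map."""
        m = MBFFNet(ModelConfig())
        out = m.forward(_image(256))
        assert out.shape == (1, 1, 256, 256)
        assert out.data.min() > 0.0 and out.data.max() < 1.0

    def test_inference_deterministic(self, tiny_model):
        img = _image(64, seed=5)
        a = tiny_model.forward(img).data
        b = tiny_model.forward(img).data
        assert np.array_equal(a, b)

    def test_same_seed_same_weights(self):
        a = MBFFNet(mb.tiny_config(64, seed=7))
        b = MBFFNet(mb.tiny_config(64, seed=7))
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_gradient_reaches_every_parameter(self, scene64):
        """No dead branch: the Dice+CE loss sends a nonzero gradient to
        every convolution on a random batch."""
        from mbffnet.train import dice_ce_objective

        m = MBFFNet(mb.tiny_config(64, seed=1))
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, size=(2, 3, 64, 64)).astype(np.float32)
        y = np.stack([scene64.mask, 1 - scene64.mask])[:, None].astype(np.float32)
        loss = dice_ce_objective(m.forward(Var(x)), y)
        loss.backward()
        for p in m.parameters():
            assert p.grad is not None and np.abs(p.grad).max() > 0, p.name


class TestConfigAndDump:
    def test_input_size_divisibility(self):
        with pytest.raises(DimensionError):
            ModelConfig(input_size=250)

    def test_yaml_round_trip(self, tmp_path):
        cfg = mb.tiny_config(64, seed=3)
        p = tmp_path / "model.yaml"
        cfg.to_yaml(p)
        assert ModelConfig.from_yaml(str(p)) == cfg

    def test_dump_matches_instantiated_convs(self, tiny_model):
        specs = tiny_model.conv_layer_specs(64)
        params = tiny_model.parameters()
        assert len(specs) == len(params)
        for sp, p in zip(specs, params):
            assert sp.name == p.name
            assert p.data.shape == (sp.co, sp.ci, sp.kh, sp.kw)

    def test_checkpoint_round_trip(self, tmp_path):
        m = MBFFNet(mb.tiny_config(64, seed=2))
        img = _image(64, seed=9)
        before = m.forward(img).data
        path = tmp_path / "w.npz"
        m.save_weights(path)
        other = MBFFNet(mb.tiny_config(64, seed=99))
        other.load_weights(path)
        assert np.array_equal(other.forward(img).data, before)
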