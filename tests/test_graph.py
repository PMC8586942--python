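"""Layer-graph construction and forward-pass behaviour."""

import numpy as np
import pytest

import tinyseg as ts
from tinyseg.graph import GraphError

from conftest import brute_force_forward


class TestMultiResBlock:
    @pytest.mark.parametrize("xc,expected", [
        (6, (1, 2, 3)),
        (96, (16, 32, 48)),
        (30, (5, 10, 15)),
    ])
    def test_branch_widths_are_sixths(self, xc, expected):
        assert ts.MRBConfig(xc).branch_channels == expected

    @pytest.mark.parametrize("xc", [5, 7, 0, -6, 10])
    def test_rejects_widths_not_divisible_by_six(self, xc):
        with pytest.raises(GraphError):
            ts.MRBConfig(xc)

    @pytest.mark.parametrize("xc", [6, 12, 30, 96])
    def test_output_channels_equal_input_channels(self, xc):
        """The additive shortcut forces shape preservation."""
        sub = ts.mrb_subgraph(ts.MRBConfig(xc))
        shapes = sub.infer_shapes()
        assert shapes["mrb/add"] == (16, 16, xc)


class TestResPath:
    def test_parameter_ledger(self):
        """4 reps of parallel 1x1 and 3x3 convs: 4*[(c^2+c)+(9c^2+c)]."""
        for c in (1, 3, 8):
            sub = ts.respath_subgraph(ts.ResPathConfig(c))
            expected = 4 * ((c * c + c) + (9 * c * c + c))
            head = sub.node("out").conv.n_parameters
            assert ts.count_parameters(sub) - head == expected

    def test_single_channel_instance(self):
        sub = ts.respath_subgraph(ts.ResPathConfig(1))
        assert ts.count_parameters(sub) - sub.node("out").conv.n_parameters == 48

    def test_repetitions_fixed_at_four(self):
        with pytest.raises(GraphError):
            ts.ResPathConfig(8, repetitions=3)


class TestBuildModel:
    def test_unknown_architecture(self):
        with pytest.raises(GraphError):
            ts.build_model("segnet")

    @pytest.mark.parametrize("name,divisor", [
        ("unet", 16), ("multiresunet", 16),
        ("half_unet", 4), ("half_multiresunet", 4),
        ("quarter_multiresunet", 2),
    ])
    def test_indivisible_input_rejected(self, name, divisor):
        bad = divisor + divisor // 2
        with pytest.raises(GraphError):
            ts.build_model(name, input_shape=(bad, bad, 3))

    def test_quarter_has_one_pooling_level(self):
        m = ts.build_model("quarter_multiresunet", input_shape=(64, 64, 1))
        ops = [n.op for n in m.nodes]
        assert ops.count("maxpool2") == 1
        assert ops.count("upsample2") == 1

    @pytest.mark.parametrize("name,stages", [
        ("unet", 9), ("half_unet", 5), ("multiresunet", 9),
        ("half_multiresunet", 5), ("quarter_multiresunet", 3),
    ])
    def test_stage_counts(self, name, stages):
        size = 64
        m = ts.build_model(name, input_shape=(size, size, 3))
        seen = {n.stage for n in m.nodes if n.stage is not None}
        assert seen == set(range(stages))

    def test_toy_half_unet_parameter_ledger(self):
        """Hand-summed k^2*in*out + out over the node list."""
        m = ts.build_model("half_unet",
                           config={"encoder": [8, 16, 32], "decoder": [16, 8]},
                           input_shape=(64, 64, 1))
        ledger = 0
        for node in m.conv_nodes():
            s = node.conv
            ledger += s.kernel_size ** 2 * s.in_channels * s.out_channels
            ledger += s.out_channels
        assert ts.count_parameters(m) == ledger
        # independently: the explicit sum for this width table
        expected = sum(
            9 * a * b + b
            for a, b in [(1, 8), (8, 8), (8, 16), (16, 16), (16, 32),
                         (32, 32), (48, 16), (16, 16), (24, 8), (8, 8)]
        ) + (8 * 1 + 1)
        assert ledger == expected

    @pytest.mark.parametrize("name", ts.ARCH_NAMES)
    @pytest.mark.parametrize("scale", [1, 2, 4])
    def test_output_spatial_size_equals_input(self, name, scale):
        size = 16 * scale
        m = ts.build_model(name, input_shape=(size, size, 3))
        assert m.output_shape == (size, size, 1)

    def test_concat_order_encoder_first(self):
        """Skip operand order: encoder output, then upsampled decoder."""
        m = ts.build_model("half_unet",
                           config={"encoder": [4, 6, 8], "decoder": [6, 4]},
                           input_shape=(32, 32, 1))
        for node in m.nodes:
            if node.op == "concat":
                skip, up = node.inputs
                assert skip.startswith("enc")
                assert up.endswith("/up")


class TestForward:
    def test_zero_weights_give_half_everywhere(self, toy_quarter, rng):
        toy_quarter.initialize(rng)
        for n in toy_quarter.conv_nodes():
            n.conv.kernel[:] = 0.0
            n.conv.bias[:] = 0.0
        out = ts.forward(toy_quarter, rng.random((16, 16, 1)))
        assert np.allclose(out, 0.5)

    def test_single_conv_closed_form(self):
        """1x1 conv on a constant image: sigmoid(w*v + b) everywhere."""
        from tinyseg.graph import ConvSpec, ModelSpec, Node
        w, b, v = 0.7, -0.2, 0.31
        spec = ConvSpec(1, 1, 1, 1, "sigmoid",
                        kernel=np.full((1, 1, 1, 1), w, np.float32),
                        bias=np.full(1, b, np.float32))
        m = ModelSpec("toy", [Node("in", "input"),
                              Node("out", "conv", ("in",), spec)], (8, 8, 1))
        out = ts.forward(m, np.full((8, 8, 1), v, np.float32))
        expected = 1.0 / (1.0 + np.exp(-(w * v + b)))
        assert np.allclose(out, expected, atol=1e-6)

    def test_shape_mismatch_rejected(self, toy_quarter, rng):
        toy_quarter.initialize(rng)
        with pytest.raises(GraphError):
            ts.forward(toy_quarter, rng.random((8, 8, 1)))

    def test_outputs_strictly_inside_unit_interval(self, toy_quarter, rng):
        toy_quarter.initialize(rng)
        out = ts.forward(toy_quarter, rng.random((16, 16, 1)))
        assert np.all(out > 0) and np.all(out < 1)

    @pytest.mark.parametrize("fixture", ["toy_quarter", "toy_unet"])
    def test_matches_scalar_loop_oracle(self, fixture, rng, request):
        """Pixel-for-pixel agreement with a straight-line scalar oracle."""
        model = request.getfixturevalue(fixture)
        model.initialize(rng)
        size = model.input_shape[0]
        image = rng.random((size, size, 1)).astype(np.float32)
        fast = ts.forward(model, image)
        slow = brute_force_forward(model, image)
        np.testing.assert_allclose(fast, slow, atol=1e-5)

    def test_forward_deterministic(self, toy_quarter, rng):
        toy_quarter.initialize(rng)
        image = rng.random((16, 16, 1))
        np.testing.assert_array_equal(ts.forward(toy_quarter, image),
                                      ts.forward(toy_quarter, image))


def test_pool_then_upsample_preserves_constant_images():
    from tinyseg.graph import maxpool2, upsample2
    x = np.full((1, 8, 8, 3), 0.37, np.float32)
    np.testing.assert_array_equal(upsample2(maxpool2(x)), x)
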