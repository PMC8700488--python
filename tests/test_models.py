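"""Architecture census, dense connectivity, loss, and CNN training."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from okcpipe import (
    ModelSpec,
    SmallCNN,
    bce_loss,
    build_densenet,
    build_model,
    build_vgg16,
    dense_connection_count,
    dense_layer_input,
)
from okcpipe.models import VGG16_CONV_FILTERS, images_to_array, predict, train
from okcpipe.nn import softmax
from okcpipe.synthdata import OKC, SyntheticSpec, generate_dataset


class TestVGG16Census:
    def test_thirteen_conv_layers(self):
        desc = build_vgg16()
        assert len(desc.conv_layers) == 13

    def test_filter_sequence(self):
        desc = build_vgg16()
        assert tuple(l.filters for l in desc.conv_layers) == VGG16_CONV_FILTERS
        assert all(l.kernel == (3, 3) for l in desc.conv_layers)
        assert all(l.stride == 1 and l.padding == 1 for l in desc.conv_layers)

    def test_head_widths(self):
        desc = build_vgg16()
        assert desc.head_widths == (25088, 4096, 2)
        assert desc.flattened_features == 25088  # 7 * 7 * 512

    def test_five_pools_halve_to_seven(self):
        desc = build_vgg16()
        pools = [l for l in desc.layers if l.kind == "maxpool"]
        assert len(pools) == 5
        assert pools[-1].output_shape == (7, 7, 512)

    def test_conv_layers_frozen_head_trainable(self):
        desc = build_vgg16()
        assert all(l.frozen for l in desc.conv_layers)
        assert all(not l.frozen for l in desc.layers if l.kind == "dense")

    def test_softmax_output_layer(self):
        assert build_vgg16().layers[-1].activation == "softmax"

    def test_wrong_input_shape_rejected(self):
        with pytest.raises(ValueError, match="224"):
            build_vgg16(ModelSpec(architecture="vgg16", input_shape=(96, 96, 3)))


class TestDenseNet:
    def test_169_block_configuration(self):
        desc = build_densenet()
        dense_layers = [l for l in desc.layers if l.kind == "bn_relu_conv"]
        assert len(dense_layers) == 6 + 12 + 32 + 32
        assert desc.name == "densenet169"

    def test_growth_rate_channel_arithmetic(self):
        """A 4-layer block with growth 12 on a 12-channel input: layer 4
        sees the 48-channel concatenation of y0..y3."""
        maps = [np.zeros((8, 8, 12)) for _ in range(4)]
        concat = dense_layer_input(maps)
        assert concat.shape == (8, 8, 48)

    def test_single_map_base_case(self):
        y0 = np.ones((4, 4, 12))
        np.testing.assert_array_equal(dense_layer_input([y0]), y0)

    def test_spatial_mismatch_rejected(self):
        with pytest.raises(ValueError, match="spatial"):
            dense_layer_input([np.zeros((4, 4, 3)), np.zeros((5, 4, 3))])

    def test_transitions_compress_channels_by_half(self):
        desc = build_densenet(block_config=(6, 12), growth_rate=32)
        transitions = [l for l in desc.layers if l.name.startswith("transition")]
        # after block 1: 64 + 6*32 = 256 -> 128
        assert transitions[0].filters == 128

    def test_small_growth_rate_admissible(self):
        desc = build_densenet(block_config=(4,), growth_rate=12, initial_channels=12)
        last = [l for l in desc.layers if l.kind == "bn_relu_conv"][-1]
        assert last.output_shape[-1] == 12 + 4 * 12


class TestDenseConnectionCount:
    @pytest.mark.parametrize("n,expected", [(1, 1), (4, 10), (169, 14365)])
    def test_closed_form(self, n, expected):
        assert dense_connection_count(n) == expected

    @given(st.integers(min_value=1, max_value=20))
    @settings(max_examples=20, derandomize=True)
    def test_matches_edge_enumeration(self, n):
        # enumerate the forward connections explicitly: the input and
        # every layer feed each subsequent layer
        edges = sum(1 for src in range(n + 1) for dst in range(src + 1, n + 1))
        assert dense_connection_count(n) == edges

    def test_rejects_zero_layers(self):
        with pytest.raises(ValueError):
            dense_connection_count(0)


class TestBCELoss:
    def test_perfect_prediction_near_zero(self):
        assert bce_loss([1.0], [1.0 - 1e-7]) == pytest.approx(0.0, abs=1e-6)

    def test_coin_flip_is_ln2(self):
        assert bce_loss([1, 0], [0.5, 0.5]) == pytest.approx(math.log(2), rel=1e-12)

    def test_confident_correct_pair(self):
        assert bce_loss([1, 0], [0.9, 0.1]) == pytest.approx(
            -(math.log(0.9) + math.log(0.9)) / 2, rel=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss([1, 0], [0.5])

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=1),
                st.floats(min_value=0.01, max_value=0.99),
            ),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_matches_per_sample_log_sum(self, pairs):
        y = [p[0] for p in pairs]
        p = [p[1] for p in pairs]
        expected = -sum(
            yi * math.log(pi) + (1 - yi) * math.log(1 - pi) for yi, pi in zip(y, p)
        ) / len(pairs)
        assert bce_loss(y, p) == pytest.approx(expected, abs=1e-9)


class TestSoftmax:
    @given(
        st.lists(st.floats(min_value=-30, max_value=30), min_size=2, max_size=2)
    )
    @settings(max_examples=50, derandomize=True)
    def test_rows_sum_to_one(self, logits):
        out = softmax(np.array([logits]))
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        assert (out >= 0).all()


class TestSmallCNNGradients:
    def test_backprop_matches_numerical_gradient(self):
        """Central-difference check of the full backward pass."""
        net = SmallCNN(input_shape=(8, 8, 3), filters=(4, 4, 4), hidden=5, seed=0)
        rng = np.random.default_rng(1)
        x = rng.random((3, 8, 8, 3))
        y = np.array([1, 0, 1])

        def loss():
            probs = softmax(net.logits(x))
            return bce_loss(y, probs[:, 1])

        probs = softmax(net.logits(x))
        net._backward_from_logits(probs, y)

        checked = 0
        for layer in net.layers:
            for _, param, gname in layer.params():
                grad = getattr(layer, gname)
                flat = param.ravel()
                idxs = rng.choice(flat.size, size=min(4, flat.size), replace=False)
                for i in idxs:
                    eps = 1e-6
                    orig = flat[i]
                    flat[i] = orig + eps
                    lp = loss()
                    flat[i] = orig - eps
                    lm = loss()
                    flat[i] = orig
                    numeric = (lp - lm) / (2 * eps)
                    assert grad.ravel()[i] == pytest.approx(numeric, rel=1e-3, abs=1e-7)
                    checked += 1
        assert checked >= 20


@pytest.fixture(scope="module")
def separable_fixture():
    images = generate_dataset(20, seed=99, spec=SyntheticSpec())
    return images


class TestTraining:
    def test_zero_epochs_leaves_model_unchanged(self, separable_fixture):
        spec = ModelSpec(epochs=0, input_shape=(32, 32, 3))
        model = build_model(spec)
        before = [p.copy() for l in model.layers for _, p, _ in l.params()]
        results = train(model, separable_fixture, spec)
        after = [p for l in model.layers for _, p, _ in l.params()]
        assert results.history == []
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a)

    def test_history_length_matches_epochs(self, separable_fixture):
        spec = ModelSpec(epochs=3, input_shape=(32, 32, 3), learning_rate=1e-3)
        model = build_model(spec)
        results = train(model, separable_fixture, spec)
        assert len(results.history) == 3
        assert {"epoch", "train_loss", "train_acc"} <= set(results.history[0])

    def test_learns_separable_fixture(self, separable_fixture):
        spec = ModelSpec(epochs=35, input_shape=(32, 32, 3), learning_rate=3e-3, seed=1)
        model = build_model(spec)
        results = train(model, separable_fixture, spec)
        assert results.history[-1]["train_acc"] >= 0.9

    def test_trained_beats_untrained_on_positive_scores(self, separable_fixture):
        spec = ModelSpec(epochs=35, input_shape=(32, 32, 3), learning_rate=3e-3, seed=1)
        untrained = build_model(spec)
        okc_imgs = [im for im in separable_fixture if im.label == OKC]
        before = np.mean([s.p_okc for s in predict(untrained, okc_imgs)])
        trained = build_model(spec)
        train(trained, separable_fixture, spec)
        after = np.mean([s.p_okc for s in predict(trained, okc_imgs)])
        assert after > before

    def test_empty_training_set_rejected(self):
        model = SmallCNN(input_shape=(8, 8, 3))
        with pytest.raises(ValueError):
            model.fit(np.empty((0, 8, 8, 3)), np.empty(0), epochs=1)

    def test_fit_deterministic_under_seed(self, separable_fixture):
        x, y, _ = images_to_array(separable_fixture[:10], (16, 16, 3))
        outs = []
        for _ in range(2):
            net = SmallCNN(input_shape=(16, 16, 3), seed=5)
            net.fit(x, y, epochs=2, batch_size=4)
            outs.append(net.predict_proba(x))
        np.testing.assert_array_equal(outs[0], outs[1])


class TestPredict:
    def test_probability_pairs_sum_to_one(self, separable_fixture):
        model = SmallCNN(input_shape=(16, 16, 3), seed=0)
        scores = predict(model, separable_fixture[:8])
        for s in scores:
            assert s.p_okc + s.p_nonokc == pytest.approx(1.0, abs=1e-6)

    def test_cardinality_and_order(self, separable_fixture):
        model = SmallCNN(input_shape=(16, 16, 3), seed=0)
        scores = predict(model, separable_fixture[:8])
        assert [s.id for s in scores] == [im.source_id for im in separable_fixture[:8]]

    def test_duplicate_images_get_identical_scores(self, separable_fixture):
        model = SmallCNN(input_shape=(16, 16, 3), seed=0)
        img = separable_fixture[0]
        scores = predict(model, [img, img])
        assert scores[0].p_okc == scores[1].p_okc

    def test_structural_architectures_not_trainable(self):
        with pytest.raises(ValueError, match="structural"):
            build_model(ModelSpec(architecture="vgg16"))
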