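"""Model builders: heads, shape arithmetic, parameter counts, registry."""

import numpy as np
import pytest

from vpctrace import (
    ImageModelSpec,
    build_image_model,
    build_ts_model,
    conv_output_length,
    kernel_size_grid,
    tiny_ts_spec,
    ts_feature_lengths,
)
from vpctrace.modelspec import SWEEP_KERNEL_SIZES, default_ts_spec
from vpctrace.nn import Dense


def _brute_force_windows(length, kernel, stride):
    """Count valid window placements by enumeration."""
    return len([s for s in range(0, length - kernel + 1, stride)])


@pytest.mark.parametrize("kernel", SWEEP_KERNEL_SIZES)
def test_conv_pool_shape_arithmetic(kernel):
    """Conv (stride 3) then pool (5, stride 3) output lengths on 1250
    samples equal both the closed form and brute-force enumeration."""
    L1 = conv_output_length(1250, kernel, 3)
    assert L1 == (1250 - kernel) // 3 + 1 == _brute_force_windows(1250, kernel, 3)
    L2 = conv_output_length(L1, 5, 3)
    assert L2 == (L1 - 5) // 3 + 1 == _brute_force_windows(L1, 5, 3)


@pytest.mark.parametrize("kernel", [3, 11])
def test_actual_activations_match_shape_arithmetic(kernel):
    spec = tiny_ts_spec("single_input", kernel)
    model = build_ts_model(spec, seed=0)
    from vpctrace.nn import Conv1D, MaxPool1D

    lengths = ts_feature_lengths(spec)
    x = np.zeros((2, 1250, 12))
    observed = []
    for layer in model.layers:
        x = layer.forward(x, train=False)
        if isinstance(layer, (Conv1D, MaxPool1D)):
            observed.append(x.shape[1])
    assert observed == lengths


def test_single_input_softmax_output():
    model = build_ts_model(tiny_ts_spec("single_input"), seed=1)
    p = model.predict_proba(np.random.default_rng(0).normal(size=(3, 1250, 12)))
    assert p.shape == (3, 2)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
    assert (p >= 0).all()


def test_multi_input_accepts_exactly_12_inputs():
    model = build_ts_model(tiny_ts_spec("multi_input"), seed=1)
    assert model.n_inputs == 12
    xs = [np.zeros((2, 1250, 1)) for _ in range(12)]
    assert model.predict_proba(xs).shape == (2, 2)
    with pytest.raises(ValueError, match="12"):
        model.forward(xs[:5])


def test_multi_input_branches_have_independent_weights():
    model = build_ts_model(tiny_ts_spec("multi_input"), seed=2)
    w0 = model.branches[0].parameters()[0]
    w1 = model.branches[1].parameters()[0]
    assert w0 is not w1
    assert not np.array_equal(w0, w1)


def test_multi_input_head_has_no_dropout():
    from vpctrace.nn import Dropout

    model = build_ts_model(tiny_ts_spec("multi_input"), seed=0)
    assert not any(isinstance(l, Dropout) for l in model.head.layers)


def test_image_model_head_widths():
    model = build_image_model(ImageModelSpec(dense_size=512), seed=0)
    dense = [l for l in model.layers if isinstance(l, Dense)]
    assert dense[-2].W.shape[1] == 512
    assert dense[-1].W.shape == (512, 2)
    x = np.random.default_rng(3).random((1, 256, 512, 3))
    p = model.predict_proba(x)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
    assert (p >= 0).all()


def test_tiny_backbone_parameter_count_closed_form():
    """Analytic parameter sum over the declared TINY layers."""
    def conv2d(cin, cout, k=3):
        return k * k * cin * cout + cout

    def bn(c):
        return 2 * c

    def dense(i, o):
        return i * o + o

    expected = (
        conv2d(3, 8) + bn(8)
        + conv2d(8, 16) + bn(16)
        + conv2d(16, 32) + bn(32)
        + dense(32, 512) + dense(512, 2)
    )
    model = build_image_model(ImageModelSpec(backbone_id="TINY"), seed=0)
    assert model.n_parameters() == expected


def test_unknown_backbone_lists_registry():
    with pytest.raises(ValueError, match="TINY"):
        build_image_model(ImageModelSpec(backbone_id="LeNet"), seed=0)


def test_unrunnable_backbone_raises_clearly():
    with pytest.raises(NotImplementedError, match="ResNet50V2"):
        build_image_model(ImageModelSpec(backbone_id="ResNet50V2"), seed=0)


def test_vgg16_constructs():
    model = build_image_model(ImageModelSpec(backbone_id="VGG16"), seed=0)
    assert model.n_parameters() > 10_000_000


def test_kernel_grid_specs_differ_only_in_kernel():
    specs = kernel_size_grid("single_input", [3, 5, 7, 9, 11])
    assert len(specs) == 5
    for spec, k in zip(specs, [3, 5, 7, 9, 11]):
        assert all(b.kernel_size == k for b in spec.blocks)
        assert spec.mode == "single_input"
        assert [b.n_filters for b in spec.blocks] == [32, 64, 128]
    single = kernel_size_grid("single_input", [7])
    assert len(single) == 1 and single[0] == default_ts_spec("single_input", 7)


def test_unusual_kernel_size_warns():
    spec = tiny_ts_spec("single_input", 13)
    with pytest.warns(UserWarning, match="sweep"):
        model = build_ts_model(spec, seed=0)
    assert model.predict_proba(np.zeros((1, 1250, 12))).shape == (1, 2)


def test_inference_forward_deterministic():
    model = build_ts_model(tiny_ts_spec("single_input"), seed=5)
    x = np.random.default_rng(4).normal(size=(4, 1250, 12))
    np.testing.assert_array_equal(model.predict_proba(x), model.predict_proba(x))


def test_residual_variant_builds_and_runs():
    spec = default_ts_spec("single_input", 7, residual=True)
    model = build_ts_model(spec, seed=0)
    p = model.predict_proba(np.random.default_rng(0).normal(size=(2, 1250, 12)))
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
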