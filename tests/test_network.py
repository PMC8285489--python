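"""Architecture construction, ablations and parameter-count contracts."""

import dataclasses

import numpy as np
import pytest
import yaml

from mvseg.nn import (
    MVCNN,
    NetworkConfig,
    ablation_config,
    build_network,
    count_parameters,
)
from mvseg.nn.branch import Branch2D
from mvseg.nn.layers import (
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    MaxPool2D,
    ReLU,
    Sequential,
)


def random_batch(config, batch=4, seed=0):
    rng = np.random.default_rng(seed)
    shape = (batch, 32, 32, 32, config.ch) if config.is_3d else (batch, 32, 32, config.ch)
    return {key: rng.normal(size=shape).astype(np.float32)
            for key in config.branch_keys}


def test_best_configuration_has_nine_branch_stems():
    model = build_network(NetworkConfig(conv_filters=(2, 4)))
    assert len(model.branches) == 9
    assert set(model.config.branch_keys) == {
        (v, s) for v in ("axial", "coronal", "sagittal") for s in (0, 1, 2)
    }


def test_softmax_output_rows_are_distributions():
    config = NetworkConfig(conv_filters=(2, 4), seed=5)
    model = build_network(config)
    probs = model.forward(random_batch(config))
    assert (probs >= 0).all()
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_same_seed_builds_identical_networks():
    config = NetworkConfig(conv_filters=(2, 4), seed=9)
    batch = random_batch(config)
    a = build_network(config).forward(batch)
    b = build_network(config).forward(batch)
    assert np.array_equal(a, b)


def test_ablation_configurations():
    ax = ablation_config("axial_view")
    assert ax.views == ("axial",)
    assert ax.scales == (0, 1, 2)
    assert ax.ch == 3
    d3 = ablation_config("3d_view")
    assert d3.views == ("3d",)
    assert d3.scales == (0, 1, 2)
    base = NetworkConfig()
    for cfg in (ax, d3):
        assert cfg.conv_filters == base.conv_filters
        assert cfg.dense_units == base.dense_units == 32
        assert cfg.dropout_p == base.dropout_p == 0.25
        assert cfg.n_classes == 6
    with pytest.raises(ValueError):
        ablation_config("coronal_only")


def test_parameter_count_increases_with_filters():
    small = count_parameters(NetworkConfig(conv_filters=(4, 8)))
    big = count_parameters(NetworkConfig(conv_filters=(8, 16)))
    assert big > small


def test_3d_variant_has_more_parameters_than_multiview():
    mv = count_parameters(NetworkConfig(conv_filters=(8, 16)))
    d3 = count_parameters(
        dataclasses.replace(ablation_config("3d_view"), conv_filters=(8, 16))
    )
    assert d3 > mv


def test_parameter_count_matches_closed_form_for_toy_config():
    ch, f1, f2, du, C = 2, 4, 8, 32, 6
    config = NetworkConfig(views=("axial",), scales=(0,), ch=ch,
                           conv_filters=(f1, f2), dense_units=du, n_classes=C)
    # hand-summed: conv1 + BN1 + conv2 + BN2 + branch dense + BN + head
    conv1 = 9 * ch * f1 + f1
    bn1 = 2 * f1
    conv2 = 9 * f1 * f2 + f2
    bn2 = 2 * f2
    dense_b = 16 * 16 * f2 * du + du
    bn3 = 2 * du
    head_dense1 = du * du + du  # one branch -> concat width du
    head_bn = 2 * du
    head_out = du * C + C
    expected = conv1 + bn1 + conv2 + bn2 + dense_b + bn3 + head_dense1 + head_bn + head_out
    assert count_parameters(config) == expected


def test_architecture_echo_roundtrip():
    model = build_network(NetworkConfig(conv_filters=(2, 4)))
    text = model.architecture_yaml()
    assert yaml.safe_load(text) == model.architecture()


def test_batchnorm_precedes_every_relu():
    model = build_network(NetworkConfig(conv_filters=(2, 4)))
    for entry in model.architecture():
        layers = entry["layers"]
        for i, layer in enumerate(layers):
            if layer["type"] == "ReLU":
                assert layers[i - 1]["type"] == "BatchNorm"
    # the final softmax layer is a Dense without BN in front
    head = model.architecture()[-1]["layers"]
    assert head[-1]["type"] == "Dense"


def test_zero_input_yields_softmax_of_biases():
    config = NetworkConfig(conv_filters=(2, 4), seed=1)
    model = build_network(config)
    batch = {key: np.zeros((3, 32, 32, config.ch), np.float32)
             for key in config.branch_keys}
    probs = model.forward(batch)
    assert np.isfinite(probs).all()
    # zero activations propagate; output biases are zero-initialized
    assert np.allclose(probs, 1.0 / config.n_classes, atol=1e-6)


def test_dropout_p_and_dense_width_defaults_fixed():
    config = NetworkConfig()
    assert config.dropout_p == 0.25
    assert config.dense_units == 32
    desc = build_network(NetworkConfig(conv_filters=(2, 4))).architecture()
    drops = [l for e in desc for l in e["layers"] if l["type"] == "Dropout"]
    assert drops and all(d["p"] == 0.25 for d in drops)
    denses = [l for e in desc[:-1] for l in e["layers"] if l["type"] == "Dense"]
    assert denses and all(d["units"] == 32 for d in denses)


def test_invalid_configurations_rejected():
    with pytest.raises(ValueError):
        NetworkConfig(views=("axial", "3d"))
    with pytest.raises(ValueError):
        NetworkConfig(scales=())
    with pytest.raises(ValueError):
        NetworkConfig(scales=(2, 1))
    with pytest.raises(ValueError):
        NetworkConfig(conv_filters=(0, 4))


def test_weight_checkpoint_roundtrip(tmp_path):
    config = NetworkConfig(conv_filters=(2, 4), seed=3)
    model = build_network(config)
    batch = random_batch(config)
    before = model.forward(batch)
    path = tmp_path / "weights.npz"
    model.save_weights(path)
    other = build_network(dataclasses.replace(config, seed=99))
    other.load_weights(path)
    assert np.array_equal(other.forward(batch), before)
    incompatible = build_network(NetworkConfig(conv_filters=(4, 8)))
    with pytest.raises(ValueError, match="hash"):
        incompatible.load_weights(path)


def test_kernel_branch_matches_generic_layer_stack(rng):
    """The numba-backed 2D stem reproduces the generic layers' forward pass
    and gradients (dropout off so both paths are deterministic)."""
    B, ch, f1, f2, du = 6, 3, 4, 8, 32
    br = Branch2D(ch, f1, f2, du, 0.0, np.random.default_rng(1),
                  np.random.default_rng(2))
    init = np.random.default_rng(99)
    g_conv1 = Conv2D(ch, f1, init, first=True)
    g_conv2 = Conv2D(f1, f2, init)
    g_bn1, g_bn2, g_bn3 = BatchNorm(f1), BatchNorm(f2), BatchNorm(du)
    g_dense = Dense(f2 * 256, du, init)
    seq = Sequential([g_conv1, g_bn1, ReLU(), g_conv2, g_bn2, ReLU(),
                      MaxPool2D(), Dropout(0.0, np.random.default_rng(3)),
                      Flatten(), g_dense, g_bn3, ReLU()])
    g_conv1.w.value[...] = br.w1.value.transpose(1, 2, 0, 3).reshape(9 * ch, f1)
    g_conv2.w.value[...] = br.w2.value.transpose(1, 2, 0, 3).reshape(9 * f1, f2)
    g_dense.w.value[...] = (
        br.wd.value.reshape(f2, 16, 16, du).transpose(1, 2, 0, 3).reshape(-1, du)
    )
    x = rng.normal(size=(B, 32, 32, ch)).astype(np.float32)
    for training in (False, True):
        assert np.allclose(br.forward(x, training), seq.forward(x, training),
                           atol=2e-5)
    g = rng.normal(size=(B, du)).astype(np.float32)
    br.forward(x, True)
    seq.forward(x, True)
    br.backward(g.copy())
    seq.backward(g.copy())
    pairs = [
        (br.w1.grad.transpose(1, 2, 0, 3).reshape(9 * ch, f1), g_conv1.w.grad),
        (br.bn1.gamma.grad, g_bn1.gamma.grad),
        (br.bn1.beta.grad, g_bn1.beta.grad),
        (br.w2.grad.transpose(1, 2, 0, 3).reshape(9 * f1, f2), g_conv2.w.grad),
        (br.bn2.gamma.grad, g_bn2.gamma.grad),
        (br.bn2.beta.grad, g_bn2.beta.grad),
        (br.wd.grad.reshape(f2, 16, 16, du).transpose(1, 2, 0, 3).reshape(-1, du),
         g_dense.w.grad),
        (br.bn3.gamma.grad, g_bn3.gamma.grad),
    ]
    for a, b in pairs:
        assert np.abs(a - b).max() <= 1e-3 * max(np.abs(b).max(), 1e-3)
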