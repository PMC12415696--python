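"""HawksheadNet architecture, preprocessing, training behaviour, TL head."""

import numpy as np
import pandas as pd
import pytest

from hawkshead import synthcohort
from hawkshead.network import (
    HawksheadSpec,
    RandomFeatureExtractor,
    TileClassifier,
    TrainConfig,
    build_hawkshead,
    build_tl_head,
    predict,
    predict_scores,
    preprocess_tiles,
    train,
)
from hawkshead.nn import Dense
from hawkshead.synthcohort import MorphologyParams


# ---------------------------------------------------------------------------
# Architecture conformance


def test_layer_sequence_and_widths():
    model = build_hawkshead(HawksheadSpec(), seed=0)
    arch = model.architecture()
    expected = [
        ("Conv2D", 128),
        ("ReLU", None),
        ("MaxPool2D", None),
        ("Conv2D", 64),
        ("ReLU", None),
        ("MaxPool2D", None),
        ("GlobalAveragePooling", None),
        ("Dropout", None),
        ("Dense", 128),
        ("ReLU", None),
        ("Dense", 64),
        ("ReLU", None),
        ("Dense", 1),
        ("Sigmoid", None),
    ]
    assert arch == expected


def test_parameter_count_closed_form():
    """3x3 kernels: 3,584 + 73,792 + 8,320 + 8,256 + 65 = 94,017."""
    model = build_hawkshead(HawksheadSpec(), seed=0)
    assert model.n_params == 3584 + 73792 + 8320 + 8256 + 65 == 94017


def test_gap_width_is_second_conv_filters():
    model = build_hawkshead(HawksheadSpec(), seed=1)
    x = np.random.default_rng(0).random((2, 128, 128, 3), dtype=np.float32)
    h = x
    for layer in model.layers[:7]:
        h = layer.forward(h)
    assert h.shape == (2, 64)


def test_forward_pass_outputs_probabilities():
    model = build_hawkshead(HawksheadSpec(), seed=2)
    x = np.random.default_rng(1).random((4, 128, 128, 3), dtype=np.float32)
    out = model.forward(x)
    assert out.shape == (4, 1)
    assert np.all((out >= 0) & (out <= 1))


def test_zeroed_output_layer_scores_half():
    model = build_hawkshead(HawksheadSpec(), seed=0)
    final = model.layers[-2]
    assert isinstance(final, Dense)
    final.W.value[:] = 0.0
    final.b.value[:] = 0.0
    x = np.random.default_rng(2).random((5, 128, 128, 3), dtype=np.float32)
    np.testing.assert_array_equal(predict_scores(model, x), np.full(5, 0.5, dtype=np.float32))


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        HawksheadSpec(dense_widths=(128, 64, 2))
    with pytest.raises(ValueError):
        HawksheadSpec(dropout_rate=1.0)
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=0.0)


# ---------------------------------------------------------------------------
# Transfer-learning head


def test_tl_head_parameter_count_closed_form():
    """Trainable parameters: 32*D + 577 (dense 32, 16, 1 with biases)."""
    for dim in (8, 64):
        extractor = RandomFeatureExtractor(output_dim=dim, seed=0)
        model = build_tl_head(extractor)
        assert model.n_params == 32 * dim + 577
    assert build_tl_head(RandomFeatureExtractor(output_dim=8)).n_params == 833


def test_tl_head_architecture():
    model = build_tl_head(RandomFeatureExtractor(output_dim=16))
    names = [name for name, _ in model.architecture()]
    assert names == [
        "FrozenExtractor",
        "Flatten",
        "Dropout",
        "Dense",
        "ReLU",
        "Dense",
        "ReLU",
        "Dense",
        "Sigmoid",
    ]


def test_tl_extractor_input_size_mismatch_rejected():
    with pytest.raises(ValueError):
        build_tl_head(RandomFeatureExtractor(input_size=128), input_size=224)


def test_tl_extractor_frozen_through_training():
    extractor = RandomFeatureExtractor(output_dim=8, seed=3)
    before = extractor.projection.copy()
    model = build_tl_head(extractor, seed=0)
    rng = np.random.default_rng(0)
    x = rng.random((8, 224, 224, 3), dtype=np.float32)
    y = np.tile([0.0, 1.0], 4).astype(np.float32)
    train(model, x, y, x, y, TrainConfig(learning_rate=1e-3, batch_size=4, max_epochs=2, seed=0))
    np.testing.assert_array_equal(extractor.projection, before)
    assert all(p.size <= 32 * 8 + 32 + 528 + 17 for p in model.params())


# ---------------------------------------------------------------------------
# Preprocessing


def test_preprocess_constant_tile_stays_constant():
    tile = np.full((1, 512, 512, 3), 120, dtype=np.uint8)
    out = preprocess_tiles(tile, 128)
    assert out.shape == (1, 128, 128, 3)
    np.testing.assert_allclose(out, 120 / 255.0, atol=1e-6)


def test_preprocess_block_checker_is_exact():
    """Integer-factor downscale is an exact block mean: a checker of 128-px
    blocks maps to a checker of 32-px blocks with unchanged values."""
    tile = np.zeros((1, 512, 512, 3), dtype=np.uint8)
    for i in range(4):
        for j in range(4):
            if (i + j) % 2 == 0:
                tile[0, 128 * i : 128 * (i + 1), 128 * j : 128 * (j + 1)] = 255
    out = preprocess_tiles(tile, 128)
    expected = np.zeros((128, 128))
    for i in range(4):
        for j in range(4):
            if (i + j) % 2 == 0:
                expected[32 * i : 32 * (i + 1), 32 * j : 32 * (j + 1)] = 1.0
    np.testing.assert_array_equal(out[0, :, :, 0], expected)


def test_preprocess_range_and_shape_validation():
    tiles = np.random.default_rng(0).integers(0, 256, (2, 512, 512, 3), dtype=np.uint8)
    out = preprocess_tiles(tiles, 224)
    assert out.shape == (2, 224, 224, 3)
    assert out.min() >= 0.0 and out.max() <= 1.0
    with pytest.raises(ValueError):
        preprocess_tiles(np.zeros((1, 512, 256, 3), dtype=np.uint8), 128)


# ---------------------------------------------------------------------------
# Training behaviour


@pytest.fixture(scope="module")
def contrast_tiles():
    """One patient per class with amplified morphological contrast."""
    params = (
        MorphologyParams(nucleus_radius_mean=4, nucleus_radius_sd=0.8, nucleus_density=20),
        MorphologyParams(nucleus_radius_mean=9, nucleus_radius_sd=1.2, nucleus_density=300),
    )
    cohort = synthcohort.generate_cohort(1, 8, class_params=params, seed=21)
    tiles = [t for p in cohort.patients for t in cohort.iter_tiles(p)]
    x = preprocess_tiles(tiles, 128)
    y = np.array([t.label for t in tiles], dtype=np.float32)
    return tiles, x, y


def test_capacity_memorises_small_set(contrast_tiles):
    """The network fits 16 distinguishable tiles to >= 95% training accuracy
    (dropout off: this probes capacity, not regularisation)."""
    _, x, y = contrast_tiles
    model = build_hawkshead(HawksheadSpec(dropout_rate=0.0), seed=0)
    train(model, x, y, x, y, TrainConfig(learning_rate=1e-2, batch_size=2, max_epochs=12, seed=0))
    eval_acc = float(((predict_scores(model, x) >= 0.5) == (y >= 0.5)).mean())
    assert eval_acc >= 0.95


def test_training_is_deterministic(contrast_tiles):
    _, x, y = contrast_tiles
    losses = []
    for _ in range(2):
        model = build_hawkshead(HawksheadSpec(), seed=5)
        hist = train(model, x[::2], y[::2], x[1::2], y[1::2], TrainConfig(learning_rate=1e-3, batch_size=4, max_epochs=2, seed=5))
        losses.append(hist["train_loss"].iloc[-1])
    assert losses[0] == losses[1]


def test_history_shape_and_single_class_rejected(contrast_tiles):
    _, x, y = contrast_tiles
    model = build_hawkshead(HawksheadSpec(), seed=0)
    hist = train(model, x, y, x, y, TrainConfig(learning_rate=1e-3, batch_size=8, max_epochs=3, seed=0))
    assert list(hist.columns) == ["epoch", "train_loss", "val_loss", "train_acc", "val_acc"]
    assert len(hist) == 3
    with pytest.raises(ValueError):
        train(model, x[y == 0], y[y == 0], x, y, TrainConfig(max_epochs=1))


def test_early_stopping_on_stagnant_validation(contrast_tiles):
    _, x, y = contrast_tiles
    model = build_hawkshead(HawksheadSpec(), seed=0)
    # learning rate so small that validation accuracy cannot improve
    config = TrainConfig(learning_rate=1e-12, batch_size=8, max_epochs=10, early_stop_patience=2, seed=0)
    hist = train(model, x, y, x, y, config)
    assert len(hist) == 3  # epoch 1 sets the best; epochs 2-3 exhaust patience


def test_l2_regularisation_shrinks_dense_weights(contrast_tiles):
    _, x, y = contrast_tiles
    norms = {}
    for l2 in (0.0, 1.0):
        model = build_hawkshead(HawksheadSpec(l2=l2), seed=7)
        train(model, x, y, x, y, TrainConfig(learning_rate=1e-3, batch_size=4, max_epochs=2, seed=7))
        dense_w = [l.W.value for l in model.layers if isinstance(l, Dense)]
        norms[l2] = sum(float(np.linalg.norm(w)) for w in dense_w)
    assert norms[1.0] < norms[0.0]


# ---------------------------------------------------------------------------
# Prediction


def test_predict_one_record_per_tile_in_order(contrast_tiles):
    tiles, x, y = contrast_tiles
    model = build_hawkshead(HawksheadSpec(), seed=0)
    records = predict(model, tiles)
    assert len(records) == len(tiles)
    assert [r.tile_id for r in records] == [t.tile_id for t in tiles]
    assert all(0.0 <= r.score <= 1.0 for r in records)


def test_prediction_invariant_to_batch_partitioning(contrast_tiles):
    _, x, _ = contrast_tiles
    model = build_hawkshead(HawksheadSpec(), seed=3)
    s1 = predict_scores(model, x, batch_size=1)
    s2 = predict_scores(model, x, batch_size=16)
    np.testing.assert_allclose(s1, s2, atol=1e-6)


# ---------------------------------------------------------------------------
# Model/Results façade


def test_classifier_fit_returns_results_with_summary(contrast_tiles):
    tiles, _, _ = contrast_tiles
    clf = TileClassifier(
        tiles[:8] + tiles[12:],
        val_tiles=tiles[8:12],
        config=TrainConfig(learning_rate=1e-3, batch_size=4, max_epochs=2, seed=0),
    )
    res = clf.fit()
    assert res.epochs_run == 2
    assert isinstance(res.history, pd.DataFrame)
    text = res.summary()
    assert "94,017" in text and "Conv2D" in text and "epochs run" in text
    preds = res.predict(tiles[8:12])
    assert len(preds) == 4
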