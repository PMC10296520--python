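"""Dual-patch CNN: shapes, determinism, learning, pre-training."""

import numpy as np
import pytest

from dcefoci.classifier import (
    DualPatchCNN,
    ModelConfig,
    PatchDataset,
    _propagate,
    build_model,
    generate_texture_images,
    predict,
    pretrain_extractors,
    train,
)
from dcefoci.errors import ConfigurationError, DataError, FormatError
from dcefoci.io import PatchPair

TINY = dict(
    local_branch_blocks=[4],
    context_branch_blocks=[4, 8],
    mlp_hidden=16,
    epochs=2,
    batch_size=8,
    dropout_rate=0.0,
    augment_flips=False,
)


def make_separable(n=20, offset=3.0, seed=0, noise=1.0):
    """Half cancer, half benign; cancer patches carry a +offset*sigma mean shift."""
    rng = np.random.default_rng(seed)
    labels = np.array([1, 0] * (n // 2))
    local = rng.standard_normal((n, 24, 24)).astype(np.float32) * noise
    context = rng.standard_normal((n, 128, 128)).astype(np.float32) * noise
    local[labels == 1] += offset * noise
    context[labels == 1] += offset * noise
    return PatchDataset(local, context, labels, [f"P{i}" for i in range(n)])


# -- configuration ----------------------------------------------------------


def test_shape_propagation_oracle():
    assert _propagate(24, [16, 32]) == 6
    assert _propagate(24, [16, 32, 32]) == 3  # 24 -> 12 -> 6 -> 3
    assert _propagate(24, [16] * 4) == 1  # 3 -> 1 via floor pooling
    assert _propagate(128, [16, 32, 64, 64]) == 8
    with pytest.raises(ConfigurationError):
        _propagate(24, [16] * 5)  # cannot pool a 1-px map


def test_invalid_config_rejected():
    with pytest.raises(ConfigurationError):
        ModelConfig(local_branch_blocks=[8] * 5).validate()
    with pytest.raises(ConfigurationError):
        ModelConfig(learning_rate=0).validate()


# -- forward contract -------------------------------------------------------


def test_output_is_probability_vector(rng):
    model = build_model(ModelConfig(**TINY, seed=4))
    pair = PatchPair(
        rng.standard_normal((24, 24)).astype(np.float32),
        rng.standard_normal((128, 128)).astype(np.float32),
    )
    proba = predict(model, pair)
    assert proba.shape == (2,)
    assert np.all(proba >= 0) and np.all(proba <= 1)
    assert proba.sum() == pytest.approx(1.0, abs=1e-6)


def test_batch_outputs_valid_and_duplicates_identical(rng):
    model = build_model(ModelConfig(**TINY, seed=4))
    local = rng.standard_normal((3, 24, 24)).astype(np.float32)
    context = rng.standard_normal((3, 128, 128)).astype(np.float32)
    local[2], context[2] = local[0], context[0]  # duplicate sample 0
    proba = model.predict_proba(local, context)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
    np.testing.assert_array_equal(proba[0], proba[2])


def test_shape_mismatch_rejected(rng):
    model = build_model(ModelConfig(**TINY, seed=4))
    with pytest.raises(FormatError):
        model.predict_proba(
            rng.standard_normal((1, 24, 25)), rng.standard_normal((1, 128, 128))
        )


# -- training ---------------------------------------------------------------


def test_training_deterministic_given_seed():
    ds = make_separable(16, seed=3)
    logs, sums = [], []
    for _ in range(2):
        model = build_model(ModelConfig(**TINY, seed=11))
        train(model, ds, seed=11)
        logs.append(tuple(model.loss_log))
        sums.append(model.weight_checksum())
    assert logs[0] == logs[1]
    assert sums[0] == sums[1]


def test_separable_patches_reach_perfect_training_accuracy():
    """20 linearly separable pairs (+3 sigma offset): the net must fit them."""
    ds = make_separable(20, offset=3.0, seed=1)
    cfg = ModelConfig(**{**TINY, "epochs": 30}, learning_rate=1e-3, seed=2)
    model = train(build_model(cfg), ds)
    proba = model.predict_proba(ds.local, ds.context)
    acc = (np.argmax(proba, axis=1) == ds.labels).mean()
    assert acc == 1.0
    assert model.loss_log[-1] < model.loss_log[0]
    assert np.isfinite(model.loss_log).all()


def test_single_class_dataset_rejected():
    ds = make_separable(8)
    one = ds.subset(np.flatnonzero(ds.labels == 1))
    model = build_model(ModelConfig(**TINY, seed=0))
    with pytest.raises(DataError):
        train(model, one)
    with pytest.raises(DataError):
        train(model, ds.subset([]))


# -- pre-training -----------------------------------------------------------


def test_pretrain_off_is_identity():
    model = build_model(ModelConfig(**TINY, pretrain=False, seed=6))
    before = model.weight_checksum()
    pretrain_extractors(model)
    assert model.weight_checksum() == before


def test_pretrain_deterministic_and_changes_branches():
    images, labels = generate_texture_images(24, seed=5)
    sums = []
    for _ in range(2):
        cfg = ModelConfig(**{**TINY, "epochs": 1}, pretrain=True,
                          pretrain_epochs=1, seed=6)
        model = build_model(cfg)
        init = model.weight_checksum()
        pretrain_extractors(model, images, labels)
        assert model.weight_checksum() != init
        sums.append(model.weight_checksum())
    assert sums[0] == sums[1]


def test_pretrain_empty_image_set_rejected():
    cfg = ModelConfig(**TINY, pretrain=True, seed=6)
    model = build_model(cfg)
    with pytest.raises(DataError):
        pretrain_extractors(model, np.empty((0, 32, 32)), np.empty(0, dtype=int))


# -- persistence ------------------------------------------------------------


def test_patch_dataset_cache_round_trip(tmp_path):
    ds = make_separable(10, seed=2)
    ds.save(tmp_path / "cache")
    back = PatchDataset.load(tmp_path / "cache")
    np.testing.assert_array_equal(back.local, ds.local)
    np.testing.assert_array_equal(back.context, ds.context)
    np.testing.assert_array_equal(back.labels, ds.labels)
    assert back.subject_ids == ds.subject_ids


def test_checkpoint_round_trip(tmp_path, rng):
    ds = make_separable(12, seed=9)
    model = train(build_model(ModelConfig(**TINY, seed=7)), ds)
    model.save(tmp_path / "model")
    clone = DualPatchCNN.load(tmp_path / "model")
    assert clone.weight_checksum() == model.weight_checksum()
    np.testing.assert_array_equal(
        clone.predict_proba(ds.local[:3], ds.context[:3]),
        model.predict_proba(ds.local[:3], ds.context[:3]),
    )
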