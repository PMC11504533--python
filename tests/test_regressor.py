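"""End-to-end model: prediction contracts, training, checkpoints."""

import numpy as np
import pytest

from limbfuse.nn import Tensor
from limbfuse.regressor import (JointAngleModel, TrainConfig, load_checkpoint,
                                predict_sequence, predict_dataset,
                                save_checkpoint, train_full)
from limbfuse.vision_net import VisionSpec

FAST = dict(epochs=2, seq_len=10, seq_stride=10, batch_size=4)


@pytest.fixture(scope="module")
def small_model():
    return JointAngleModel(vision_spec=VisionSpec(resolution=(32, 32)),
                           seed=0)


def test_predict_sequence_matches_input_length(rng, small_model):
    seq = [rng.normal(size=small_model.fusion_spec.fused_dim)
           for _ in range(7)]
    out = predict_sequence(seq, small_model)
    assert len(out) == 7
    for s in out:
        assert np.isfinite(s.as_array()).all()


def test_empty_sequence_rejected(small_model):
    with pytest.raises(ValueError):
        predict_sequence([], small_model)


def test_zero_head_with_bias_gives_constant_output(rng):
    model = JointAngleModel(seed=1)
    model.head.weight.data[...] = 0.0
    model.head.bias.data[...] = [10.0, 20.0, -5.0]
    seq = [rng.normal(size=model.fusion_spec.fused_dim) for _ in range(5)]
    out = predict_sequence(seq, model)
    for s in out:
        np.testing.assert_allclose(s.as_array(), [10.0, 20.0, -5.0],
                                   atol=1e-5)


def test_prediction_is_deterministic(rng, small_model):
    seq = [rng.normal(size=small_model.fusion_spec.fused_dim)
           for _ in range(5)]
    a = np.stack([s.as_array() for s in predict_sequence(seq, small_model)])
    b = np.stack([s.as_array() for s in predict_sequence(seq, small_model)])
    np.testing.assert_array_equal(a, b)


def test_training_history_is_deterministic(small_dataset):
    cfg = TrainConfig(seed=5, **FAST)
    _, h1 = train_full(small_dataset, cfg)
    _, h2 = train_full(small_dataset, cfg)
    assert h1["train_loss"] == h2["train_loss"]
    assert h1["val_loss"] == h2["val_loss"]


def test_one_step_updates_all_four_submodules(small_dataset):
    cfg = TrainConfig(seed=6, epochs=1, seq_len=10, seq_stride=10,
                      batch_size=4)
    model = JointAngleModel(vision_spec=VisionSpec(resolution=(32, 32)),
                            seed=6)
    before = {name: p.data.copy() for name, p in model.named_parameters()}
    model, _ = train_full(small_dataset, cfg, model=model)
    changed = {"autoencoder": False, "vision": False, "fusion": False,
               "lstm": False}
    for name, p in model.named_parameters():
        for part in changed:
            if name.startswith(part) and not np.array_equal(before[name],
                                                            p.data):
                changed[part] = True
    assert changed["autoencoder"] and changed["vision"]
    assert changed["fusion"] and changed["lstm"]


def test_semg_mode_ignores_depth_frames(small_dataset):
    cfg = TrainConfig(seed=7, modality="semg", **FAST)
    model, _ = train_full(small_dataset, cfg)
    sl = np.arange(0, 10)
    windows = tuple(w[sl][None] for w in (small_dataset.windows_full,
                                          small_dataset.windows_mid,
                                          small_dataset.windows_short))
    frames = small_dataset.frames[sl][None]
    a = model.predict_arrays(windows, frames)
    b = model.predict_arrays(windows, frames + 500.0)  # perturb depth
    np.testing.assert_array_equal(a, b)


def test_vision_mode_ignores_emg_windows(small_dataset):
    cfg = TrainConfig(seed=8, modality="vision", **FAST)
    model, _ = train_full(small_dataset, cfg)
    sl = np.arange(0, 10)
    windows = tuple(w[sl][None] for w in (small_dataset.windows_full,
                                          small_dataset.windows_mid,
                                          small_dataset.windows_short))
    perturbed = tuple(w + 1.0 for w in windows)
    frames = small_dataset.frames[sl][None]
    a = model.predict_arrays(windows, frames)
    b = model.predict_arrays(perturbed, frames)
    np.testing.assert_array_equal(a, b)


def test_vision_mode_has_no_reconstruction_term(small_dataset):
    model = JointAngleModel(modality="vision", seed=9)
    sl = np.arange(0, 4)
    windows = tuple(w[sl][None] for w in (small_dataset.windows_full,
                                          small_dataset.windows_mid,
                                          small_dataset.windows_short))
    # frames at the model's configured 64x64 are required; use zeros
    frames = np.zeros((1, 4, 64, 64), np.float32)
    _, recon = model.fused_sequence(windows, frames)
    assert recon is None


def test_training_smoke_reduces_validation_loss(small_dataset):
    cfg = TrainConfig(seed=10, epochs=6, seq_len=10, seq_stride=10,
                      batch_size=4)
    _, hist = train_full(small_dataset, cfg)
    assert min(hist["val_loss"]) < hist["val_loss"][0]


def test_two_stage_training_with_autoencoder_pretraining(small_dataset):
    cfg = TrainConfig(seed=12, pretrain_ae_epochs=1, **FAST)
    model, hist = train_full(small_dataset, cfg)
    assert len(hist["train_loss"]) == cfg.epochs
    pred = predict_dataset(model, small_dataset, seq_len=10)
    assert np.isfinite(pred).all()


def test_dataset_smaller_than_one_sequence_rejected(small_dataset):
    with pytest.raises(ValueError):
        train_full(small_dataset, TrainConfig(seq_len=10 ** 6))


def test_checkpoint_round_trip_is_bitwise(small_dataset, tmp_path):
    cfg = TrainConfig(seed=11, **FAST)
    model, _ = train_full(small_dataset, cfg)
    pred_before = predict_dataset(model, small_dataset, seq_len=10)
    p = tmp_path / "model.ckpt.npz"
    save_checkpoint(model, p)
    back = load_checkpoint(p)
    for (na, a), (nb, b) in zip(sorted(model.named_parameters()),
                                sorted(back.named_parameters())):
        assert na == nb
        np.testing.assert_array_equal(a.data, b.data)
    pred_after = predict_dataset(back, small_dataset, seq_len=10)
    np.testing.assert_array_equal(pred_before, pred_after)


def test_invalid_train_config_rejected():
    with pytest.raises(ValueError):
        TrainConfig(val_frac=1.5)
    with pytest.raises(ValueError):
        TrainConfig(lambda_recon=-1.0)
    with pytest.raises(ValueError):
        TrainConfig(modality="audio")
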