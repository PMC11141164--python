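"""Training loop behavior, evaluation flow and the prediction round trip."""

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from datransunet import (TrainConfig, build_model, evaluate, load_checkpoint,
                         predict, predict_mask, save_checkpoint, synapse_preset,
                         tiny_config, train)


def test_tiny_model_overfits_the_phantoms(overfit_run):
    """Capacity check: the tiny network memorizes 8 binary phantoms to
    train-set Dice >= 0.95 well within the 200-epoch budget."""
    _, history, _ = overfit_run
    assert len(history) <= 200
    assert history["val_dice"].iloc[-1] >= 0.95


def test_loss_is_finite_and_decreasing_early(overfit_run):
    _, history, _ = overfit_run
    losses = history["train_loss"].to_numpy()
    assert np.isfinite(losses).all()
    assert losses[4] < losses[0]


def test_same_seed_reproduces_epoch_one_loss(overfit_phantoms):
    cfg = TrainConfig(network=tiny_config(n_classes=1), epochs=1, val_fraction=0.0,
                      seed=12)
    _, h1 = train(cfg, overfit_phantoms)
    _, h2 = train(cfg, overfit_phantoms)
    assert h1["train_loss"].iloc[0] == h2["train_loss"].iloc[0]


def test_nonfinite_loss_aborts_with_diagnostic(overfit_phantoms):
    cfg = TrainConfig(network=tiny_config(n_classes=1), optimizer="sgd", lr=1e12,
                      epochs=3, val_fraction=0.0, seed=0)
    with pytest.raises(RuntimeError, match="non-finite"):
        train(cfg, overfit_phantoms)


def test_evaluating_against_own_predictions_is_perfect(overfit_run):
    model, _, data = overfit_run
    self_truth = [(img, predict_mask(model, img)) for img, _ in data[:4]]
    frame, summary = evaluate(model, self_truth)
    assert summary["mean_dice"] == 1.0
    assert summary["mean_iou"] == 1.0
    assert summary["mean_hd"] == 0.0


def test_constant_background_predictor_scores_zero_and_is_flagged(overfit_phantoms):
    model = build_model(tiny_config(n_classes=1), seed=0)
    model.seg_head.bias.data[:] = -50.0      # sigmoid ~ 0 everywhere
    frame, summary = evaluate(model, overfit_phantoms[:4])
    assert summary["mean_dice"] == 0.0
    assert summary["n_empty_predictions"] == 4
    assert frame["pred_empty"].all()


def test_report_means_match_the_emitted_csv(overfit_run, tmp_path):
    model, _, data = overfit_run
    frame, summary = evaluate(model, data, output_dir=tmp_path)
    disk = pd.read_csv(tmp_path / "metrics.csv")
    assert summary["mean_dice"] == pytest.approx(disk["dice"].mean())
    assert summary["mean_iou"] == pytest.approx(disk["iou"].mean())
    assert (tmp_path / "summary.json").exists()


def test_evaluation_is_deterministic_across_checkpoint_reload(overfit_run, tmp_path):
    model, _, data = overfit_run
    save_checkpoint(model, tmp_path / "m.npz")
    f1, s1 = evaluate(model, data[:4])
    f2, s2 = evaluate(tmp_path / "m.npz", data[:4])
    pd.testing.assert_frame_equal(f1, f2)
    assert s1 == s2


def test_predict_round_trip_recovers_the_phantom_mask(overfit_run, tmp_path):
    model, _, data = overfit_run
    save_checkpoint(model, tmp_path / "m.npz")
    image, mask = data[0]
    img8 = np.round(image * 255).astype(np.uint8)
    Image.fromarray(img8, mode="L").save(tmp_path / "img.png")
    pred = predict(tmp_path / "m.npz", tmp_path / "img.png", tmp_path / "mask.png")
    assert set(np.unique(pred)) <= {0, 1}
    inter = np.logical_and(pred, mask).sum()
    dice = 2 * inter / (pred.sum() + mask.sum())
    assert dice >= 0.95
    on_disk = np.asarray(Image.open(tmp_path / "mask.png"))
    np.testing.assert_array_equal(on_disk, pred)


def test_predict_size_checking_and_resize(overfit_run, tmp_path):
    model, _, _ = overfit_run
    save_checkpoint(model, tmp_path / "m.npz")
    Image.fromarray(np.zeros((40, 40), np.uint8)).save(tmp_path / "small.png")
    with pytest.raises(ValueError, match="resize"):
        predict(tmp_path / "m.npz", tmp_path / "small.png", tmp_path / "out.png")
    pred = predict(tmp_path / "m.npz", tmp_path / "small.png", tmp_path / "out.png",
                   resize=True)
    assert pred.shape == (64, 64)


def test_presets_follow_the_published_protocol():
    default = TrainConfig()
    assert (default.optimizer, default.lr, default.momentum,
            default.weight_decay) == ("adam", 1e-3, 0.9, 1e-4)
    synapse = synapse_preset(tiny_config(n_classes=9))
    assert (synapse.optimizer, synapse.lr, synapse.momentum,
            synapse.weight_decay, synapse.batch_size) == ("sgd", 0.01, 0.9, 1e-4, 24)


def test_multiclass_training_one_epoch_runs():
    from datransunet import PhantomSpec, make_multiclass_phantoms
    data = make_multiclass_phantoms(
        PhantomSpec(n_images=4, img_size=32, mode="multiclass", n_classes=3,
                    blob_radius=(0.1, 0.18), seed=6))
    cfg = TrainConfig(network=tiny_config(img_size=32, n_classes=3), loss="ce_dice",
                      epochs=1, val_fraction=0.0, seed=1)
    _, history = train(cfg, data)
    assert np.isfinite(history["train_loss"]).all()
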