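"""Training loop contracts, fusion head, and the attention-free ablation."""

from __future__ import annotations

import numpy as np
import pytest

from _helpers import TINY, tiny_dataset, tiny_model

from msa3d import TrainConfig, train
from msa3d.nn import Tensor, no_grad


class TestTrain:
    def test_learnability_smoke(self):
        """Easy separable phantoms: training reduces the loss."""
        model, hist = train(tiny_dataset(), model=tiny_model(),
                            train_cfg=TrainConfig(seed=1, max_epochs=5,
                                                  batch_size=6))
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_same_seed_reproducible_history(self):
        runs = []
        for _ in range(2):
            model, hist = train(tiny_dataset(), model=tiny_model(3),
                                train_cfg=TrainConfig(seed=7, max_epochs=3,
                                                      batch_size=6))
            runs.append((hist.train_loss, hist.val_loss))
        assert runs[0] == runs[1]

    def test_early_stopping_halts_before_max_epochs(self):
        """With an infinitesimal step, validation never improves and the
        patience rule stops training."""
        cfg = TrainConfig(seed=2, max_epochs=30, patience=3, batch_size=6,
                          learning_rate=1e-30)
        model, hist = train(tiny_dataset(), model=tiny_model(1), train_cfg=cfg)
        assert hist.stopped_early
        assert len(hist.train_loss) < 30

    def test_best_weights_restored(self):
        model, hist = train(tiny_dataset(), model=tiny_model(2),
                            train_cfg=TrainConfig(seed=5, max_epochs=4,
                                                  batch_size=6))
        assert 0 <= hist.best_epoch < len(hist.val_loss)
        assert hist.val_loss[hist.best_epoch] == min(hist.val_loss)

    def test_single_class_rejected(self):
        x = np.zeros((6, *TINY), dtype=np.float32)
        y = np.zeros(6, dtype=int)
        with pytest.raises(ValueError):
            train((x, y), model=tiny_model())


class TestFusionHead:
    def test_probabilities_normalised(self):
        model = tiny_model()
        probs = model.fuse_and_classify(
            np.random.default_rng(0).random(model.slice_feature_dim),
            np.random.default_rng(1).random(32))
        assert probs.shape == (2,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert (probs > 0).all()

    def test_zero_weight_head_uniform(self):
        model = tiny_model()
        for layer in (model.fc1, model.fc2):
            layer.weight.data[:] = 0
            layer.bias.data[:] = 0
        probs = model.fuse_and_classify(np.ones(model.slice_feature_dim),
                                        np.ones(32))
        np.testing.assert_allclose(probs, 0.5, atol=1e-7)

    def test_softmax_shift_invariance(self):
        """A constant added to all logits (via fc2 bias) changes nothing."""
        model = tiny_model()
        x = np.random.default_rng(2).random((1, *TINY)).astype(np.float32)
        before = model.predict_proba(x)
        model.fc2.bias.data += 7.5
        np.testing.assert_allclose(model.predict_proba(x), before, atol=1e-5)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            tiny_model().fuse_and_classify(np.ones(10), np.ones(3))


class TestAblationIdentity:
    def test_ms3d_equals_msa3d_at_zero_gate(self):
        """With beta frozen at 0, removing the attention module changes no
        logit bit: the attended model starts exactly as its ablation."""
        msa = tiny_model(seed=42, use_sam=True)
        ms3d = tiny_model(seed=42, use_sam=False)
        ms3d.load_state_dict(msa.state_dict())
        rng = np.random.default_rng(0)
        msa.eval(), ms3d.eval()
        for _ in range(10):
            x = Tensor(rng.standard_normal((1, *TINY)).astype(np.float32))
            with no_grad():
                a = msa(x).data
                b = ms3d(x).data
            np.testing.assert_array_equal(a, b)

    def test_trained_gate_breaks_identity(self):
        msa = tiny_model(seed=42, use_sam=True)
        ms3d = tiny_model(seed=42, use_sam=False)
        ms3d.load_state_dict(msa.state_dict())
        for key in "xyz":
            msa._view_banks()[key][1].beta.data[:] = 0.5
        x = Tensor(np.random.default_rng(1)
                   .standard_normal((1, *TINY)).astype(np.float32))
        msa.eval(), ms3d.eval()
        with no_grad():
            assert not np.array_equal(msa(x).data, ms3d(x).data)


def test_checkpoint_round_trip(tmp_path):
    from msa3d import load_checkpoint, save_checkpoint
    model = tiny_model(seed=9)
    p = tmp_path / "model.npz"
    save_checkpoint(model, p, meta={"epoch": 3})
    clone = tiny_model(seed=10)
    meta = load_checkpoint(clone, p)
    assert meta == {"epoch": 3}
    x = np.random.default_rng(3).random((2, *TINY)).astype(np.float32)
    np.testing.assert_array_equal(model.predict_proba(x),
                                  clone.predict_proba(x))
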