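import numpy as np
import pytest

from lvquant import geometry, nn
from lvquant.geometry import IndexVector
from lvquant.phantom import PhantomSpec, render_subject
from lvquant.reg_path import RegConfig
from lvquant.seg_path import SegConfig
from lvquant.trainer import (TrainConfig, UnifiedModel,
                             build_training_windows, decode_cyclic_phase,
                             load_checkpoint, make_folds, predict_subject,
                             save_checkpoint, train, train_step,
                             _batch_arrays)

SIZE = 48


def small_model(seed=0, size=SIZE):
    return UnifiedModel(SegConfig.small(size), RegConfig.small(),
                        init_rng=np.random.default_rng(seed))


def tiny_subject(seed=0):
    spec = PhantomSpec(image_size=SIZE, r_endo_ed=11.0, r_endo_es=8.0,
                       wall_ed=np.full(6, 5.0), wall_es=np.full(6, 6.5),
                       noise_sigma=0.02)
    return render_subject(spec)


def tiny_config(**kw):
    kw.setdefault("epochs", 1)
    kw.setdefault("steps_per_epoch", 1)
    cfg = TrainConfig.small(**{k: kw.pop(k) for k in ("epochs", "steps_per_epoch")})
    for k, v in kw.items():
        setattr(cfg, k, v)
    return cfg


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(folds=1)
        with pytest.raises(ValueError):
            TrainConfig(seg_lr=0.0)
        with pytest.raises(ValueError):
            TrainConfig(seg_lr_decay=0.0)

    def test_reference_protocol_defaults(self):
        cfg = TrainConfig()
        assert (cfg.epochs, cfg.batch_size, cfg.folds) == (500, 20, 5)
        assert cfg.seg_lr == cfg.reg_lr == 5e-4
        assert cfg.reg_momentum == 0.06 and cfg.reg_weight_decay == 5e-3
        assert cfg.seg_lr_decay == 0.99


class TestModel:
    def test_forward_triple(self):
        m = small_model()
        m.eval()
        x = np.random.default_rng(1).standard_normal(
            (2, 1, 5, SIZE, SIZE)).astype(np.float32)
        from lvquant.autodiff import Tensor, no_grad
        with no_grad():
            logits, idx, ph = m(Tensor(x))
        assert logits.shape == (2, 3, 5, SIZE, SIZE)
        assert idx.shape == (2, 11) and ph.shape == (2, 2)

    def test_parameter_groups_disjoint_and_complete(self):
        m = small_model()
        seg = {id(p) for p in m.seg_parameters()}
        reg = {id(p) for p in m.reg_parameters()}
        assert not seg & reg
        assert seg | reg == {id(p) for p in m.parameters()}
        # the SE-fusion blocks belong to the regression group
        assert {id(p) for p in m.reg.fuse1.parameters()} <= reg

    def test_standardization_roundtrip(self, rng):
        m = small_model()
        y = rng.uniform(0.1, 0.5, (6, 11))
        m.set_index_norm(y.mean(axis=0), y.std(axis=0) + 0.01)
        np.testing.assert_allclose(
            m.destandardize_indices(m.standardize_targets(y)), y, atol=1e-12)

    def test_index_norm_validation(self):
        m = small_model()
        with pytest.raises(ValueError):
            m.set_index_norm(np.zeros(5), np.ones(5))
        with pytest.raises(ValueError):
            m.set_index_norm(np.zeros(11), np.zeros(11))

    def test_norm_buffers_in_state_dict(self, rng):
        m = small_model()
        m.set_index_norm(rng.uniform(0, 1, 11), rng.uniform(0.1, 1, 11))
        m2 = small_model(seed=5)
        m2.load_state_dict(m.state_dict())
        np.testing.assert_array_equal(m2.index_mean, m.index_mean)
        np.testing.assert_array_equal(m2.index_std, m.index_std)


class TestDataPlumbing:
    def test_build_training_windows(self):
        s = tiny_subject()
        ws = build_training_windows(s, apply_clahe=False)
        assert len(ws) == 20
        assert ws[0].frames.shape == (5, SIZE, SIZE)
        assert isinstance(ws[3].target, IndexVector)

    def test_batch_arrays_layout(self):
        ws = build_training_windows(tiny_subject(), apply_clahe=False)[:4]
        x, y_seg, y_idx, y_phase = _batch_arrays(ws)
        assert x.shape == (4, 1, 5, SIZE, SIZE) and x.dtype == nn.DTYPE
        assert y_seg.shape == (4, 3, 5, SIZE, SIZE)
        np.testing.assert_allclose(y_seg.sum(axis=1), 1.0)
        assert y_idx.shape == (4, 11) and y_phase.shape == (4,)

    def test_make_folds_partition(self):
        folds = make_folds(145, 5, np.random.default_rng(0))
        assert len(folds) == 5
        all_test = np.concatenate([t for _, t in folds])
        assert sorted(all_test) == list(range(145))
        for train_idx, test_idx in folds:
            assert len(test_idx) == 29
            assert not set(train_idx) & set(test_idx)
            assert len(set(train_idx) | set(test_idx)) == 145

    def test_make_folds_validation(self):
        with pytest.raises(ValueError):
            make_folds(3, 4, np.random.default_rng(0))


class TestTraining:
    def test_zero_lr_leaves_model_unchanged(self):
        m = small_model()
        ws = build_training_windows(tiny_subject(), apply_clahe=False)
        cfg = tiny_config(seg_lr=1e-30, reg_lr=1e-30, batch_size=4,
                          reg_weight_decay=0.0, seg_weight_decay=0.0)
        before = {k: p.data.copy() for k, p in m.named_parameters()}
        train(m, ws, cfg)
        for k, p in m.named_parameters():
            np.testing.assert_allclose(p.data, before[k], atol=1e-7, err_msg=k)

    def test_one_epoch_updates_and_history(self):
        m = small_model()
        ws = build_training_windows(tiny_subject(), apply_clahe=False)
        cfg = tiny_config(epochs=2, batch_size=4)
        history, (opt_seg, _) = train(m, ws, cfg)
        assert [h["epoch"] for h in history] == [0, 1]
        assert all(np.isfinite(h["loss"]) for h in history)
        # per-epoch decay applied twice
        assert opt_seg.lr == pytest.approx(cfg.seg_lr * cfg.seg_lr_decay ** 2)

    def test_training_is_seeded_deterministic(self):
        losses = []
        for _ in range(2):
            m = small_model(seed=3)
            ws = build_training_windows(tiny_subject(), apply_clahe=False)
            cfg = tiny_config(epochs=2, batch_size=4)
            history, _ = train(m, ws, cfg, rng=np.random.default_rng(7))
            losses.append([h["loss"] for h in history])
        np.testing.assert_allclose(losses[0], losses[1], atol=1e-6)

    @pytest.mark.filterwarnings("ignore:overflow:RuntimeWarning")
    @pytest.mark.filterwarnings("ignore:invalid value:RuntimeWarning")
    def test_nonfinite_loss_raises(self):
        m = small_model()
        ws = build_training_windows(tiny_subject(), apply_clahe=False)[:2]
        for p in m.reg.head_lin.parameters():
            p.data = np.full_like(p.data, np.finfo(np.float32).max)
        with pytest.raises(FloatingPointError):
            train_step(m, _batch_arrays(ws), TrainConfig.small().loss_weights)

    def test_checkpoint_resume_bit_equal(self, tmp_path):
        ws = build_training_windows(tiny_subject(), apply_clahe=False)
        cfg = tiny_config(epochs=3, batch_size=4)

        # uninterrupted 3-epoch run
        m_full = small_model(seed=9)
        hist_full, _ = train(m_full, ws, cfg, rng=np.random.default_rng(11))

        # 2 epochs, checkpoint, resume for the third
        m = small_model(seed=9)
        rng = np.random.default_rng(11)
        cfg2 = tiny_config(epochs=2, batch_size=4)
        hist_a, opts = train(m, ws, cfg2, rng=rng)
        save_checkpoint(tmp_path / "c.ckpt", m, opts, 2, rng, cfg, hist_a)

        m2 = small_model(seed=1234)   # different init, fully overwritten
        opts2, epoch, rng2, hist_b = load_checkpoint(tmp_path / "c.ckpt", m2, cfg)
        hist_c, _ = train(m2, ws, cfg, optimizers=opts2, start_epoch=epoch,
                          rng=rng2)
        got = [h["loss"] for h in hist_b + hist_c]
        want = [h["loss"] for h in hist_full]
        np.testing.assert_allclose(got, want, atol=1e-6)
        for (k, p), (_, q) in zip(m_full.named_parameters(),
                                  m2.named_parameters()):
            np.testing.assert_allclose(p.data, q.data, atol=1e-6, err_msg=k)


class TestInference:
    def test_predict_subject_shapes(self):
        m = small_model()
        s = tiny_subject()
        masks, idx, phase = predict_subject(m, s.images, apply_clahe=False)
        assert masks.shape == (20, SIZE, SIZE)
        assert set(np.unique(masks)) <= {0, 1, 2}
        assert idx.shape == (20, 11)
        assert phase.shape == (20,) and set(np.unique(phase)) <= {0, 1}

    def test_predictions_destandardized(self):
        m = small_model()
        mean = np.full(11, 100.0)
        m.set_index_norm(mean, np.ones(11))
        s = tiny_subject()
        _, idx, _ = predict_subject(m, s.images, apply_clahe=False)
        # raw head outputs are near zero at init; the offset must show up
        assert idx.mean() > 50.0

    def test_invalid_readout_rejected(self):
        with pytest.raises(ValueError):
            predict_subject(small_model(), tiny_subject().images,
                            readout="bogus")

    def test_unified_readout_contract(self):
        # every frame is either measured geometrically from the returned
        # mask or falls back to the regression head's prediction
        m = small_model()
        s = tiny_subject()
        masks, idx_u, _ = predict_subject(m, s.images, apply_clahe=False,
                                          readout="unified")
        _, idx_h, _ = predict_subject(m, s.images, apply_clahe=False)
        for t in range(masks.shape[0]):
            if np.allclose(idx_u[t], idx_h[t]):
                continue
            geo = geometry.indices_from_mask(masks[t:t + 1])[0].to_array()
            np.testing.assert_allclose(idx_u[t], geo, atol=1e-12)

    def test_phase_is_single_cyclic_run(self):
        # both the unified readout and the smoothed head readout impose
        # exactly one cyclic systolic run
        m = small_model()
        s = tiny_subject()
        for kw in ({"readout": "unified"}, {"smooth_phase": True}):
            _, _, phase = predict_subject(m, s.images, apply_clahe=False, **kw)
            flips = np.sum(phase != np.roll(phase, 1))
            assert flips == 2, kw


class TestDecodeCyclicPhase:
    def test_recovers_clean_run(self):
        truth = np.array([0, 0, 1, 1, 1, 0, 0, 0])
        probs = np.where(truth == 1, 0.9, 0.1)
        assert np.array_equal(decode_cyclic_phase(probs), truth)

    def test_recovers_wraparound_run(self):
        truth = np.array([1, 1, 0, 0, 0, 0, 1, 1])
        probs = np.where(truth == 1, 0.8, 0.2)
        assert np.array_equal(decode_cyclic_phase(probs), truth)

    def test_fixes_isolated_flip(self):
        truth = np.array([0, 0, 1, 1, 1, 1, 0, 0, 0, 0])
        probs = np.where(truth == 1, 0.9, 0.1)
        probs[4] = 0.3    # one noisy systolic frame must be overridden
        assert np.array_equal(decode_cyclic_phase(probs), truth)

    def test_never_all_one_label(self):
        for probs in (np.full(6, 0.99), np.full(6, 0.01)):
            labels = decode_cyclic_phase(probs)
            assert 0 < labels.sum() < labels.size

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            decode_cyclic_phase(np.array([0.2, 0.8]))
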