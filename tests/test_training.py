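"""Learning-rate policy, parameter groups, and small training runs."""

import numpy as np
import pytest

from bladderseg.networks import (NetConfig, ReconstructionNet, SegmentationNet,
                                 load_checkpoint, transfer_weights)
from bladderseg.phantoms import PhantomConfig, generate_phantom
from bladderseg.training import (LRPolicy, TrainConfig, beta_for_n,
                                 build_param_groups, pretrain,
                                 train_semisupervised)


class TestBetaPolicy:
    @pytest.mark.parametrize("n,beta", [(42, 0.02), (21, 0.2), (12, 2.0),
                                        (4, 10.0), (1, 20.0)])
    def test_tabulated_points_exact(self, n, beta):
        assert beta_for_n(n) == pytest.approx(beta, rel=1e-12)

    def test_clamped_beyond_table(self):
        assert beta_for_n(100) == pytest.approx(0.02)
        assert beta_for_n(1) == pytest.approx(20.0)

    def test_log_linear_between_points(self):
        # halfway in log n between 4 and 12 -> halfway in log beta
        n = int(round(np.sqrt(4 * 12)))
        b = beta_for_n(7)
        expected = np.exp(np.interp(np.log(7), [np.log(4), np.log(12)],
                                    [np.log(10.0), np.log(2.0)]))
        assert b == pytest.approx(expected, rel=1e-9)

    def test_monotone_non_increasing_on_full_range(self):
        betas = [beta_for_n(n) for n in range(1, 43)]
        assert all(b1 >= b2 - 1e-12 for b1, b2 in zip(betas, betas[1:]))

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            beta_for_n(0)


class TestParamGroups:
    def test_two_groups_partition_parameters(self, tiny_net_config):
        pre = ReconstructionNet(tiny_net_config, seed=0)
        seg = SegmentationNet(tiny_net_config, seed=1)
        report = transfer_weights(pre, seg)
        policy = LRPolicy(lr1=1e-4, n_labeled=42)
        groups = build_param_groups(seg, policy, report)
        assert len(groups) == 2
        ids = [id(p) for g in groups for p in g["params"]]
        assert len(ids) == len(set(ids)) == len(seg.parameters())
        assert groups[0]["lr"] == pytest.approx(1e-4)
        assert groups[1]["lr"] == pytest.approx(2e-6)  # beta(42) = 0.02

    def test_single_label_regime_boosts_random_layers(self, tiny_net_config):
        seg = SegmentationNet(tiny_net_config, seed=1)
        pre = ReconstructionNet(tiny_net_config, seed=0)
        report = transfer_weights(pre, seg)
        groups = build_param_groups(seg, LRPolicy(lr1=1e-4, n_labeled=1), report)
        assert groups[1]["lr"] == pytest.approx(20e-4)

    def test_missing_parameter_in_report_rejected(self, tiny_net_config):
        seg = SegmentationNet(tiny_net_config, seed=1)
        with pytest.raises(KeyError, match="missing"):
            build_param_groups(seg, LRPolicy(), {"bogus": "transferred"})

    def test_scratch_training_uses_single_group(self, tiny_net_config):
        seg = SegmentationNet(tiny_net_config, seed=1)
        groups = build_param_groups(seg, LRPolicy(lr1=3e-4), None)
        assert len(groups) == 1 and groups[0]["lr"] == pytest.approx(3e-4)


@pytest.fixture(scope="module")
def tiny_images():
    cfg = PhantomConfig(image_size=48, tumor_radius_range=(4, 7))
    return [generate_phantom(cfg, seed=s) for s in range(10)]


def tiny_train_config(**kw):
    base = dict(stage="pretrain", optimizer="adam", lr=1e-3, epochs=4,
                batch_size=4, seed=0, crop_size=32)
    base.update(kw)
    from bladderseg.patching import MaskConfig
    cfg = TrainConfig(**base)
    cfg.mask = MaskConfig(holes_min=2, holes_max=4, side_min=6, side_max=10)
    return cfg


class TestPretrain:
    def test_loss_decreases_and_history_shape(self, tiny_images, tiny_net_config):
        net = ReconstructionNet(tiny_net_config, seed=0)
        images = [s.image for s in tiny_images]
        net, hist = pretrain(images, net, tiny_train_config(epochs=6))
        assert list(hist.columns) == ["epoch", "train_loss", "val_loss"]
        assert len(hist) == 6
        assert hist.train_loss.iloc[-1] <= hist.train_loss.iloc[0]

    def test_empty_dataset_rejected(self, tiny_net_config):
        with pytest.raises(ValueError, match="at least one"):
            pretrain([], ReconstructionNet(tiny_net_config, seed=0),
                     tiny_train_config())

    def test_checkpoint_round_trip_same_val_loss(self, tiny_images,
                                                 tiny_net_config, tmp_path):
        from bladderseg.training import _pretrain_val_loss
        from bladderseg.patching import make_pretrain_pair, random_crop
        net = ReconstructionNet(tiny_net_config, seed=0)
        images = [s.image for s in tiny_images]
        cfg = tiny_train_config(epochs=2)
        ckpt = tmp_path / "pre.npz"
        net, _ = pretrain(images, net, cfg, out_ckpt=ckpt)
        loaded, extra = load_checkpoint(ckpt)
        assert extra["stage"] == "pretrain"
        pairs = [make_pretrain_pair(random_crop(im, 32, 1), cfg.mask, 2)
                 for im in images[:4]]
        assert _pretrain_val_loss(net, pairs) == pytest.approx(
            _pretrain_val_loss(loaded, pairs), rel=1e-6)

    def test_deterministic_given_seed(self, tiny_images, tiny_net_config):
        images = [s.image for s in tiny_images[:6]]
        runs = []
        for _ in range(2):
            net = ReconstructionNet(tiny_net_config, seed=0)
            _, hist = pretrain(images, net, tiny_train_config(epochs=2))
            runs.append(hist)
        np.testing.assert_allclose(runs[0].train_loss, runs[1].train_loss, rtol=1e-6)

    def test_zero_hole_config_reduces_to_plain_reconstruction(self, tiny_images,
                                                              tiny_net_config):
        from bladderseg.patching import MaskConfig
        images = [s.image for s in tiny_images[:4]]
        net = ReconstructionNet(tiny_net_config, seed=0)
        cfg = tiny_train_config(epochs=1)
        cfg.mask = MaskConfig(holes_min=0, holes_max=0)
        net, hist = pretrain(images, net, cfg)
        assert np.isfinite(hist.train_loss.iloc[0])


class TestTrainSemisupervised:
    def _data(self, tiny_images):
        labeled = [(s.image, s.label) for s in tiny_images[:5]]
        unlabeled = [s.image for s in tiny_images[5:]]
        return labeled, unlabeled

    def _config(self, **kw):
        base = dict(stage="segment", optimizer="adamw", lr=1e-3, epochs=3,
                    batch_size=4, seed=0)
        base.update(kw)
        return TrainConfig(**base)

    def test_runs_and_records_history(self, tiny_images, tiny_net_config):
        labeled, unlabeled = self._data(tiny_images)
        seg = SegmentationNet(tiny_net_config, seed=0)
        seg, hist = train_semisupervised(labeled, unlabeled, seg, self._config(),
                                         LRPolicy(n_labeled=len(labeled)))
        assert {"epoch", "dfl", "vae", "total", "val_dsc"} <= set(hist.columns)
        assert len(hist) == 3
        assert (hist.val_dsc >= 0).all() and (hist.val_dsc <= 1).all()

    def test_no_unlabeled_data_still_trains(self, tiny_images, tiny_net_config):
        labeled, _ = self._data(tiny_images)
        seg = SegmentationNet(tiny_net_config, seed=0)
        _, hist = train_semisupervised(labeled, [], seg, self._config(epochs=2),
                                       LRPolicy(n_labeled=len(labeled)))
        assert len(hist) == 2

    def test_no_labeled_data_rejected(self, tiny_images, tiny_net_config):
        seg = SegmentationNet(tiny_net_config, seed=0)
        with pytest.raises(ValueError, match="labeled"):
            train_semisupervised([], [s.image for s in tiny_images], seg,
                                 self._config(), LRPolicy())

    def test_deterministic_history(self, tiny_images, tiny_net_config):
        labeled, unlabeled = self._data(tiny_images)
        hists = []
        for _ in range(2):
            seg = SegmentationNet(tiny_net_config, seed=0)
            _, h = train_semisupervised(labeled, unlabeled, seg,
                                        self._config(epochs=2),
                                        LRPolicy(n_labeled=len(labeled)))
            hists.append(h)
        np.testing.assert_allclose(hists[0].total, hists[1].total, rtol=1e-5)

    def test_best_model_selected_by_validation_dsc(self, tiny_images,
                                                   tiny_net_config):
        from bladderseg.training import _val_dsc
        labeled, unlabeled = self._data(tiny_images)
        seg = SegmentationNet(tiny_net_config, seed=0)
        cfg = self._config(epochs=4)
        seg, hist = train_semisupervised(labeled, unlabeled, seg, cfg,
                                         LRPolicy(n_labeled=len(labeled)))
        # the returned network must reproduce the best recorded val DSC
        rng = np.random.default_rng(cfg.seed)
        order = rng.permutation(len(labeled))
        n_val = min(max(1, int(round(cfg.val_fraction * len(labeled)))),
                    len(labeled) - 1)
        val_set = [labeled[i] for i in order[:n_val]]
        assert _val_dsc(seg, val_set) == pytest.approx(hist.val_dsc.max(), abs=1e-6)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(val_fraction=0.0)
    with pytest.raises(ValueError):
        TrainConfig(stage="finetune")
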