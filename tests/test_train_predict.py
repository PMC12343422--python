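"""Training loop behaviour, sliding-window inference, cross-validation."""

import numpy as np
import pytest

from hepavol.synthetic.phantom import PhantomSpec, make_liver_phantom
from hepavol.unet.crossval import stratified_folds
from hepavol.unet.network import UNet3D, UNetConfig
from hepavol.unet.train import VesselSegmentationModel, predict

SMALL_CFG = dict(n_levels=3, base_channels=8, n_classes=5, group_norm_groups=4,
                 patch_size=(32, 32, 32), stride=(16, 16, 16))


def small_cases(n, seed0=50, noise=0.0):
    cases = {}
    for i in range(n):
        spec = PhantomSpec(grid_shape=(32, 32, 32), spacing_mm=(5.0, 5.0, 5.0),
                           liver_axes_mm=(60, 55, 58), spleen_axes_mm=(20, 15, 22),
                           noise_sigma=noise, bias_field_amplitude=0.0, seed=seed0 + i)
        img, labels, _ = make_liver_phantom(spec)
        cases[f"c{i}"] = (img, labels)
    return cases


class TestFit:
    def test_empty_cases_rejected(self):
        with pytest.raises(ValueError):
            VesselSegmentationModel({}, UNetConfig(**SMALL_CFG))

    def test_zero_learning_rate_constant_trace(self):
        cases = small_cases(1)
        cfg = UNetConfig(**SMALL_CFG, learning_rate=0.0, epochs=5, seed=0)
        trace = VesselSegmentationModel(cases, cfg).fit().loss_trace
        assert len(trace) == 5
        assert max(trace) - min(trace) < 1e-6

    def test_learning_beats_untrained_baseline(self):
        """On easy high-contrast phantoms the trained network's vessel
        Dice exceeds the untrained network's by a wide margin."""
        cases = small_cases(2)
        cfg = UNetConfig(**SMALL_CFG, epochs=400, seed=0)
        model = VesselSegmentationModel(cases, cfg)
        untrained = UNet3D(cfg)
        from hepavol.unet.train import SegmentationResults

        base = SegmentationResults(untrained, cfg, [], list(cases)).evaluate(cases)
        results = model.fit()
        trained = results.evaluate(cases)
        for cid in cases:
            assert trained[cid]["vessel_dice"] >= base[cid]["vessel_dice"] + 0.3
        assert results.loss_trace[-1] < results.loss_trace[0]

    def test_seeded_runs_identical(self):
        cases = small_cases(1)
        cfg = UNetConfig(**SMALL_CFG, epochs=3, seed=9)
        t1 = VesselSegmentationModel(cases, cfg).fit().loss_trace
        t2 = VesselSegmentationModel(cases, cfg).fit().loss_trace
        assert t1 == t2

    def test_checkpoint_round_trip(self, tmp_path):
        cases = small_cases(1)
        cfg = UNetConfig(**SMALL_CFG, epochs=2, seed=1)
        res = VesselSegmentationModel(cases, cfg).fit()
        res.save(tmp_path / "model.npz")
        reloaded = UNet3D.load(tmp_path / "model.npz")
        img = cases["c0"][0]
        np.testing.assert_array_equal(predict(reloaded, img), res.predict(img))


class TestPredict:
    def test_no_overlap_stitching_equality(self):
        """With stride = patch size on an exactly tiling volume, the
        stitched output equals per-patch argmax concatenation."""
        cfg = UNetConfig(n_levels=2, base_channels=4, n_classes=3, group_norm_groups=2,
                         patch_size=(16, 16, 16), stride=(16, 16, 16), seed=3)
        net = UNet3D(cfg)
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(32, 32, 32)).astype(np.float32)
        stitched = predict(net, vol)
        from hepavol.unet.network import softmax
        from hepavol.unet.train import normalize_volume

        norm = normalize_volume(vol)
        manual = np.zeros((32, 32, 32), dtype=np.uint8)
        for o in np.ndindex(2, 2, 2):
            sl = tuple(slice(16 * i, 16 * i + 16) for i in o)
            manual[sl] = softmax(net.forward(norm[sl])).argmax(axis=0)
        np.testing.assert_array_equal(stitched, manual)

    def test_output_congruent_and_labels_in_range(self):
        cfg = UNetConfig(n_levels=2, base_channels=4, n_classes=3, group_norm_groups=2,
                         patch_size=(16, 16, 16), stride=(8, 8, 8), seed=4)
        net = UNet3D(cfg)
        vol = np.random.default_rng(1).normal(size=(20, 24, 18)).astype(np.float32)
        pred = predict(net, vol)
        assert pred.shape == vol.shape
        assert set(np.unique(pred)) <= {0, 1, 2}

    def test_constant_bias_network_single_class(self):
        cfg = UNetConfig(n_levels=2, base_channels=4, n_classes=3, group_norm_groups=2,
                         patch_size=(16, 16, 16), stride=(16, 16, 16), seed=5)
        net = UNet3D(cfg)
        for _, value, _ in net.params():
            value[...] = 0.0
        net.final.b[:] = np.array([0.0, 5.0, 0.0])
        pred = predict(net, np.zeros((16, 16, 16), dtype=np.float32))
        assert (pred == 1).all()


class TestCrossValidation:
    def test_every_case_tested_once_with_dice_reported(self):
        from hepavol.unet.crossval import crossvalidate

        cases = small_cases(4)
        groups = {cid: ("a" if i % 2 else "b") for i, cid in enumerate(cases)}
        cfg = UNetConfig(n_levels=2, base_channels=4, n_classes=5, group_norm_groups=2,
                         patch_size=(16, 16, 16), stride=(16, 16, 16), epochs=2, seed=0)
        reports = crossvalidate(cases, k=2, group_labels=groups, seed=1, config=cfg)
        tested = [cid for r in reports for cid in r.test_ids]
        assert sorted(tested) == sorted(cases)
        for r in reports:
            assert set(r.train_ids).isdisjoint(r.test_ids)
            for scores in r.per_case_dice.values():
                assert {"vessel_dice", "portal_dice", "hepatic_dice"} <= set(scores)


class TestStratifiedFolds:
    def test_partition_property(self):
        ids = [f"s{i}" for i in range(24)]
        groups = {cid: ["ctrl", "non", "acld"][i % 3] for i, cid in enumerate(ids)}
        folds = stratified_folds(ids, groups, k=3, seed=0)
        seen = [cid for fold in folds for cid in fold]
        assert sorted(seen) == sorted(ids)  # every case in exactly one fold

    def test_stratification_balances_groups(self):
        ids = [f"s{i}" for i in range(24)]
        groups = {cid: "a" if i < 6 else ("b" if i < 18 else "c") for i, cid in enumerate(ids)}
        folds = stratified_folds(ids, groups, k=3, seed=1)
        for fold in folds:
            assert sum(groups[c] == "b" for c in fold) == 4

    def test_small_stratum_falls_back_with_warning(self):
        ids = [f"s{i}" for i in range(6)]
        groups = {cid: "rare" if cid == "s0" else "common" for cid in ids}
        with pytest.warns(UserWarning):
            folds = stratified_folds(ids, groups, k=3, seed=0)
        assert sorted(c for f in folds for c in f) == sorted(ids)

    def test_two_fold_split_of_four(self):
        folds = stratified_folds([f"s{i}" for i in range(4)], {}, k=2, seed=0)
        assert sorted(len(f) for f in folds) == [2, 2]

    def test_seeded_assignment_reproducible(self):
        ids = [f"s{i}" for i in range(12)]
        assert stratified_folds(ids, {}, 3, seed=5) == stratified_folds(ids, {}, 3, seed=5)
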