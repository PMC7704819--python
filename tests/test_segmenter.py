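"""U-net segmenter: normalization, dataset building, training contracts."""

import numpy as np
import pytest

from muscleseg import (
    FatWaterVolume,
    MuscleLabelVolume,
    UnetConfig,
    build_unet,
    load_model,
    make_slice_dataset,
    normalize_channels,
    predict_volume,
    save_model,
    train,
)


def _vol(water, fat=None, spacing=(1, 1, 1)):
    return FatWaterVolume(water, water.copy() if fat is None else fat, spacing)


class TestNormalize:
    def test_linear_map_to_unit_interval(self):
        w = np.zeros((3, 1, 1))
        w[:, 0, 0] = [0.0, 5.0, 10.0]
        out = normalize_channels(_vol(np.broadcast_to(w, (3, 1, 1)).copy()))
        assert np.allclose(out.water.ravel(), [0.0, 0.5, 1.0])

    def test_constant_channel_maps_to_zero(self):
        out = normalize_channels(_vol(np.full((2, 2, 2), 7.0)))
        assert np.all(out.water == 0.0) and np.all(out.fat == 0.0)

    def test_idempotent_and_affine_invariant(self, rng):
        w = rng.uniform(0, 1, (4, 4, 2))
        w.flat[0], w.flat[1] = 0.0, 1.0  # pin min/max
        v = _vol(w)
        once = normalize_channels(v)
        assert np.allclose(once.water, w)
        rescaled = normalize_channels(_vol(3.0 * w + 2.0))
        assert np.allclose(rescaled.water, once.water)


def _fake_volumes(n, shape=(8, 8, 10), seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        w = rng.uniform(0, 1, shape)
        lab = rng.integers(0, 5, shape)
        out.append((_vol(w), MuscleLabelVolume(lab, (1, 1, 1))))
    return out


class TestSliceDataset:
    def test_counts_and_volume_disjointness(self):
        train, val = make_slice_dataset(_fake_volumes(4), split=(3, 1), seed=0)
        assert len(train) == 30 and len(val) == 10
        assert not ({s.volume_id for s in train} & {s.volume_id for s in val})

    def test_same_seed_reproduces_split(self):
        a = make_slice_dataset(_fake_volumes(6), split=0.75, seed=3)
        b = make_slice_dataset(_fake_volumes(6), split=0.75, seed=3)
        assert [s.volume_id for s in a[0]] == [s.volume_id for s in b[0]]

    def test_scan_level_split_counts_match_reference_cohort(self):
        # 46 thigh volumes split ~3/4 : ~1/4 at the volume level -> 36 + 10
        vols = _fake_volumes(46, shape=(4, 4, 2))
        train, val = make_slice_dataset(vols, split=(36, 10), seed=0)
        assert len({s.volume_id for s in train}) == 36
        assert len({s.volume_id for s in val}) == 10

    def test_too_few_volumes_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            make_slice_dataset(_fake_volumes(1))

    def test_grouped_split_keeps_group_members_together(self):
        vols = _fake_volumes(8, shape=(4, 4, 2))
        groups = ["A", "A", "B", "B", "C", "C", "D", "D"]
        ids = [f"v{i}" for i in range(8)]
        train, val = make_slice_dataset(vols, split=0.75, seed=1, volume_ids=ids, groups=groups)
        gid = dict(zip(ids, groups))
        assert not ({gid[s.volume_id] for s in train} & {gid[s.volume_id] for s in val})

    def test_restacking_targets_reconstructs_label_volume(self):
        vols = _fake_volumes(2, shape=(6, 6, 5))
        train, val = make_slice_dataset(vols, split=(1, 1), seed=0)
        for subset in (train, val):
            vid = subset[0].volume_id
            idx = int(vid[3:])
            stacked = np.stack([s.target for s in subset], axis=2)
            assert np.array_equal(stacked, vols[idx][1].labels)


class TestBuildUnet:
    def test_bottleneck_size_halves_per_level(self):
        cfg = UnetConfig(depth=4, base_filters=2, epochs=0)
        model = build_unet(cfg)
        model.net.forward(np.zeros((1, 2, 64, 64), np.float32))
        assert model.net.bottleneck_hw == (4, 4)

    def test_parameter_count_increases_with_base_filters(self):
        n = [build_unet(UnetConfig(base_filters=b, epochs=0)).net.n_parameters() for b in (4, 8, 16)]
        assert n[0] < n[1] < n[2]

    def test_forward_preserves_spatial_size(self):
        model = build_unet(UnetConfig(depth=3, base_filters=4, epochs=0))
        out = model.net.forward(np.zeros((2, 2, 32, 48), np.float32))
        assert out.shape == (2, 5, 32, 48)

    def test_indivisible_input_size_raises_with_padding_hint(self):
        model = build_unet(UnetConfig(depth=3, base_filters=4, epochs=0))
        with pytest.raises(ValueError, match="pad"):
            model.net.forward(np.zeros((1, 2, 30, 32), np.float32))


def _one_slice_sets(shape=(16, 16)):
    rng = np.random.default_rng(0)
    w = rng.uniform(0.2, 1.0, shape + (1,))
    lab = np.zeros(shape + (1,), int)
    lab[4:12, 4:8, 0] = 1
    lab[4:12, 8:12, 0] = 2
    vols = [(_vol(w), MuscleLabelVolume(lab, (1, 1, 1))),
            (_vol(w.copy()), MuscleLabelVolume(lab.copy(), (1, 1, 1)))]
    return make_slice_dataset(vols, split=(1, 1), seed=0)


class TestTrain:
    def test_single_slice_overfit_reduces_loss(self):
        tr, va = _one_slice_sets()
        cfg = UnetConfig(depth=2, base_filters=4, epochs=50, learning_rate=5e-3, batch_size=1, seed=0)
        model = train(build_unet(cfg), tr, va, cfg)
        losses = model.history["train_loss"]
        assert losses[-1] < 0.2 * losses[0]

    def test_zero_epochs_is_a_noop(self):
        cfg = UnetConfig(depth=2, base_filters=4, epochs=0, seed=0)
        model = build_unet(cfg)
        before = {k: v.copy() for k, v in model.net.state_dict().items()}
        out = train(model, [], [], cfg)
        assert out is model
        for k, v in out.net.state_dict().items():
            assert np.array_equal(v, before[k])

    def test_same_seed_same_loss_trajectory(self):
        tr, va = _one_slice_sets()
        cfg = UnetConfig(depth=2, base_filters=4, epochs=5, learning_rate=1e-3, batch_size=1, seed=11)
        m1 = train(build_unet(cfg), tr, va, cfg)
        m2 = train(build_unet(cfg), tr, va, cfg)
        assert m1.history["val_loss"] == m2.history["val_loss"]

    def test_nonfinite_loss_aborts_with_diagnostic(self):
        tr, va = _one_slice_sets()
        cfg = UnetConfig(depth=2, base_filters=4, epochs=5, learning_rate=1e6, batch_size=1, seed=0)
        with pytest.raises(RuntimeError, match="learning_rate"):
            train(build_unet(cfg), tr, va, cfg)


class TestPredict:
    def test_background_biased_model_yields_empty_rois(self):
        cfg = UnetConfig(depth=2, base_filters=4, epochs=0)
        model = build_unet(cfg)
        head = model.net.head
        head.W[...] = 0.0
        head.b[...] = [10.0, -10.0, -10.0, -10.0, -10.0]
        vol = _vol(np.zeros((16, 16, 3)))
        pred = predict_volume(model, vol, cfg)
        assert np.all(pred.labels == 0)

    def test_predictions_are_single_label_in_range(self, rng):
        cfg = UnetConfig(depth=2, base_filters=4, epochs=0, seed=5)
        model = build_unet(cfg)
        vol = _vol(rng.uniform(0, 1, (16, 16, 4)), rng.uniform(0, 1, (16, 16, 4)))
        pred = predict_volume(model, vol, cfg)
        assert pred.labels.shape == (16, 16, 4)
        assert set(np.unique(pred.labels)) <= {0, 1, 2, 3, 4}

    def test_save_load_roundtrip_is_bit_identical(self, rng, tmp_path):
        tr, va = _one_slice_sets()
        cfg = UnetConfig(depth=2, base_filters=4, epochs=3, learning_rate=1e-3, batch_size=1, seed=0)
        model = train(build_unet(cfg), tr, va, cfg)
        save_model(model, tmp_path / "m")
        reloaded = load_model(tmp_path / "m")
        vol = _vol(rng.uniform(0, 1, (16, 16, 2)))
        a = predict_volume(model, vol, cfg)
        b = predict_volume(reloaded, vol, cfg)
        assert np.array_equal(a.labels, b.labels)


def test_group_norm_variant_trains_and_roundtrips(tmp_path, rng):
    tr, va = _one_slice_sets()
    cfg = UnetConfig(depth=2, base_filters=4, epochs=2, learning_rate=1e-3,
                     batch_size=1, norm="group", seed=0)
    model = train(build_unet(cfg), tr, va, cfg)
    save_model(model, tmp_path / "gn")
    reloaded = load_model(tmp_path / "gn")
    vol = _vol(rng.uniform(0, 1, (16, 16, 2)))
    assert np.array_equal(
        predict_volume(model, vol, cfg).labels,
        predict_volume(reloaded, vol, cfg).labels,
    )
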