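"""Splitting, pairing, the masked loss, and the optimization loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from multiview_wss.network import NetworkConfig, build_model
from multiview_wss.render import ViewImage
from multiview_wss.synthetic import build_dataset
from multiview_wss.training import (
    SplitManifest,
    TrainConfig,
    ViewPair,
    emse_loss,
    make_pairs,
    split_dataset,
    train,
)


def cohort_with_real(n_real=23, n_base=23, variants=9):
    """230 synthetic geometries in 23 families plus 23 singleton real records."""
    manifest = build_dataset(n_base, variants, seed=0)
    for k in range(n_real):
        manifest.append({"id": f"patient{k:03d}", "family": f"patient{k:03d}",
                         "real": True, "split_eligible": True,
                         "params": {}, "paths": {}})
    return manifest


def toy_view(mask, rng, meta=None):
    pix = rng.random((*mask.shape, 3))
    pix[~mask] = 1.0
    return ViewImage(pix, mask, meta or {})


def toy_pair(rng, gid="g0", fam="f0", axis="z", step=0, aug=False, size=16):
    mask = np.zeros((size, size), dtype=bool)
    mask[3:12, 4:13] = True
    inp = toy_view(mask, rng, {"axis": axis, "step_index": step,
                               "augmentation": aug})
    tgt = toy_view(mask, rng, {"axis": axis, "step_index": step,
                               "augmentation": aug})
    return ViewPair(inp, tgt, gid, fam, axis, step, aug)


class TestSplitDataset:
    def test_published_cohort_counts(self):
        split = split_dataset(cohort_with_real(), 40, seed=0)
        assert len(split.test_ids) == 63
        assert len(split.train_ids) == 190

    def test_all_real_geometries_in_test(self):
        split = split_dataset(cohort_with_real(), 40, seed=1)
        assert all(f"patient{k:03d}" in split.test_ids for k in range(23))

    def test_partitions_disjoint_and_exhaustive(self):
        manifest = cohort_with_real()
        split = split_dataset(manifest, 40, seed=2)
        ids = {r["id"] for r in manifest}
        assert set(split.train_ids) | set(split.test_ids) == ids
        assert not set(split.train_ids) & set(split.test_ids)

    def test_no_family_spans_partitions(self):
        split = split_dataset(cohort_with_real(), 40, seed=3)
        prov = split.provenance
        train_fams = {prov[g]["family"] for g in split.train_ids}
        test_fams = {prov[g]["family"] for g in split.test_ids}
        assert not train_fams & test_fams

    def test_empty_test_partition_warns_but_works(self):
        manifest = build_dataset(3, 1, seed=0)
        split = split_dataset(manifest, 0, seed=0)
        assert split.test_ids == []
        assert len(split.train_ids) == 6

    def test_unreachable_count_rejected(self):
        manifest = build_dataset(4, 9, seed=0)  # families of 10
        with pytest.raises(ValueError):
            split_dataset(manifest, 15, seed=0)

    def test_mixed_family_rejected(self):
        manifest = build_dataset(2, 1, seed=0)
        manifest[1]["real"] = True  # same family as manifest[0]
        with pytest.raises(ValueError):
            split_dataset(manifest, 0, seed=0)

    def test_deterministic_in_seed(self):
        m = cohort_with_real()
        a = split_dataset(m, 40, seed=5)
        b = split_dataset(m, 40, seed=5)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_manifest_invariants_enforced(self):
        with pytest.raises(ValueError):
            SplitManifest(["a"], ["a"])


class TestMakePairs:
    def _rendered(self, rng, gids, augmented):
        out = {}
        for gid in gids:
            mask = np.zeros((16, 16), dtype=bool)
            mask[2:10, 3:11] = True
            views = {"input": [], "target": []}
            axes = ["z", "x", "y"] if augmented else ["z"]
            for axis in axes:
                for step in range(3):
                    for role in ("input", "target"):
                        views[role].append(toy_view(
                            mask, rng, {"axis": axis, "step_index": step,
                                        "augmentation": axis != "z"}))
            out[gid] = views
        return out

    def test_train_pairs_include_augmentation(self):
        rng = np.random.default_rng(0)
        split = SplitManifest(["a"], ["b"],
                              {"a": {"family": "a", "real": False},
                               "b": {"family": "b", "real": False}})
        rendered = {"a": self._rendered(rng, ["a"], True)["a"],
                    "b": self._rendered(rng, ["b"], False)["b"]}
        train_pairs, test_pairs = make_pairs(split, rendered)
        assert len(train_pairs) == 9   # 3 axes x 3 steps
        assert len(test_pairs) == 3    # z only
        assert all(p.axis == "z" for p in test_pairs)

    def test_pair_masks_identical(self):
        rng = np.random.default_rng(1)
        split = SplitManifest(["a"], [], {"a": {"family": "a", "real": False}})
        rendered = self._rendered(rng, ["a"], True)
        train_pairs, _ = make_pairs(split, {"a": rendered["a"]})
        for p in train_pairs:
            np.testing.assert_array_equal(p.input.mask, p.target.mask)

    def test_missing_target_view_rejected(self):
        rng = np.random.default_rng(2)
        split = SplitManifest(["a"], [], {"a": {"family": "a", "real": False}})
        rendered = self._rendered(rng, ["a"], False)
        rendered["a"]["target"] = rendered["a"]["target"][:-1]
        with pytest.raises(ValueError):
            make_pairs(split, {"a": rendered["a"]})


class TestEmseLoss:
    def test_perfect_prediction_is_zero(self):
        rng = np.random.default_rng(0)
        img = rng.random((8, 8, 3))
        mask = rng.random((8, 8)) > 0.5
        assert emse_loss(img, img, mask) == 0.0

    def test_background_only_difference_is_zero(self):
        rng = np.random.default_rng(1)
        a = rng.random((8, 8, 3))
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:5, 2:5] = True
        b = a.copy()
        b[~mask] = rng.random(((~mask).sum(), 3))
        assert emse_loss(a, b, mask) == 0.0

    def test_hand_computed_toy_example(self):
        # 2x2 single-channel, 3 masked pixels with diffs {0, 0.5, 0.5}:
        # EMSE = (0 + 0.25 + 0.25) / 3 = 1/6
        target = np.array([[0.0, 0.0], [0.0, 0.0]])
        pred = np.array([[0.0, 0.5], [0.5, 0.9]])
        mask = np.array([[True, True], [True, False]])
        assert emse_loss(pred, target, mask) == pytest.approx(1 / 6, abs=1e-15)

    def test_all_true_mask_equals_plain_mse(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((6, 6, 3)), rng.random((6, 6, 3))
        mask = np.ones((6, 6), dtype=bool)
        assert emse_loss(a, b, mask) == pytest.approx(((a - b) ** 2).mean(),
                                                      rel=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            emse_loss(np.ones((4, 4, 3)), np.ones((4, 4, 3)),
                      np.zeros((4, 4), dtype=bool))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_background_noise(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random((8, 8, 3)), rng.random((8, 8, 3))
        mask = rng.random((8, 8)) > 0.4
        if not mask.any():
            mask[0, 0] = True
        ref = emse_loss(a, b, mask)
        a2 = a.copy()
        a2[~mask] += rng.normal(size=((~mask).sum(), 3))
        assert emse_loss(a2, b, mask) == pytest.approx(ref, rel=1e-12)


class TestTrainLoop:
    def _pairs(self, rng, n_fams=4, per_fam=3):
        return [toy_pair(rng, gid=f"f{f}g{i}", fam=f"f{f}")
                for f in range(n_fams) for i in range(per_fam)]

    def test_frozen_model_stops_after_patience(self):
        rng = np.random.default_rng(0)
        pairs = self._pairs(rng)
        model = build_model(NetworkConfig(depth=2, base_filters=4,
                                          input_size=16), seed=0)
        # learning rate zero freezes the model: validation loss never improves
        config = TrainConfig(learning_rate=0.0, max_epochs=50,
                             early_stop_patience=3, batch_size=4, seed=0,
                             zoom_range=(1.0, 1.0))
        history = train(model, pairs, config)
        assert history["stopped_epoch"] == 4  # patience + 1
        assert len(history["val_loss"]) == 4

    def test_history_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        pairs = self._pairs(rng)
        config = TrainConfig(learning_rate=1e-3, max_epochs=3,
                             early_stop_patience=2, batch_size=4, seed=5)
        runs = []
        for _ in range(2):
            model = build_model(NetworkConfig(depth=2, base_filters=4,
                                              input_size=16), seed=9)
            runs.append(train(model, list(pairs), config))
        assert runs[0]["train_loss"] == runs[1]["train_loss"]
        assert runs[0]["val_loss"] == runs[1]["val_loss"]

    def test_validation_split_is_family_stratified(self, monkeypatch):
        rng = np.random.default_rng(2)
        pairs = self._pairs(rng, n_fams=10)
        model = build_model(NetworkConfig(depth=2, base_filters=4,
                                          input_size=16), seed=0)
        import multiview_wss.training as tr

        seen: dict = {}
        original = tr._eval_loss

        def spy(model, val_pairs, batch_size):
            seen["fams"] = {p.family for p in val_pairs}
            return original(model, val_pairs, batch_size)

        monkeypatch.setattr(tr, "_eval_loss", spy)
        config = TrainConfig(learning_rate=1e-3, max_epochs=2,
                             early_stop_patience=1, batch_size=8, seed=1)
        history = train(model, list(pairs), config)
        assert len(seen["fams"]) == 1  # 10% of 10 families held out whole
        assert len(history["train_loss"]) >= 1

    def test_nonfinite_loss_aborts(self):
        rng = np.random.default_rng(3)
        pairs = self._pairs(rng)
        model = build_model(NetworkConfig(depth=2, base_filters=4,
                                          input_size=16), seed=0)
        for p in model.parameters():
            p.data[...] = np.nan
        config = TrainConfig(learning_rate=1e-3, max_epochs=2,
                             early_stop_patience=1, batch_size=4, seed=0)
        with pytest.raises(RuntimeError):
            train(model, pairs, config)

    def test_no_training_pairs_rejected(self):
        model = build_model(NetworkConfig(depth=2, base_filters=4,
                                          input_size=16), seed=0)
        config = TrainConfig(max_epochs=2, early_stop_patience=1)
        with pytest.raises(ValueError):
            train(model, [], config)


class TestTrainConfig:
    def test_patience_must_be_below_max_epochs(self):
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=10, early_stop_patience=10)

    def test_validation_fraction_bounds(self):
        with pytest.raises(ValueError):
            TrainConfig(validation_fraction=0.7)
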