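import numpy as np
import pytest

from woundmetric.raster_io import BinaryMask, LabelMask, RgbImage
from woundmetric.tissue_classification import (
    TissueExample, TissueModel, TrainingConfig, augment, build_dataset,
    combined_objective, cross_entropy_loss, evaluate, extract_patches,
    preprocess_roi, size_category, split_dataset, train,
)


def uniform_label_mask(value, shape=(200, 200)):
    return LabelMask(np.full(shape, value, np.uint8))


def make_example(color, label, scene, rng=None):
    patch = np.full((5, 5, 3), color, float)
    if rng is not None:
        patch = np.clip(patch + rng.normal(0, 0.02, patch.shape), 0, 1)
    return TissueExample(patch=patch, tissue_label=label, source_scene=scene)


class TestPreprocessRoi:
    def test_full_roi_keeps_geometry(self, rng):
        img = RgbImage(rng.integers(0, 256, (200, 200, 3)).astype(np.uint8))
        roi = BinaryMask(np.ones((200, 200), bool))
        out = preprocess_roi(img, roi)
        assert out.shape == (200, 200, 3)
        assert np.allclose(out, img.pixels / 255.0, atol=1e-6)

    def test_outside_roi_is_black(self):
        img = RgbImage(np.full((200, 200, 3), 200, np.uint8))
        half = np.zeros((200, 200), bool)
        half[:, :100] = True
        out = preprocess_roi(img, BinaryMask(half))
        # crop is the left half, stretched to 200 wide; no black remains
        # inside, and masking happened before the crop
        assert out.min() >= 0.0 and out.max() <= 1.0
        # with an L-shaped roi the excluded corner stays black after resize
        ell = np.zeros((200, 200), bool)
        ell[:, :100] = True
        ell[:100, :] = True
        out = preprocess_roi(img, BinaryMask(ell))
        assert out[150:, 150:].max() == 0.0

    def test_resize_contract(self, rng):
        img = RgbImage(rng.integers(0, 256, (400, 400, 3)).astype(np.uint8))
        out = preprocess_roi(img, BinaryMask(np.ones((400, 400), bool)))
        assert out.shape == (200, 200, 3)

    def test_empty_roi_rejected(self):
        img = RgbImage(np.zeros((10, 10, 3), np.uint8))
        with pytest.raises(ValueError):
            preprocess_roi(img, BinaryMask(np.zeros((10, 10), bool)))


class TestExtractPatches:
    def test_uniform_roi_gives_full_grid(self, rng):
        processed = rng.random((200, 200, 3))
        ex = extract_patches(processed, uniform_label_mask(3))
        assert len(ex) == 1600
        assert all(e.tissue_label == "granulated" for e in ex)

    def test_half_roi_gives_half_grid(self, rng):
        labels = np.zeros((200, 200), np.uint8)
        labels[:, :100] = 2
        ex = extract_patches(rng.random((200, 200, 3)), LabelMask(labels))
        assert abs(len(ex) - 800) <= 40

    def test_majority_background_cell_dropped(self):
        labels = np.zeros((200, 200), np.uint8)
        # one cell with 12 tissue pixels (13 background) -> dropped;
        # one cell with 13 tissue pixels -> kept
        labels[0:5, 0:5].flat[:12] = 1
        labels[0:5, 5:10].flat[:13] = 1
        ex = extract_patches(np.ones((200, 200, 3)), LabelMask(labels))
        assert len(ex) == 1
        assert ex[0].tissue_label == "necrotic"

    def test_misaligned_shapes_rejected(self):
        with pytest.raises(ValueError):
            extract_patches(np.ones((100, 100, 3)), uniform_label_mask(1))


class TestAugment:
    def test_flip_is_involution(self, rng):
        ex = make_example(0.5, "slough", "s0", rng)
        flipped = ex.patch[:, ::-1]
        assert np.array_equal(flipped[:, ::-1], ex.patch)

    def test_counting_and_determinism(self, rng):
        exs = [make_example(0.3, "necrotic", "s0", rng) for _ in range(7)]
        out1 = augment(exs, seed=4)
        out2 = augment(exs, seed=4)
        assert len(out1) == 21
        assert all(np.array_equal(a.patch, b.patch) for a, b in zip(out1, out2))

    def test_zoom_identity(self):
        from woundmetric.tissue_classification import _zoom_patch
        patch = np.random.default_rng(0).random((5, 5, 3))
        assert np.array_equal(_zoom_patch(patch, 1.0), patch)

    def test_test_split_refused(self):
        ex = TissueExample(np.zeros((5, 5, 3)), "slough", "s0", split="test")
        with pytest.raises(ValueError):
            augment([ex])


class TestSplitDataset:
    def test_exact_stratified_fraction_with_singleton_scenes(self, rng):
        exs = []
        for cls in ("necrotic", "slough", "granulated"):
            for i in range(100):
                exs.append(make_example(0.5, cls, f"{cls}-{i}", rng))
        train_set, test_set = split_dataset(exs, seed=0)
        for cls in ("necrotic", "slough", "granulated"):
            n_train = sum(e.tissue_label == cls for e in train_set)
            assert abs(n_train - 80) <= 1

    def test_same_seed_same_split(self, rng):
        exs = [make_example(0.5, c, f"sc-{i % 9}", rng)
               for i, c in enumerate(
                   ["necrotic", "slough", "granulated"] * 40)]
        a = split_dataset(exs, seed=7)
        b = split_dataset(exs, seed=7)
        assert [e.source_scene for e in a[0]] == [e.source_scene for e in b[0]]

    def test_no_scene_leaks_across_split(self, rng):
        exs = []
        for i in range(12):
            n = 5 + (i % 4) * 7  # heterogeneous scene sizes
            for j in range(n):
                cls = ("necrotic", "slough", "granulated")[j % 3]
                exs.append(make_example(0.5, cls, f"scene-{i}", rng))
        train_set, test_set = split_dataset(exs, seed=1)
        train_scenes = {e.source_scene for e in train_set}
        test_scenes = {e.source_scene for e in test_set}
        assert not (train_scenes & test_scenes)
        assert train_scenes | test_scenes == {f"scene-{i}" for i in range(12)}

    def test_small_class_rejected(self, rng):
        exs = [make_example(0.5, "necrotic", f"s{i}", rng) for i in range(20)]
        exs.append(make_example(0.5, "slough", "s99", rng))
        with pytest.raises(ValueError, match="slough"):
            split_dataset(exs)


class TestLosses:
    def test_perfect_prediction_zero_loss(self):
        assert cross_entropy_loss((1, 0, 0), (1, 0, 0)) == pytest.approx(0.0)

    def test_uniform_prediction_is_ln3(self):
        assert cross_entropy_loss((0, 1, 0), (1 / 3, 1 / 3, 1 / 3)) == \
            pytest.approx(np.log(3.0), abs=1e-12)

    def test_direct_substitution(self):
        assert cross_entropy_loss((0, 1, 0), (0.2, 0.5, 0.3)) == \
            pytest.approx(-np.log(0.5), abs=1e-12)

    def test_unnormalised_probs_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy_loss((1, 0, 0), (0.5, 0.4, 0.3))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy_loss((1, 0), (0.5, 0.3, 0.2))

    def test_combined_objective_direct(self):
        j = combined_objective([1.0, 2.0], [3.0, 4.0])
        assert j.total == pytest.approx(10.0)
        assert j.mean_per_example == pytest.approx(5.0)

    def test_combined_objective_zero(self):
        assert combined_objective([0.0] * 5, [0.0] * 5).total == 0.0

    def test_combined_objective_matches_resummation(self, rng):
        ls, lt = rng.random(30), rng.random(30)
        want = sum(float(a) + float(b) for a, b in zip(ls, lt))
        assert combined_objective(ls, lt).total == pytest.approx(want, abs=1e-9)


class TestSizeCategory:
    @pytest.mark.parametrize("area, want", [
        (2.0, "small"), (5.0, "medium"), (12.0, "medium"),
        (20.0, "large"), (100.0, "large"),
    ])
    def test_rules(self, area, want):
        assert size_category(area, (5.0, 20.0)) == want

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            size_category(-1.0)


def separable_examples(rng, n_per_class=120, n_scenes=12):
    colors = {"necrotic": (0.15, 0.12, 0.12),
              "slough": (0.78, 0.71, 0.35),
              "granulated": (0.71, 0.24, 0.24)}
    exs = []
    for cls, col in colors.items():
        for i in range(n_per_class):
            exs.append(make_example(col, cls, f"scene-{i % n_scenes}", rng))
    return exs


class TestModel:
    def test_softmax_rows_sum_to_one(self, rng):
        model = TissueModel.initialise(seed=0)
        probs = model.predict_proba(rng.random((17, 5, 5, 3)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_epochs_is_noop(self, rng):
        model = TissueModel.initialise(seed=0)
        cfg = TrainingConfig(epochs=0, seed=0)
        out = train(model, separable_examples(rng, 20), cfg)
        for k in model.weights:
            assert np.array_equal(out.weights[k], model.weights[k])

    def test_training_deterministic(self, rng):
        exs = separable_examples(rng, 40)
        cfg = TrainingConfig(epochs=5, seed=3)
        a = train(TissueModel.initialise(seed=3, config=cfg), exs, cfg)
        b = train(TissueModel.initialise(seed=3, config=cfg), exs, cfg)
        assert np.allclose(a.loss_history, b.loss_history, atol=1e-6)
        for k in a.weights:
            assert np.array_equal(a.weights[k], b.weights[k])

    def test_separable_colours_learned(self, rng):
        exs = separable_examples(rng)
        cfg = TrainingConfig(epochs=30, seed=0)
        model = train(TissueModel.initialise(seed=0, config=cfg), exs, cfg)
        rep = evaluate(model, exs)
        assert rep.overall_accuracy >= 0.99

    def test_loss_decreases(self, rng):
        exs = separable_examples(rng, 60)
        cfg = TrainingConfig(epochs=10, seed=1)
        model = train(TissueModel.initialise(seed=1, config=cfg), exs, cfg)
        assert model.loss_history[-1] < model.loss_history[0]

    def test_save_load_round_trip(self, tmp_path, rng):
        exs = separable_examples(rng, 20)
        cfg = TrainingConfig(epochs=3, seed=0)
        model = train(TissueModel.initialise(seed=0, config=cfg), exs, cfg)
        model.save(tmp_path / "m.json")
        back = TissueModel.load(tmp_path / "m.json")
        x = rng.random((8, 5, 5, 3))
        assert np.allclose(model.predict_proba(x), back.predict_proba(x))


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        exs = separable_examples(rng)
        cfg = TrainingConfig(epochs=30, seed=0)
        model = train(TissueModel.initialise(seed=0, config=cfg), exs, cfg)
        rep = evaluate(model, exs)
        if rep.overall_accuracy == 1.0:
            for stats in rep.per_class.values():
                assert stats["precision"] == stats["recall"] == stats["f1"] == 1.0

    def test_hand_computed_confusion(self):
        """precision/recall/F1 must match hand arithmetic for the
        confusion matrix [[8,1,1],[2,7,1],[0,2,8]]."""

        class Stub(TissueModel):
            def __init__(self):
                self.classes = ("necrotic", "slough", "granulated")
                self.preds = None

            def predict(self, x):
                return self.preds

        y_true, y_pred = [], []
        conf = [[8, 1, 1], [2, 7, 1], [0, 2, 8]]
        for i in range(3):
            for j in range(3):
                y_true += [i] * conf[i][j]
                y_pred += [j] * conf[i][j]
        stub = Stub()
        stub.preds = np.array(y_pred)
        exs = [TissueExample(np.zeros((5, 5, 3)),
                             stub.classes[t], "s") for t in y_true]
        rep = evaluate(stub, exs)
        assert rep.per_class["necrotic"]["recall"] == pytest.approx(0.8)
        assert rep.per_class["necrotic"]["precision"] == pytest.approx(0.8)
        assert rep.per_class["slough"]["recall"] == pytest.approx(0.7)
        assert rep.per_class["slough"]["precision"] == pytest.approx(0.7)
        assert rep.per_class["granulated"]["recall"] == pytest.approx(0.8)
        assert rep.per_class["granulated"]["precision"] == pytest.approx(0.8)
        assert rep.overall_accuracy == pytest.approx(23 / 30)
        want_macro = np.mean([stats["f1"] for stats in rep.per_class.values()])
        assert rep.macro_avg["f1"] == pytest.approx(want_macro, abs=1e-9)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import precision_recall_fscore_support

        exs = separable_examples(rng, 50)
        cfg = TrainingConfig(epochs=8, seed=2)
        model = train(TissueModel.initialise(seed=2, config=cfg), exs, cfg)
        rep = evaluate(model, exs)
        x, y = (np.stack([e.patch for e in exs]),
                [model.classes.index(e.tissue_label) for e in exs])
        p, r, f, _ = precision_recall_fscore_support(
            y, model.predict(x), labels=[0, 1, 2], zero_division=0)
        for i, cls in enumerate(model.classes):
            assert rep.per_class[cls]["precision"] == pytest.approx(p[i], abs=1e-9)
            assert rep.per_class[cls]["recall"] == pytest.approx(r[i], abs=1e-9)
            assert rep.per_class[cls]["f1"] == pytest.approx(f[i], abs=1e-9)

    def test_random_predictions_near_chance(self, rng):
        class Stub(TissueModel):
            def __init__(self, rng):
                self.classes = ("necrotic", "slough", "granulated")
                self.rng = rng

            def predict(self, x):
                return self.rng.integers(0, 3, len(x))

        exs = [TissueExample(np.zeros((5, 5, 3)),
                             ("necrotic", "slough", "granulated")[i % 3], "s")
               for i in range(3000)]
        rep = evaluate(Stub(rng), exs)
        assert rep.overall_accuracy == pytest.approx(1 / 3, abs=0.03)

    def test_absent_class_warns_nan_recall(self, rng):
        exs = separable_examples(rng, 30)
        only_two = [e for e in exs if e.tissue_label != "granulated"]
        cfg = TrainingConfig(epochs=3, seed=0)
        model = train(TissueModel.initialise(seed=0, config=cfg), exs, cfg)
        with pytest.warns(UserWarning, match="granulated"):
            rep = evaluate(model, only_two)
        assert np.isnan(rep.per_class["granulated"]["recall"])


class TestSceneRecovery:
    def test_fraction_consistency_on_scenes(self, scene_batch):
        """Predicted tissue fractions sum to 1 and track the generative
        mix across scenes (Pearson r >= 0.9 at low noise)."""
        from woundmetric.tissue_classification import tissue_fractions

        train_scenes = scene_batch[:10]
        eval_scenes = scene_batch[10:16]
        exs = build_dataset(train_scenes, max_patches_per_scene=250, seed=0)
        cfg = TrainingConfig(epochs=30, seed=0)
        model = train(TissueModel.initialise(seed=0, config=cfg), exs, cfg)

        got, want = [], []
        for s in eval_scenes:
            fr = tissue_fractions(model, preprocess_roi(s.image, s.wound_mask))
            assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)
            got += [fr["necrotic"], fr["slough"], fr["granulated"]]
            want += list(s.spec.tissue_mix)
        r = np.corrcoef(got, want)[0, 1]
        assert r >= 0.9
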