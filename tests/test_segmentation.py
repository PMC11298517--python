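import numpy as np
import pandas as pd
import pytest

from afspectra import (
    NoiseModel,
    PhantomSpec,
    generate_liver_phantom,
    sample_sparse_annotations,
)
from afspectra.io import MultiChannelVolume, RegionLabelVolume, default_channel_metadata
from afspectra.segmentation import (
    FeatureBankConfig,
    ProbabilityMapSet,
    compute_feature_bank,
    evaluate_segmentation,
    postprocess_background_subtraction,
    predict_probabilities,
    probability_to_mask,
    train_classifier,
)

#: Feature count of the default bank (5 families over sigmas {0,1,2,4,8,16}),
#: pinned by regression: 6 gaussian + 6 sobel + 12 hessian + 15 DoG + 6 membrane.
DEFAULT_FEATURE_COUNT = 45


class TestFeatureBank:
    def test_default_config(self):
        cfg = FeatureBankConfig()
        assert cfg.sigma_set == (0.0, 1.0, 2.0, 4.0, 8.0, 16.0)
        assert cfg.feature_count == DEFAULT_FEATURE_COUNT

    def test_count_matches_names_and_stack(self, rng):
        cfg = FeatureBankConfig()
        stack, names = compute_feature_bank(rng.normal(size=(40, 40)), cfg)
        assert stack.shape == (DEFAULT_FEATURE_COUNT, 40, 40)
        assert names == cfg.feature_names()
        assert len(set(names)) == len(names)  # deterministic unique naming

    def test_constant_slice_features(self):
        stack, names = compute_feature_bank(np.full((32, 32), 4.0))
        for plane, name in zip(stack, names):
            scale = max(1.0, float(np.abs(plane).max()))
            assert plane.std() <= 1e-5 * scale, name
            if name.startswith(("sobel", "dog", "gradient")):
                np.testing.assert_allclose(plane, 0.0, atol=1e-5)

    def test_gaussian_matches_dense_convolution_oracle(self):
        sigma = 2.0
        delta = np.zeros((41, 41))
        delta[20, 20] = 1.0
        cfg = FeatureBankConfig(features_enabled=("gaussian",))
        stack, names = compute_feature_bank(delta, cfg)
        plane = stack[names.index("gaussian_s2")]
        r = int(4 * sigma + 0.5)
        x = np.arange(-r, r + 1)
        k1 = np.exp(-(x**2) / (2 * sigma**2))
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)  # dense separable-kernel oracle
        expected = np.zeros_like(delta)
        expected[20 - r : 20 + r + 1, 20 - r : 20 + r + 1] = kernel
        np.testing.assert_allclose(plane, expected, atol=1e-4)

    def test_sigma_zero_is_unfiltered(self, rng):
        img = rng.normal(size=(16, 16))
        stack, names = compute_feature_bank(img, FeatureBankConfig(features_enabled=("gaussian",)))
        np.testing.assert_allclose(stack[names.index("gaussian_s0")], img, rtol=1e-6)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="odd"):
            FeatureBankConfig(membrane_patch_size=18)
        with pytest.raises(ValueError, match="max_sigma"):
            FeatureBankConfig(min_sigma=4.0, max_sigma=2.0)
        with pytest.raises(ValueError, match="unknown"):
            FeatureBankConfig(features_enabled=("laplacian",))

    def test_min_sigma_positive_drops_raw(self):
        cfg = FeatureBankConfig(min_sigma=1.0, max_sigma=4.0)
        assert cfg.sigma_set == (1.0, 2.0, 4.0)


def _two_class_volume(rng, nz=6, n=24, gap=100.0):
    """Perfectly separable two-intensity volume with full annotations."""
    labels = (rng.uniform(size=(nz, n, n)) > 0.5).astype(np.int32) + 1
    data = np.where(labels == 2, gap, 0.0) + rng.normal(0, 0.5, labels.shape)
    data = np.clip(data, 0, None).astype(np.float32)
    mcv = MultiChannelVolume({785: data}, {785: default_channel_metadata()[785]})
    return mcv, RegionLabelVolume(labels, {1: "dark", 2: "bright"})


class TestTraining:
    def test_five_by_two_design_provenance(self, small_phantom):
        spec, (left, right, truth) = small_phantom
        anns = [
            sample_sparse_annotations(truth, [2, 5, 8, 11, 13], 200, seed=i)
            for i in range(2)
        ]
        clf = train_classifier([left, left], anns, n_trees=20, seed=0)
        prov = clf.training_provenance
        assert prov["n_annotated_slices"] == 10
        assert prov["n_source_volumes"] == 2
        assert set(prov["n_labeled_pixels"]) == {"background", "lumen", "low_AF", "high_AF"}

    def test_separable_classes_perfect_heldout_accuracy(self, rng):
        mcv, truth = _two_class_volume(rng)
        ann = sample_sparse_annotations(truth, [0, 1, 2], 300, seed=0)
        clf = train_classifier([mcv], [ann], n_trees=20, seed=0)
        maps = predict_probabilities(clf, mcv)
        pred = probability_to_mask(maps, class_ids=truth.name_to_label)
        heldout = slice(3, None)
        assert (pred.labels[heldout] == truth.labels[heldout]).mean() == 1.0

    def test_determinism_same_seed_same_predictions(self, rng):
        mcv, truth = _two_class_volume(rng)
        ann = sample_sparse_annotations(truth, [0, 2], 100, seed=1)
        probe = mcv[785][4:5]
        runs = []
        for _ in range(2):
            clf = train_classifier([mcv], [ann], n_trees=15, seed=7)
            runs.append(predict_probabilities(clf, probe)["bright"])
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_missing_class_listed_in_error(self, small_phantom):
        _, (left, _, truth) = small_phantom
        ann = sample_sparse_annotations(truth, [8], 50, seed=0)
        ann.labels[ann.labels == truth.name_to_label["lumen"]] = 0
        with pytest.raises(ValueError, match="lumen"):
            train_classifier([left], [ann], n_trees=5)

    def test_training_slice_reproduces_recorded_accuracy(self, rng):
        mcv, truth = _two_class_volume(rng)
        ann = sample_sparse_annotations(truth, [1], 200, seed=2)
        clf = train_classifier([mcv], [ann], n_trees=15, seed=0)
        maps = predict_probabilities(clf, mcv[785][1:2])
        pred = probability_to_mask(maps, class_ids=truth.name_to_label)
        sel = ann.labels[1] > 0
        acc = (pred.labels[0][sel] == truth.labels[1][sel]).mean()
        assert acc == pytest.approx(clf.training_provenance["training_accuracy"], abs=1e-9)


class TestPrediction:
    def test_probabilities_sum_to_one(self, rng):
        mcv, truth = _two_class_volume(rng, nz=3)
        ann = sample_sparse_annotations(truth, [0], 100, seed=0)
        clf = train_classifier([mcv], [ann], n_trees=10, seed=0)
        maps = predict_probabilities(clf, mcv)
        total = sum(maps[name] for name in maps.maps)
        np.testing.assert_allclose(total, 1.0, atol=1e-6)
        assert maps.stage == "raw"

    def test_noiseless_phantom_argmax_matches_truth_off_borders(self, noiseless_phantom):
        from scipy import ndimage as ndi

        left, _, truth = noiseless_phantom
        anns = [sample_sparse_annotations(truth, [3, 6, 9, 12], 300, seed=0)]
        clf = train_classifier([left], anns, n_trees=50, seed=0)
        maps = predict_probabilities(clf, left)
        pred = probability_to_mask(maps, class_ids=truth.name_to_label)
        border = np.zeros(truth.shape, dtype=bool)
        for lab in truth.class_names:
            m = truth.labels == lab
            border |= ndi.binary_dilation(m, iterations=1) & ~m
        interior = ~border
        assert (pred.labels[interior] == truth.labels[interior]).mean() >= 0.99

    def test_channel_mismatch(self, rng):
        mcv, truth = _two_class_volume(rng, nz=2)
        ann = sample_sparse_annotations(truth, [0], 50, seed=0)
        clf = train_classifier([mcv], [ann], n_trees=5, seed=0)
        bad = MultiChannelVolume({405: mcv[785]}, {405: default_channel_metadata()[405]})
        with pytest.raises(ValueError, match="channel"):
            predict_probabilities(clf, bad)


class TestPostprocessing:
    def _maps(self, p):
        arr = {k: np.full((1, 2, 2), v, dtype=np.float32) for k, v in p.items()}
        return ProbabilityMapSet(maps=arr, stage="raw")

    def test_pure_background_voxel(self):
        out = postprocess_background_subtraction(
            self._maps({"background": 1.0, "lumen": 0.0, "high_AF": 0.0})
        )
        assert (out["lumen"] == 0).all() and (out["high_AF"] == 0).all()
        assert (out["background"] == 0).all()  # inversion of certain background

    def test_arithmetic(self):
        out = postprocess_background_subtraction(
            self._maps({"background": 0.2, "lumen": 0.6, "high_AF": 0.2})
        )
        np.testing.assert_allclose(out["lumen"], 0.4, atol=1e-7)
        np.testing.assert_allclose(out["background"], 0.8, atol=1e-7)
        assert out.stage == "background_subtracted"

    def test_random_simplex_stays_in_unit_interval(self, rng):
        p = rng.dirichlet(np.ones(4), size=(2, 3, 3)).transpose(3, 0, 1, 2)
        maps = ProbabilityMapSet(
            maps={n: p[i].astype(np.float32) for i, n in
                  enumerate(["background", "lumen", "low_AF", "high_AF"])},
            stage="raw",
        )
        out = postprocess_background_subtraction(maps)
        for name in out.maps:
            assert out[name].min() >= 0.0 and out[name].max() <= 1.0

    def test_stage_and_missing_background_errors(self):
        maps = self._maps({"background": 0.5, "lumen": 0.5})
        out = postprocess_background_subtraction(maps)
        with pytest.raises(ValueError, match="raw"):
            postprocess_background_subtraction(out)
        with pytest.raises(ValueError, match="background"):
            postprocess_background_subtraction(self._maps({"lumen": 1.0}))


class TestMasksAndEvaluation:
    def test_threshold_mask(self):
        maps = ProbabilityMapSet(maps={"lumen": np.full((1, 2, 2), 0.6, np.float32)})
        mask = probability_to_mask(maps, "lumen", threshold=0.5)
        assert (mask.labels == 1).all()

    def test_argmax_partitions(self, rng):
        p = rng.dirichlet(np.ones(3), size=(2, 4, 4)).transpose(3, 0, 1, 2)
        maps = ProbabilityMapSet(
            maps={n: p[i].astype(np.float32) for i, n in enumerate(["a", "b", "c"])}
        )
        full = probability_to_mask(maps)
        assert set(np.unique(full.labels)) <= {1, 2, 3}
        assert (full.labels > 0).all()

    def test_mask_count_monotone_in_threshold(self, rng):
        maps = ProbabilityMapSet(
            maps={"x": rng.uniform(0, 1, (2, 8, 8)).astype(np.float32)}
        )
        counts = [
            int(probability_to_mask(maps, "x", threshold=t).labels.sum())
            for t in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_unknown_class(self):
        maps = ProbabilityMapSet(maps={"x": np.zeros((1, 1, 1), np.float32)})
        with pytest.raises(ValueError, match="unknown"):
            probability_to_mask(maps, "y")

    def test_perfect_prediction_all_ones(self, noiseless_phantom):
        _, _, truth = noiseless_phantom
        table = evaluate_segmentation(truth, truth)
        np.testing.assert_allclose(table["dice"], 1.0)

    def test_absent_class_flagged_as_one(self):
        labels = np.ones((2, 4, 4), dtype=np.int32)
        names = {1: "background", 2: "ghost"}
        table = evaluate_segmentation(
            RegionLabelVolume(labels, names), RegionLabelVolume(labels, names)
        )
        assert table.loc["ghost", "dice"] == 1.0
        assert bool(table.loc["ghost", "both_empty"])

    def test_matches_brute_force_per_class(self, rng):
        names = {1: "a", 2: "b", 3: "c"}
        la = rng.integers(1, 4, (16, 16, 16)).astype(np.int32)
        lb = rng.integers(1, 4, (16, 16, 16)).astype(np.int32)
        table = evaluate_segmentation(
            RegionLabelVolume(la, names), RegionLabelVolume(lb, names)
        )
        for lab, name in names.items():
            inter = int(((la == lab) & (lb == lab)).sum())
            total = int((la == lab).sum() + (lb == lab).sum())
            assert table.loc[name, "dice"] == pytest.approx(2 * inter / total)
        assert table.loc["macro_average", "dice"] == pytest.approx(
            table.loc[list(names.values()), "dice"].mean()
        )

    def test_class_name_mismatch(self):
        a = RegionLabelVolume(np.ones((1, 2, 2), np.int32), {1: "x"})
        b = RegionLabelVolume(np.ones((1, 2, 2), np.int32), {1: "y"})
        with pytest.raises(ValueError, match="class-name"):
            evaluate_segmentation(a, b)
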