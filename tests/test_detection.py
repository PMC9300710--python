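import numpy as np
import pytest

from spinetrack.detection import (ClassifierConfig, collapse_to_two_classes,
                                  detect_interest_points, detect_spines,
                                  extract_patch, train_classifier)
from spinetrack.cnn import PatchClassifier
from spinetrack.errors import ParameterError
from spinetrack.imgio import Image2D, VoxelGeometry

GEOM72 = VoxelGeometry(dx=0.072, dy=0.072, bit_depth=12)


def _blob_image(center=(40, 40), sigma=3.0, shape=(96, 96), amp=200.0):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    data = amp * np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
                        / (2 * sigma ** 2))
    return Image2D(data, GEOM72)


class TestInterestPoints:
    def test_single_blob_found_at_center(self):
        pts = detect_interest_points(_blob_image(), threshold=1e-4)
        assert len(pts) >= 1
        best = pts[0]
        assert abs(best.row - 40) <= 1 and abs(best.col - 40) <= 1

    def test_blank_image_empty(self):
        assert detect_interest_points(Image2D(np.zeros((64, 64)), GEOM72)) == []

    def test_sorted_by_descending_response(self):
        img = _blob_image()
        img.data += _blob_image(center=(70, 70), amp=80.0).data
        pts = detect_interest_points(img, threshold=1e-5)
        responses = [p.response for p in pts]
        assert responses == sorted(responses, reverse=True)

    def test_translation_covariance(self):
        img = _blob_image(center=(40, 40))
        shifted = Image2D(np.roll(np.roll(img.data, 5, axis=0), -3, axis=1), GEOM72)
        a = detect_interest_points(img, threshold=1e-4)[0]
        b = detect_interest_points(shifted, threshold=1e-4)[0]
        assert (b.row - a.row, b.col - a.col) == (5, -3)

    def test_simulator_recall(self, lownoise_sim):
        from spinetrack.imgio import median_filter2d
        frame = median_filter2d(lownoise_sim.frames[0], 3)
        truth = lownoise_sim.truths[0]
        pts = detect_interest_points(frame)
        hits = 0
        for r, c in truth["centers_px"]:
            d = min((p.row - r) ** 2 + (p.col - c) ** 2 for p in pts) ** 0.5
            hits += d <= 5.0
        assert hits >= 0.9 * len(truth["centers_px"])


class TestExtractPatch:
    def test_97px_at_35nm_sampling(self):
        geom = VoxelGeometry(dx=0.035, dy=0.035, bit_depth=16)
        img = Image2D(np.zeros((200, 200)), geom)
        patch = extract_patch(img, (100, 100), 3.4)
        assert patch.pixels.shape == (97, 97)

    def test_rounding_forced_odd(self):
        geom = VoxelGeometry(dx=0.1, dy=0.1, bit_depth=16)
        img = Image2D(np.zeros((50, 50)), geom)
        assert extract_patch(img, (25, 25), 1.0).pixels.shape == (11, 11)

    def test_corner_patch_zero_padded(self):
        img = Image2D(np.full((60, 60), 9.0), GEOM72)
        patch = extract_patch(img, (0, 0), 3.4).pixels
        side = patch.shape[0]
        half = side // 2
        # three quadrants fully outside the image are zero
        assert patch[:half, :half].sum() == 0
        assert patch[half:, half:].any()

    def test_simulator_pixel_side(self):
        img = Image2D(np.zeros((512, 512)), GEOM72)
        assert extract_patch(img, (256, 256), 3.4).pixels.shape == (47, 47)


class TestClassifierConfig:
    def test_class_count_restricted(self):
        with pytest.raises(ParameterError):
            ClassifierConfig(n_classes=5)

    def test_six_blocks_enforced(self):
        with pytest.raises(ParameterError):
            ClassifierConfig(block_spec=(8, 8, 8))

    def test_two_class_collapse(self):
        y = np.array([1, 2, 5, 9, 1])
        np.testing.assert_array_equal(collapse_to_two_classes(y),
                                      [1, 2, 2, 2, 1])


def _disc_vs_noise_patches(n=200, side=21, seed=0):
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:side, 0:side]
    X, y = [], []
    for _ in range(n):
        img = rng.normal(100, 20, (side, side))
        img += 150 * (((rr - side // 2) ** 2 + (cc - side // 2) ** 2) <= 25)
        X.append(img)
        y.append(1)
    for _ in range(n):
        X.append(rng.normal(100, 20, (side, side)))
        y.append(9)
    return np.array(X), np.array(y)


class TestTraining:
    def test_two_class_synthetic_high_accuracy(self):
        X, y = _disc_vs_noise_patches()
        clf, cm_train, cm_val = train_classifier(
            X, y, config=ClassifierConfig(n_classes=2), small=True, epochs=8)
        assert clf.best_val_accuracy_ >= 0.95
        # oracle: the two classes are separable by mean intensity alone
        means = X.mean(axis=(1, 2))
        thr = (means[y == 1].min() + means[y != 1].max()) / 2
        oracle_acc = ((means > thr) == (y == 1)).mean()
        assert oracle_acc >= 0.95

    def test_deterministic_given_seed(self):
        X, y = _disc_vs_noise_patches(n=40)
        _, _, cm1 = train_classifier(X, y, small=True, epochs=2)
        _, _, cm2 = train_classifier(X, y, small=True, epochs=2)
        np.testing.assert_array_equal(cm1, cm2)

    def test_single_class_rejected(self):
        X = np.zeros((10, 9, 9))
        with pytest.raises(ParameterError):
            train_classifier(X, np.ones(10, int), small=True)

    def test_nine_class_confusion_diagonal_dominant(self, trained_classifier):
        _, _, cm_val = trained_classifier
        for i in range(cm_val.shape[0]):
            if cm_val[i].sum() == 0:
                continue
            assert all(cm_val[i, i] > cm_val[i, j]
                       for j in range(cm_val.shape[1]) if j != i)

    def test_probability_simplex(self, trained_classifier):
        clf, _, _ = trained_classifier
        X = np.random.default_rng(0).uniform(0, 2000, (5, 47, 47))
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert (proba >= 0).all()


class TestDetectSpines:
    def test_untrained_classifier_rejected(self):
        with pytest.raises(ParameterError):
            detect_spines(_blob_image(), PatchClassifier())

    def test_blank_image_zero_spines(self, trained_classifier):
        clf, _, _ = trained_classifier
        assert detect_spines(Image2D(np.zeros((128, 128)), GEOM72), clf) == []

    def test_nms_merges_close_detections(self):
        from spinetrack.detection import _nms
        rows = np.array([50, 52])
        cols = np.array([50, 51])
        kept = _nms(rows, cols, np.array([0.9, 0.8]),
                    radius_px=0.5 / 0.072)  # 0.2 μm apart, 0.5 μm radius
        assert len(kept) == 1

    def test_no_close_pairs_after_nms(self, trained_classifier, lownoise_sim):
        clf, _, _ = trained_classifier
        from spinetrack.imgio import median_filter2d
        frame = median_filter2d(lownoise_sim.frames[0], 3)
        det = detect_spines(frame, clf, nms_radius_um=0.5)
        radius_px = 0.5 / 0.072
        for i in range(len(det)):
            for j in range(i + 1, len(det)):
                d = np.hypot(det[i][0] - det[j][0], det[i][1] - det[j][1])
                assert d >= radius_px

    def test_simulated_count_close_to_truth(self, trained_classifier,
                                            lownoise_sim):
        clf, _, _ = trained_classifier
        from spinetrack.imgio import median_filter2d
        frame = median_filter2d(lownoise_sim.frames[0], 3)
        truth_n = len(lownoise_sim.truths[0]["centers_px"])
        det_n = len(detect_spines(frame, clf))
        assert abs(det_n - truth_n) <= max(0.5 * truth_n, 3)


class TestCountTimeseries:
    def test_identical_frames_identical_counts(self, trained_classifier,
                                               lownoise_sim):
        clf, _, _ = trained_classifier
        from spinetrack.detection import count_spines_timeseries
        frames = [lownoise_sim.frames[0]] * 3
        counts = count_spines_timeseries(frames, clf)
        assert len(set(counts.tolist())) == 1

    def test_empty_frames_zero_counts(self, trained_classifier):
        clf, _, _ = trained_classifier
        from spinetrack.detection import count_spines_timeseries
        frames = [Image2D(np.zeros((128, 128)), GEOM72)] * 3
        counts = count_spines_timeseries(frames, clf)
        assert (counts == 0).all()
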