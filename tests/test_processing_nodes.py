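import numpy as np
import pytest

from sigflow.data_model import ConfigurationError, FeatureVector, TimeSeriesWindow
from sigflow.evaluation import compute_metrics
from sigflow.node_framework import NodeSpec
from sigflow.processing_nodes import (
    apply_normalization,
    apply_spatial_filter,
    classify,
    decimate_window,
    extract_time_features,
    fit_csp,
    fit_normalization,
    fit_pca,
    fit_xdawn,
    grid_search,
    kfold_splits,
    lowpass_filter_window,
    map_score_sigmoid,
    split_train_test,
    standardize_window,
    train_linear_classifier,
)
from sigflow.synthetic import generate_gaussian_features

from conftest import make_window, oddball_dataset


def cosine(a, b):
    return abs(float(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestStandardize:
    def test_hand_zscore(self):
        # population std of [2,4,6] is sqrt(8/3)
        out = standardize_window(make_window([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(out.values[:, 0], [-1.224745, 0.0, 1.224745], atol=1e-6)

    def test_constant_channel_zeroed(self):
        out = standardize_window(make_window([5.0, 5.0, 5.0]))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_output_moments(self):
        rng = np.random.default_rng(0)
        out = standardize_window(make_window(rng.normal(size=(50, 3)) * 7 + 3))
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=0), 1.0, atol=1e-12)


class TestDecimate:
    def test_block_means(self):
        out = decimate_window(make_window([1.0, 2.0, 3.0, 4.0], fs=100.0), 2)
        np.testing.assert_array_equal(out.values[:, 0], [1.5, 3.5])
        assert out.sampling_frequency == 50.0

    def test_identity_factor(self):
        w = make_window([1.0, 2.0, 3.0])
        out = decimate_window(w, 1)
        np.testing.assert_array_equal(out.values, w.values)
        assert out.sampling_frequency == w.sampling_frequency

    def test_constant_stays_constant(self):
        out = decimate_window(make_window([3.0] * 12), 5)
        np.testing.assert_allclose(out.values, 3.0)

    def test_invalid_factor(self):
        with pytest.raises(ConfigurationError):
            decimate_window(make_window([1.0, 2.0]), 0)


class TestLowpass:
    fs = 100.0
    cutoff = 10.0

    def sine(self, freq, n=500):
        t = np.arange(n) / self.fs
        return make_window(np.sin(2 * np.pi * freq * t), fs=self.fs)

    def rms_ratio(self, freq):
        w = self.sine(freq)
        out = lowpass_filter_window(w, self.cutoff)
        inner = slice(50, 450)  # interior samples, away from edge effects
        return float(
            np.sqrt((out.values[inner] ** 2).mean() / (w.values[inner] ** 2).mean())
        )

    def test_passband_preserved_within_1db(self):
        ratio = self.rms_ratio(0.1 * self.cutoff)
        assert 10 ** (-1 / 20) < ratio < 10 ** (1 / 20)

    def test_stopband_attenuated_20db(self):
        assert self.rms_ratio(3 * self.cutoff) < 10 ** (-20 / 20)

    def test_dc_unity_gain(self):
        w = make_window([4.25] * 100, fs=self.fs)
        out = lowpass_filter_window(w, self.cutoff)
        np.testing.assert_allclose(out.values, 4.25, atol=1e-9)

    def test_invalid_cutoff(self):
        with pytest.raises(ConfigurationError):
            lowpass_filter_window(self.sine(1.0), 60.0)


def erp_windows(rng, n_targets=40, n_standards=40, n_ch=4, t_len=30, pattern=None, amp=3.0):
    if pattern is None:
        pattern = np.zeros(n_ch)
        pattern[0] = 1.0
    pulse = np.zeros(t_len)
    pulse[10:20] = amp
    windows = []
    for label, n in (("Target", n_targets), ("Standard", n_standards)):
        for _ in range(n):
            values = rng.normal(size=(t_len, n_ch))
            if label == "Target":
                values = values + np.outer(pulse, pattern)
            windows.append(make_window(values, label=label))
    return windows, pattern


class TestXdawn:
    def test_recovers_single_channel_erp(self):
        windows, pattern = erp_windows(np.random.default_rng(0))
        model = fit_xdawn(windows, "Target", 2)
        assert cosine(model.filters[:, 0], pattern) >= 0.99

    def test_recovers_planted_pattern_vs_closed_form(self):
        dataset, truth = oddball_dataset(
            seed=5, amplitude=2.0, n_targets=100, n_standards=400
        )
        model = fit_xdawn(dataset.samples, "Target", 2)
        # white noise => optimal filter is proportional to the pattern itself
        assert cosine(model.filters[:, 0], truth.spatial_pattern) >= 0.95

    def test_full_rank_reconstruction(self):
        windows, _ = erp_windows(np.random.default_rng(1), n_ch=3)
        model = fit_xdawn(windows, "Target", 3)
        w = windows[0]
        projected = apply_spatial_filter(model, w)
        back = projected.values @ np.linalg.inv(model.filters)
        np.testing.assert_allclose(back, w.values, atol=1e-6)

    def test_unit_norm_columns(self):
        windows, _ = erp_windows(np.random.default_rng(2))
        model = fit_xdawn(windows, "Target", 4)
        np.testing.assert_allclose(np.linalg.norm(model.filters, axis=0), 1.0, atol=1e-9)

    def test_requires_targets(self):
        windows, _ = erp_windows(np.random.default_rng(3), n_targets=1)
        with pytest.raises(ValueError, match="Target"):
            fit_xdawn([w for w in windows if w.label != "Target"] + windows[:1], "Target", 2)

    def test_permutation_invariance(self):
        windows, _ = erp_windows(np.random.default_rng(4))
        model = fit_xdawn(windows, "Target", 2)
        perm = [2, 0, 3, 1]
        permuted = [
            TimeSeriesWindow(
                w.values[:, perm],
                tuple(w.channel_names[i] for i in perm),
                w.sampling_frequency,
                label=w.label,
            )
            for w in windows
        ]
        model_p = fit_xdawn(permuted, "Target", 2)
        for j in range(2):
            assert cosine(model_p.filters[:, j], model.filters[perm, j]) >= 1 - 1e-9


def csp_windows(rng, v, n_per_class=200, n_ch=6, t_len=50, scale=np.sqrt(10.0)):
    windows = []
    for label, s in (("A", scale), ("B", 1.0)):
        for _ in range(n_per_class):
            noise = rng.normal(size=(t_len, n_ch))
            extra = s * rng.normal(size=(t_len, 1)) @ v[None, :]
            windows.append(make_window(noise + extra, label=label))
    return windows


class TestCsp:
    def test_recovers_variance_direction(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=6)
        v /= np.linalg.norm(v)
        model = fit_csp(csp_windows(rng, v), 2)
        assert cosine(model.filters[:, 0], v) >= 0.95

    def test_eigenvalues_in_unit_interval(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=4)
        v /= np.linalg.norm(v)
        model = fit_csp(csp_windows(rng, v, n_ch=4), 4)
        assert np.all(model.eigenvalues > 0) and np.all(model.eigenvalues < 1)

    def test_identical_distributions_near_half(self):
        rng = np.random.default_rng(2)
        windows = []
        for label in ("A", "B"):
            for _ in range(300):
                windows.append(make_window(rng.normal(size=(50, 4)), label=label))
        model = fit_csp(windows, 4)
        assert np.max(np.abs(model.eigenvalues - 0.5)) < 0.05

    def test_requires_two_classes(self):
        rng = np.random.default_rng(3)
        windows = [make_window(rng.normal(size=(10, 3)), label="A") for _ in range(5)]
        with pytest.raises(ValueError, match="2 classes"):
            fit_csp(windows, 2)


class TestPca:
    def test_dominant_direction(self):
        rng = np.random.default_rng(0)
        u = np.array([0.6, 0.8])
        data = 3.0 * rng.normal(size=(2000, 1)) @ u[None, :] + rng.normal(size=(2000, 2))
        windows = [make_window(data[i * 100 : (i + 1) * 100]) for i in range(20)]
        model = fit_pca(windows, 1)
        assert cosine(model.filters[:, 0], u) >= 0.99

    def test_full_rank_orthonormal(self):
        rng = np.random.default_rng(1)
        windows = [make_window(rng.normal(size=(40, 5))) for _ in range(10)]
        model = fit_pca(windows, 5)
        np.testing.assert_allclose(
            model.filters.T @ model.filters, np.eye(5), atol=1e-9
        )

    def test_eigenvalues_non_increasing(self):
        rng = np.random.default_rng(2)
        windows = [make_window(rng.normal(size=(40, 5)) * [5, 4, 3, 2, 1]) for _ in range(10)]
        model = fit_pca(windows, 5)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)


class TestApplySpatialFilter:
    def test_identity_filters_rename_channels(self):
        from sigflow.processing_nodes import SpatialFilterModel

        model = SpatialFilterModel(
            filters=np.eye(3),
            input_channel_names=("a", "b", "c"),
            output_channel_names=("pca00", "pca01", "pca02"),
            method="pca",
        )
        w = make_window(np.arange(6.0).reshape(2, 3), channel_names=("a", "b", "c"))
        out = apply_spatial_filter(model, w)
        np.testing.assert_array_equal(out.values, w.values)
        assert out.channel_names == ("pca00", "pca01", "pca02")

    def test_channel_reduction(self):
        rng = np.random.default_rng(0)
        windows, _ = erp_windows(rng, n_ch=8)
        model = fit_xdawn(windows, "Target", 3)
        out = apply_spatial_filter(model, windows[0])
        assert out.values.shape == (30, 3)
        assert out.channel_names == ("xdawn00", "xdawn01", "xdawn02")

    def test_linearity(self):
        rng = np.random.default_rng(1)
        windows, _ = erp_windows(rng, n_ch=4)
        model = fit_xdawn(windows, "Target", 2)
        x, y = windows[0], windows[1]
        combo = make_window(2.0 * x.values + 3.0 * y.values)
        lhs = apply_spatial_filter(model, combo).values
        rhs = 2.0 * apply_spatial_filter(model, x).values + 3.0 * apply_spatial_filter(model, y).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_channel_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        windows, _ = erp_windows(rng, n_ch=4)
        model = fit_xdawn(windows, "Target", 2)
        other = make_window(np.zeros((30, 4)), channel_names=("w", "x", "y", "z"))
        with pytest.raises(ValueError, match="mismatch"):
            apply_spatial_filter(model, other)

    def test_apply_idempotent_on_fresh_copy(self):
        rng = np.random.default_rng(3)
        windows, _ = erp_windows(rng, n_ch=4)
        model = fit_xdawn(windows, "Target", 2)
        a = apply_spatial_filter(model, windows[0])
        b = apply_spatial_filter(model, windows[0])
        np.testing.assert_array_equal(a.values, b.values)


class TestTimeFeatures:
    def test_naming_rule(self):
        w = make_window(np.array([[1.0, 2.0], [3.0, 4.0]]), fs=100.0)
        fv = extract_time_features(w)
        assert fv.feature_names == (
            "TD_ch1_0.0",
            "TD_ch2_0.0",
            "TD_ch1_10.0",
            "TD_ch2_10.0",
        )
        np.testing.assert_array_equal(fv.values, [1.0, 2.0, 3.0, 4.0])

    def test_feature_count(self):
        w = make_window(np.zeros((7, 3)))
        assert len(extract_time_features(w).values) == 21

    def test_label_copied(self):
        w = make_window(np.zeros((2, 2)), label="Target")
        assert extract_time_features(w).label == "Target"


class TestNormalization:
    def test_hand_case(self):
        train = [FeatureVector([0.0], ("f",)), FeatureVector([2.0], ("f",))]
        model = fit_normalization(train)
        np.testing.assert_allclose(model.location, [1.0])
        np.testing.assert_allclose(model.scale, [1.0])
        out = apply_normalization(model, FeatureVector([3.0], ("f",)))
        np.testing.assert_allclose(out.values, [2.0])

    def test_training_data_standardized(self):
        rng = np.random.default_rng(0)
        train = [FeatureVector(rng.normal(size=3) * 5 + 2, ("a", "b", "c")) for _ in range(40)]
        model = fit_normalization(train)
        out = np.stack([apply_normalization(model, fv).values for fv in train])
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-9)

    def test_constant_feature_maps_to_zero(self):
        train = [FeatureVector([7.0], ("f",)) for _ in range(3)]
        model = fit_normalization(train)
        out = apply_normalization(model, FeatureVector([99.0], ("f",)))
        assert out.values[0] == 0.0

    def test_name_mismatch(self):
        model = fit_normalization(
            [FeatureVector([0.0], ("f",)), FeatureVector([1.0], ("f",))]
        )
        with pytest.raises(ValueError, match="names"):
            apply_normalization(model, FeatureVector([0.0], ("g",)))


def toy_separable():
    names = ("x", "y")
    return [
        FeatureVector([-2.0, -1.0], names, label="Standard"),
        FeatureVector([-1.0, -2.0], names, label="Standard"),
        FeatureVector([2.0, 1.0], names, label="Target"),
        FeatureVector([1.0, 2.0], names, label="Target"),
    ]


class TestLinearClassifier:
    def test_separable_training_accuracy(self):
        train = toy_separable()
        model = train_linear_classifier(train, complexity=1e3)
        predictions = [classify(model, fv) for fv in train]
        assert all(p.assigned_label == p.true_label for p in predictions)

    def test_symmetric_data_zero_bias(self):
        names = ("x",)
        train = [
            FeatureVector([1.0], names, label="Target"),
            FeatureVector([-1.0], names, label="Standard"),
            FeatureVector([2.0], names, label="Target"),
            FeatureVector([-2.0], names, label="Standard"),
        ]
        model = train_linear_classifier(train, complexity=1.0)
        assert abs(model.bias) < 1e-6

    def test_weight_norm_shrinks_with_c(self):
        train = toy_separable()
        norms = [
            np.linalg.norm(train_linear_classifier(train, complexity=c).weights)
            for c in (1e3, 1e2, 1e1, 1e0, 1e-1, 1e-2)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_one_class_rejected(self):
        train = [FeatureVector([0.0], ("f",), label="A") for _ in range(3)]
        with pytest.raises(ValueError):
            train_linear_classifier(train, complexity=1.0)

    def test_classify_conventions(self):
        from sigflow.processing_nodes import LinearModel

        model = LinearModel(
            weights=np.array([1.0]),
            bias=0.0,
            complexity=1.0,
            class_labels=("Standard", "Target"),
            feature_names=("f",),
        )
        assert classify(model, FeatureVector([2.0], ("f",))).score == 2.0
        assert classify(model, FeatureVector([2.0], ("f",))).assigned_label == "Target"
        assert classify(model, FeatureVector([-2.0], ("f",))).assigned_label == "Standard"
        # tie rule: score 0 goes to the positive class
        assert classify(model, FeatureVector([0.0], ("f",))).assigned_label == "Target"


class TestSigmoidMapping:
    def test_zero_maps_to_half(self):
        from sigflow.data_model import PredictionVector

        p = PredictionVector(0.0, "Target", "Target", "clf")
        assert map_score_sigmoid(p).score == 0.5

    def test_monotone_and_bounded(self):
        from sigflow.data_model import PredictionVector

        scores = [-50.0, -2.0, 0.0, 1.0, 30.0]
        mapped = [
            map_score_sigmoid(PredictionVector(s, "T", "T", "c"), scale=2.0).score
            for s in scores
        ]
        assert mapped == sorted(mapped)
        assert all(0.0 <= m <= 1.0 for m in mapped)
        assert 0.0 < mapped[1] < mapped[3] < 1.0
        assert mapped[-1] > 0.999


class TestSplitting:
    @staticmethod
    def labeled(n_a, n_b):
        return [FeatureVector([float(i)], ("f",), label="A") for i in range(n_a)] + [
            FeatureVector([float(i)], ("f",), label="B") for i in range(n_b)
        ]

    def test_half_split_balanced(self):
        samples = self.labeled(5, 5)
        assignment = split_train_test(samples, 0.5, seed=0)
        flags = assignment.train_flags
        assert sum(flags) == 5
        labels_train = {s.label for s, f in zip(samples, flags) if f}
        labels_test = {s.label for s, f in zip(samples, flags) if not f}
        assert labels_train == labels_test == {"A", "B"}

    def test_deterministic_in_seed(self):
        samples = self.labeled(10, 10)
        assert split_train_test(samples, 0.3, 5) == split_train_test(samples, 0.3, 5)

    def test_different_seeds_differ(self):
        samples = self.labeled(50, 50)
        a = split_train_test(samples, 0.5, 0)
        b = split_train_test(samples, 0.5, 1)
        assert a.train_flags != b.train_flags

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            split_train_test(self.labeled(1, 5), 0.5, 0)

    def test_kfold_sizes(self):
        samples = self.labeled(10, 10)
        splits = kfold_splits(samples, 5, seed=0)
        assert len(splits) == 5
        for s in splits:
            validation = [i for i, f in enumerate(s.train_flags) if not f]
            assert len(validation) == 4
            labels = [samples[i].label for i in validation]
            assert labels.count("A") == 2 and labels.count("B") == 2

    def test_kfold_disjoint_exhaustive(self):
        samples = self.labeled(9, 7)
        splits = kfold_splits(samples, 3, seed=1)
        validation_sets = [
            {i for i, f in enumerate(s.train_flags) if not f} for s in splits
        ]
        union = set().union(*validation_sets)
        assert union == set(range(16))
        assert sum(len(v) for v in validation_sets) == 16

    def test_kfold_k_too_large(self):
        with pytest.raises(ConfigurationError, match="smallest class"):
            kfold_splits(self.labeled(10, 3), 4, seed=0)


class TestGridSearch:
    tail = [NodeSpec("LinearClassifier", {"complexity": "__C__"})]

    def brute_force(self, grid_values, train, k, seed):
        """Independent re-computation of fold-mean balanced accuracy."""
        folds = kfold_splits(train, k, seed)
        means = {}
        for c in grid_values:
            scores = []
            for assignment in folds:
                tr = [s for s, f in zip(train, assignment.train_flags) if f]
                va = [s for s, f in zip(train, assignment.train_flags) if not f]
                model = train_linear_classifier(tr, complexity=c)
                preds = [classify(model, fv) for fv in va]
                scores.append(compute_metrics(preds, "Target").balanced_accuracy)
            means[c] = float(np.mean(scores))
        return means

    def test_matches_brute_force_selection(self):
        train = generate_gaussian_features(20, 3, separation=2.0, seed=4).samples
        grid_values = [0.01, 1.0, 100.0]
        best, _, scores = grid_search(
            self.tail, {"__C__": grid_values}, 5, "balanced_accuracy", train, seed=11
        )
        oracle = self.brute_force(grid_values, train, 5, seed=11)
        for c in grid_values:
            assert scores[(c,)] == pytest.approx(oracle[c], abs=1e-12)
        best_oracle = max(grid_values, key=lambda c: oracle[c])
        assert best["__C__"] == best_oracle

    def test_single_point_grid(self):
        train = generate_gaussian_features(10, 2, separation=4.0, seed=0).samples
        best, tail, _ = grid_search(
            self.tail, {"__C__": [0.5]}, 5, "accuracy", train, seed=0
        )
        assert best == {"__C__": 0.5}
        assert tail[0].model.complexity == 0.5

    def test_tie_prefers_first_listed(self):
        # perfectly separable: every C achieves the same fold means
        train = generate_gaussian_features(10, 2, separation=50.0, seed=1).samples
        best, _, scores = grid_search(
            self.tail, {"__C__": [7.0, 3.0, 1.0]}, 5, "accuracy", train, seed=2
        )
        assert len(set(scores.values())) == 1
        assert best == {"__C__": 7.0}


class TestEndToEndSanity:
    def test_chance_level_at_zero_separation(self):
        accs = []
        for seed in range(10):
            train = generate_gaussian_features(30, 4, separation=0.0, seed=seed)
            flags = split_train_test(train.samples, 0.5, seed).train_flags
            tr = [s for s, f in zip(train.samples, flags) if f]
            te = [s for s, f in zip(train.samples, flags) if not f]
            model = train_linear_classifier(tr, complexity=1.0)
            preds = [classify(model, fv) for fv in te]
            accs.append(compute_metrics(preds, "Target").balanced_accuracy)
        assert 0.4 <= float(np.mean(accs)) <= 0.6

    def test_high_accuracy_at_high_separation(self):
        train = generate_gaussian_features(50, 4, separation=6.0, seed=0)
        flags = split_train_test(train.samples, 0.5, 0).train_flags
        tr = [s for s, f in zip(train.samples, flags) if f]
        te = [s for s, f in zip(train.samples, flags) if not f]
        model = train_linear_classifier(tr, complexity=1.0)
        preds = [classify(model, fv) for fv in te]
        assert compute_metrics(preds, "Target").accuracy >= 0.95
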