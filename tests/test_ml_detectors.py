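import itertools
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imutrack.ml_detectors import (
    FEATURE_NAMES,
    FeatureTable,
    SequenceClassifier,
    TrainingProtocol,
    build_feature_table,
    extract_window_features,
    fit_sequence_classifier,
    fit_window_classifier,
    median_filter_labels,
    prune_correlated,
    split_subjects,
    standardize,
)
from imutrack.signal_model import LabelSequence, WindowSpec


class TestExtractWindowFeatures:
    def test_constant_window(self):
        c, n = 2.5, 8
        f = extract_window_features(np.full(n, c))
        for key in ("mean", "max", "min", "median", "q25", "q75"):
            assert f[key] == pytest.approx(c)
        assert f["sd"] == f["var"] == f["maxdiff"] == 0.0
        assert f["sum"] == pytest.approx(n * c)
        assert f["energy"] == pytest.approx(n * c**2)

    def test_hand_computed_one_two_three(self):
        f = extract_window_features(np.array([1.0, 2.0, 3.0]))
        assert f["mean"] == 2.0
        assert f["sum"] == 6.0
        assert f["energy"] == 14.0
        assert f["maxdiff"] == 1.0
        assert f["var"] == pytest.approx(2 / 3)

    def test_reversal_only_flips_maxdiff(self):
        a = extract_window_features(np.array([1.0, 2.0, 3.0]))
        b = extract_window_features(np.array([3.0, 2.0, 1.0]))
        assert b["maxdiff"] == -1.0
        for key in FEATURE_NAMES:
            if key != "maxdiff":
                assert a[key] == pytest.approx(b[key])

    def test_absolute_maxdiff_flag(self):
        f = extract_window_features(np.array([3.0, 2.0, 1.0]), absolute_maxdiff=True)
        assert f["maxdiff"] == 1.0

    def test_eleven_features(self):
        assert set(extract_window_features(np.arange(5.0))) == set(FEATURE_NAMES)

    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=20),
        st.floats(-5, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_translation_covariance(self, values, c):
        x = np.array(values)
        a = extract_window_features(x)
        b = extract_window_features(x + c)
        for key in ("mean", "max", "min", "median", "q25", "q75"):
            assert b[key] == pytest.approx(a[key] + c, abs=1e-9)
        assert b["sum"] == pytest.approx(a["sum"] + len(x) * c, abs=1e-9)
        for key in ("sd", "var", "maxdiff"):
            assert b[key] == pytest.approx(a[key], abs=1e-9)


class TestPruneCorrelated:
    def test_duplicate_column_dropped(self, rng):
        x = rng.standard_normal(100)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.standard_normal(100)})
        kept, dropped = prune_correlated(df)
        assert kept == ["a", "c"] and dropped == ["b"]

    def test_negated_column_dropped(self, rng):
        x = rng.standard_normal(100)
        df = pd.DataFrame({"a": x, "neg": -x})
        _, dropped = prune_correlated(df)
        assert dropped == ["neg"]

    def test_independent_columns_kept(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((1000, 8)), columns=list("abcdefgh"))
        kept, dropped = prune_correlated(df)
        assert dropped == []

    def test_zero_variance_column_kept(self, rng):
        df = pd.DataFrame({"flat": np.ones(50), "x": rng.standard_normal(50)})
        kept, dropped = prune_correlated(df)
        assert "flat" in kept and dropped == []

    def test_dropped_list_reusable_on_other_table(self, rng):
        x = rng.standard_normal(60)
        train = pd.DataFrame({"a": x, "b": x * 2, "c": rng.standard_normal(60)})
        _, dropped = prune_correlated(train)
        test = pd.DataFrame(rng.standard_normal((10, 3)), columns=["a", "b", "c"])
        reduced = test.drop(columns=dropped)
        assert list(reduced.columns) == ["a", "c"]


class TestStandardize:
    def test_training_rows_become_standard(self, rng):
        df = pd.DataFrame(rng.standard_normal((200, 4)) * 3 + 7)
        out, _ = standardize(df)
        np.testing.assert_allclose(out.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(ddof=0), 1.0, atol=1e-12)

    def test_zero_variance_column_centered_only(self):
        df = pd.DataFrame({"flat": np.full(10, 5.0)})
        out, _ = standardize(df)
        np.testing.assert_array_equal(out["flat"], 0.0)

    def test_test_rows_use_train_params(self, rng):
        train = pd.DataFrame(rng.standard_normal((100, 2)))
        test = pd.DataFrame(rng.standard_normal((100, 2)) + 5)
        _, params = standardize(train)
        with_train, _ = standardize(test, params)
        self_std, _ = standardize(test)
        assert not np.allclose(with_train, self_std)


def separable_table(rng, n_per_group=40, n_groups=4):
    rows, labels, groups = [], [], []
    for g in range(n_groups):
        for _ in range(n_per_group):
            y = rng.integers(0, 2)
            rows.append(
                {"f1": y * 4 + rng.normal(0, 0.2), "f2": rng.normal(0, 1.0)}
            )
            labels.append(y)
            groups.append(f"G{g}")
    return FeatureTable(pd.DataFrame(rows), np.array(labels), np.array(groups))


class TestFitWindowClassifier:
    @pytest.mark.parametrize("kind", ["lr", "svm", "rf"])
    def test_separable_data_perfect_cv(self, kind, rng):
        table = separable_table(rng)
        _, report = fit_window_classifier(kind, table, n_iter=2, seed=0)
        assert report["best_cv_accuracy"] == 1.0

    def test_group_folds_keep_subjects_apart(self, rng):
        from sklearn.model_selection import GroupKFold

        table = separable_table(rng)
        for tr, va in GroupKFold(3).split(
            table.features, table.labels, table.groups
        ):
            assert set(table.groups[tr]) & set(table.groups[va]) == set()

    def test_shuffled_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(3)
        table = separable_table(rng, n_per_group=60)
        # balanced labels, shuffled: chance accuracy == 0.5
        n = len(table.labels)
        table.labels = rng.permutation(np.arange(n) % 2)
        _, report = fit_window_classifier("lr", table, n_iter=2, seed=0)
        assert report["best_cv_accuracy"] == pytest.approx(0.5, abs=0.05)

    def test_fewer_than_three_groups_rejected(self, rng):
        table = separable_table(rng, n_groups=2)
        with pytest.raises(ValueError):
            fit_window_classifier("lr", table)

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_window_classifier("mlp", separable_table(rng))


class TestFeatureTable:
    def test_66_columns(self, noisy_dataset):
        trial, _, labels = noisy_dataset[0]
        table = build_feature_table([trial], [labels], WindowSpec(N=30, stride=20))
        assert table.features.shape[1] == 66
        assert len(table.features) == len(table.labels) == len(table.groups)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            FeatureTable(
                pd.DataFrame({"a": [1.0, np.nan]}),
                np.array([0, 1]),
                np.array(["g", "g"]),
            )


class TestSequenceClassifier:
    def test_sigmoid_output_in_unit_interval(self, rng):
        model = SequenceClassifier("lstm30", seed=0)
        p = model.predict_proba(rng.standard_normal((8, 30, 6)))
        assert np.all((p > 0) & (p < 1))

    def test_lstm6_architecture_depth(self):
        model = SequenceClassifier("lstm6x80", seed=0)
        assert len(model.lstms) == 6
        assert all(l.hidden_size == 80 for l in model.lstms)

    def test_unknown_arch_rejected(self):
        with pytest.raises(ValueError):
            SequenceClassifier("gru", seed=0)

    def test_small_training_run_beats_090(self, noisy_dataset):
        trials = [d[0] for d in noisy_dataset]
        truths = [d[2] for d in noisy_dataset]
        proto = TrainingProtocol(max_epochs=5, batch_size=32)
        model, info = fit_sequence_classifier(
            "lstm30", trials, truths, proto, WindowSpec(N=30, stride=4), seed=0
        )
        assert info["val_accuracy"] > 0.9

    def test_lstm6_one_epoch_smoke(self, rng):
        from imutrack.nn import train_window_classifier

        model = SequenceClassifier("lstm6x80", seed=0)
        x = rng.standard_normal((24, 30, 6))
        y = (x[:, :, 0].mean(axis=1) > 0).astype(float)
        proto = TrainingProtocol(max_epochs=1, batch_size=8)
        history = train_window_classifier(model, x[:16], y[:16], x[16:], y[16:], proto)
        assert len(history["train_loss"]) == 1
        assert np.isfinite(history["val_loss"][-1])

    def test_subject_split_is_disjoint(self):
        train, val = split_subjects([f"S{i}" for i in range(10)], 0.7, seed=1)
        assert set(train) & set(val) == set()
        assert len(train) == 7 and len(val) == 3


def brute_force_median_filter(bits, kernel):
    half = kernel // 2
    padded = [bits[0]] * half + list(bits) + [bits[-1]] * half
    return [
        int(statistics.median(padded[i : i + kernel])) for i in range(len(bits))
    ]


def isolated_flips(bits):
    return sum(
        1
        for i in range(1, len(bits) - 1)
        if bits[i - 1] == bits[i + 1] != bits[i]
    )


class TestMedianFilter:
    def test_kernel_one_is_identity(self):
        labels = LabelSequence(np.array([1, 0, 1, 0, 1]))
        out = median_filter_labels(labels, 1)
        np.testing.assert_array_equal(out.labels, labels.labels)

    def test_hand_computed_example(self):
        out = median_filter_labels(LabelSequence(np.array([1, 1, 0, 1, 1])), 3)
        np.testing.assert_array_equal(out.labels, [1, 1, 1, 1, 1])

    def test_constant_sequence_unchanged(self):
        out = median_filter_labels(LabelSequence(np.zeros(20, dtype=int)), 7)
        np.testing.assert_array_equal(out.labels, 0)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            median_filter_labels(LabelSequence(np.ones(5, dtype=int)), 4)

    def test_matches_brute_force_and_never_adds_flips(self):
        for bits in itertools.product([0, 1], repeat=7):
            out = median_filter_labels(LabelSequence(np.array(bits)), 3)
            expected = brute_force_median_filter(bits, 3)
            np.testing.assert_array_equal(out.labels, expected)
            assert isolated_flips(list(out.labels)) <= isolated_flips(list(bits))
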