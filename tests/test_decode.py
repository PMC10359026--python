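"""Shrinkage-LDA classifier, time-resolved decoding, and smoothing."""

import numpy as np
import pytest

import materialdecode as md
from materialdecode.decode import (
    AccuracyTimecourse,
    compute_gram,
    decision_values,
    decode_timecourse,
    fit_lda,
    predict_lda,
    smooth_timecourse,
)
from materialdecode.schemes import FoldSpec
from conftest import make_epoched
from oracles import brute_force_lda_scores as brute_force_scores




class TestFitPredict:
    def test_identity_covariance_reduces_to_nearest_mean(self, rng):
        means = np.array([[0.0, 0.0], [4.0, 4.0]])
        X = np.vstack([rng.standard_normal((20, 2)) + m for m in means])
        y = np.repeat([0, 1], 20)
        model = fit_lda(X, y, shrinkage=0.05)
        probes = np.array([[0.5, -0.2], [3.8, 4.4]])
        dist = ((probes[:, None, :] - model.class_means[None]) ** 2).sum(-1)
        assert np.array_equal(predict_lda(model, probes), model.classes[dist.argmin(1)])

    def test_full_shrinkage_is_exactly_nearest_mean(self, rng):
        X = rng.standard_normal((12, 3)) @ np.diag([1.0, 5.0, 0.2])
        y = np.repeat([0, 1, 2], 4)
        model = fit_lda(X, y, shrinkage=1.0)
        probes = rng.standard_normal((30, 3))
        dist = ((probes[:, None, :] - model.class_means[None]) ** 2).sum(-1)
        assert np.array_equal(predict_lda(model, probes), model.classes[dist.argmin(1)])

    @pytest.mark.parametrize("seed", range(8))
    def test_decision_values_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((6, 2))
        y = np.array([0, 0, 0, 1, 1, 1])
        probes = rng.standard_normal((5, 2))
        model = fit_lda(X, y, shrinkage=0.1)
        got = decision_values(model, probes)
        # equal priors contribute the same constant to every class
        got = got - np.log(model.priors)
        _, want = brute_force_scores(X, y, probes, 0.1)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_pattern_at_class_mean_is_classified_to_it(self, rng):
        X = rng.standard_normal((20, 4))
        y = np.repeat(["a", "b"], 10)
        model = fit_lda(X, y, shrinkage=0.2)
        assert predict_lda(model, model.class_means[1:2])[0] == "b"

    def test_equidistant_tie_breaks_to_first_class(self):
        X = np.array([[-1.0, 0.1], [-1.0, -0.1], [1.0, 0.1], [1.0, -0.1]])
        y = np.array(["left", "right"]).repeat(2)
        model = fit_lda(X, y, shrinkage=1.0)
        # exactly between the two means
        assert predict_lda(model, np.array([[0.0, 0.0]]))[0] == "left"

    def test_separable_clusters_decode_perfectly(self, rng):
        means = rng.standard_normal((4, 6)) * 50
        Xtr = np.vstack([m + rng.standard_normal((10, 6)) for m in means])
        Xte = np.vstack([m + rng.standard_normal((5, 6)) for m in means])
        ytr = np.repeat(np.arange(4), 10)
        yte = np.repeat(np.arange(4), 5)
        model = fit_lda(Xtr, ytr, shrinkage=0.01)
        assert (predict_lda(model, Xte) == yte).mean() == 1.0

    def test_singular_covariance_without_shrinkage_raises(self, rng):
        X = rng.standard_normal((6, 10))  # fewer trials than channels
        y = np.repeat([0, 1], 3)
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            fit_lda(X, y, shrinkage=0.0)

    def test_dimension_mismatch_rejected(self, rng):
        model = fit_lda(rng.standard_normal((8, 3)), np.repeat([0, 1], 4), 0.1)
        with pytest.raises(ValueError, match="dimension"):
            predict_lda(model, rng.standard_normal((2, 5)))

    def test_degenerate_classes_rejected(self, rng):
        with pytest.raises(ValueError, match="classes"):
            fit_lda(rng.standard_normal((4, 2)), np.zeros(4), 0.1)
        with pytest.raises(ValueError, match="trials per class"):
            fit_lda(rng.standard_normal((3, 2)), np.array([0, 1, 1]), 0.1)

    def test_ledoit_wolf_shrinkage_lies_in_unit_interval(self, rng):
        X = rng.standard_normal((30, 8))
        y = np.repeat([0, 1], 15)
        model = fit_lda(X, y, shrinkage="ledoit-wolf")
        assert 0.0 < model.shrinkage <= 1.0


class TestTimecourse:
    def _epoched(self, rng, n_trials=32, n_ch=8, n_t=60, signal_window=None, amp=0.0):
        data = rng.standard_normal((n_trials, n_ch, n_t)).astype(np.float32)
        labels = np.tile(np.arange(4), n_trials // 4)
        if signal_window is not None:
            patterns = rng.standard_normal((4, n_ch))
            patterns /= np.linalg.norm(patterns, axis=1, keepdims=True)
            lo, hi = signal_window
            data[:, :, lo:hi] += amp * patterns[labels][:, :, None]
        d = make_epoched(data, rate_hz=100.0, t0_ms=0.0)
        folds = []
        groups = np.arange(n_trials) // 4  # consecutive blocks of one trial per class
        for k in range(4):
            test = np.flatnonzero(groups % 4 == k)
            train = np.setdiff1d(np.arange(n_trials), test)
            folds.append(FoldSpec(train, test, labels[train], labels[test]))
        return d, folds

    def test_windowed_signal_localized_in_time(self, rng):
        d, folds = self._epoched(rng, signal_window=(30, 45), amp=8.0)
        tc = decode_timecourse(d, folds, shrinkage=0.05)
        assert tc.accuracy[32:43].mean() > 0.9
        outside = np.r_[tc.accuracy[:28], tc.accuracy[47:]]
        assert abs(outside.mean() - 0.25) < 0.1

    def test_pure_noise_stays_at_chance(self, rng):
        d, folds = self._epoched(rng)
        tc = decode_timecourse(d, folds, shrinkage=0.05)
        assert abs(tc.accuracy.mean() - 0.25) < 3 * tc.accuracy.std() / np.sqrt(len(tc.accuracy))

    def test_batched_engine_matches_per_timepoint_fit_predict(self, rng):
        """The vectorized decoder must agree exactly with looping fit_lda /
        predict_lda over timepoints (float64 single fits vs float32 batch)."""
        d, folds = self._epoched(rng, n_trials=16, n_ch=4, n_t=12, signal_window=(4, 9), amp=2.0)
        tc = decode_timecourse(d, folds, shrinkage=0.1)
        for t in range(d.n_times):
            accs = []
            for f in folds:
                model = fit_lda(d.data[f.train_idx, :, t], f.train_labels, shrinkage=0.1)
                pred = predict_lda(model, d.data[f.test_idx, :, t])
                accs.append((pred == f.test_labels).mean())
            assert tc.accuracy[t] == pytest.approx(np.mean(accs), abs=1e-5)

    def test_direct_dual_and_gram_paths_agree(self, small_cohort):
        d = small_cohort[0]
        folds = md.make_folds(d.trials, "material_uncontrolled", n_folds=5, seed=3)
        a = decode_timecourse(d, folds, method="direct").accuracy
        b = decode_timecourse(d, folds, method="dual").accuracy
        c = decode_timecourse(d, folds, method="gram", gram=compute_gram(d)).accuracy
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(a, c)

    def test_no_leakage_from_test_set(self, rng):
        """Reordering test trials cannot change accuracy."""
        d, folds = self._epoched(rng, signal_window=(10, 20), amp=3.0)
        tc1 = decode_timecourse(d, folds, shrinkage=0.05)
        shuffled = [
            FoldSpec(f.train_idx, f.test_idx[::-1], f.train_labels, f.test_labels[::-1])
            for f in folds
        ]
        tc2 = decode_timecourse(d, shuffled, shrinkage=0.05)
        np.testing.assert_allclose(tc1.accuracy, tc2.accuracy, atol=1e-12)

    def test_accuracy_nondecreasing_in_signal_amplitude(self):
        peaks = []
        for amp in (0.0, 1.0, 2.5, 6.0):
            rng = np.random.default_rng(77)  # same noise for every amplitude
            d, folds = self._epoched(rng, signal_window=(20, 40), amp=amp)
            tc = decode_timecourse(d, folds, shrinkage=0.05)
            peaks.append(tc.accuracy[25:35].mean())
        assert all(b >= a - 1e-12 for a, b in zip(peaks, peaks[1:]))

    def test_label_permutation_restores_chance(self, rng):
        d, folds = self._epoched(rng, signal_window=(10, 50), amp=4.0)
        permuted = []
        for f in folds:
            permuted.append(
                FoldSpec(f.train_idx, f.test_idx,
                         rng.permutation(f.train_labels), f.test_labels)
            )
        tc = decode_timecourse(d, permuted, shrinkage=0.05)
        se = tc.accuracy.std() / np.sqrt(len(tc.accuracy))
        assert abs(tc.accuracy.mean() - 0.25) < 3 * max(se, 0.01)

    def test_fold_referencing_missing_trials_rejected(self, rng):
        d, folds = self._epoched(rng, n_trials=16, n_ch=4, n_t=10)
        bad = FoldSpec(np.array([0, 1, 2, 3, 17]), np.array([4, 5]),
                       np.array([0, 1, 0, 1, 0]), np.array([0, 1]))
        with pytest.raises(IndexError):
            decode_timecourse(d, [bad], shrinkage=0.1)


class TestSmoothing:
    def _tc(self, values):
        v = np.asarray(values, dtype=float)
        return AccuracyTimecourse("s", "x", 10.0 * np.arange(len(v)), v, 1)

    def test_constant_series_unchanged(self):
        out = smooth_timecourse(self._tc(np.full(20, 0.4)))
        assert np.allclose(out.accuracy, 0.4)

    def test_impulse_with_shrinking_edges(self):
        out = smooth_timecourse(self._tc([0.0, 1.0, 0.0]))
        assert np.allclose(out.accuracy, [0.5, 1.0 / 3.0, 0.5])

    def test_mass_approximately_preserved(self, rng):
        v = rng.random(50)
        out = smooth_timecourse(self._tc(v))
        assert abs(out.accuracy.sum() - v.sum()) <= v.sum() * 3 / 50 + 1e-9

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_timecourse(self._tc(np.zeros(10)), window_points=4)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            smooth_timecourse(self._tc([0.1, 0.2]), window_points=3)
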