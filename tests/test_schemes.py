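"""Fold construction for all eight decoding schemes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import materialdecode as md
from materialdecode.schemes import (
    SCHEMES,
    chance_level,
    folds_expectation_xpair,
    folds_material_xobject,
    folds_object_xmaterial,
    folds_to_frame,
    folds_within,
    make_folds,
)
from materialdecode.synth import SynthConfig, build_design, video_table


def design(reps=40, targets=0.0, seed=0):
    return build_design(SynthConfig(reps_per_video=reps, target_fraction=targets), seed=seed)


VIDEO_INFO = video_table().set_index("video_id")


def fold_videos(trials, fold):
    return (
        set(trials["video_id"].to_numpy()[fold.train_idx]),
        set(trials["video_id"].to_numpy()[fold.test_idx]),
    )


class TestWithinFolds:
    def test_ninety_ten_split_counts(self):
        trials = design(reps=40)
        folds = folds_within(trials, "object_uncontrolled", n_folds=10, seed=1)
        assert len(folds) == 10
        for f in folds:
            assert len(f.test_idx) == 4 * 8  # 4 trials per video
            assert len(f.train_idx) == 36 * 8

    def test_test_sets_partition_all_trials(self):
        trials = design(reps=25)
        folds = folds_within(trials, "material_uncontrolled", n_folds=10, seed=2)
        test_union = np.concatenate([f.test_idx for f in folds])
        assert len(test_union) == len(set(test_union)) == len(trials)

    def test_video_expected_restricted_to_expected_videos(self):
        trials = design(reps=12)
        folds = folds_within(trials, SCHEMES["video_expected"], n_folds=10, seed=0)
        expected_vids = set(VIDEO_INFO.index[VIDEO_INFO["expectation"] == "expected"])
        for f in folds:
            tr, te = fold_videos(trials, f)
            assert tr == te == expected_vids
            assert set(np.unique(f.train_labels)) == expected_vids
        assert SCHEMES["video_expected"].n_classes == 4
        assert chance_level("video_expected") == 0.25

    def test_targets_never_enter_folds(self):
        trials = design(reps=12, targets=0.1)
        folds = folds_within(trials, "expectation_uncontrolled", n_folds=4, seed=0)
        is_target = trials["is_target"].to_numpy()
        for f in folds:
            assert not is_target[f.train_idx].any()
            assert not is_target[f.test_idx].any()

    def test_insufficient_trials_rejected(self):
        with pytest.raises(ValueError, match="need >="):
            folds_within(design(reps=5), "object_uncontrolled", n_folds=10, seed=0)

    @given(reps=st.integers(4, 20), n_folds=st.integers(2, 4), seed=st.integers(0, 50))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_stratified_chunks_differ_by_at_most_one(self, reps, n_folds, seed):
        if reps < n_folds:
            return
        trials = design(reps=reps)
        folds = folds_within(trials, "object_uncontrolled", n_folds=n_folds, seed=seed)
        vids = trials["video_id"].to_numpy()
        sizes = [np.bincount(vids[f.test_idx], minlength=9)[1:] for f in folds]
        sizes = np.array(sizes)
        assert sizes.max() - sizes.min() <= 1
        assert np.intersect1d(folds[0].train_idx, folds[0].test_idx).size == 0


class TestObjectAcrossMaterials:
    def test_sixteen_assignments(self):
        folds = folds_object_xmaterial(design(reps=4))
        assert len(folds) == 16

    def test_videos_disjoint_and_objects_on_both_sides(self):
        trials = design(reps=4)
        for f in folds_object_xmaterial(trials):
            tr, te = fold_videos(trials, f)
            assert not tr & te
            assert len(tr) == len(te) == 4
            assert set(VIDEO_INFO.loc[list(tr), "object"]) == set(md.synth.OBJECTS)
            assert set(VIDEO_INFO.loc[list(te), "object"]) == set(md.synth.OBJECTS)
            assert set(np.unique(f.train_labels)) == set(md.synth.OBJECTS)

    def test_complement_of_each_assignment_is_also_a_fold(self):
        """Both train-test directions live inside the 16-element enumeration."""
        trials = design(reps=4)
        folds = folds_object_xmaterial(trials)
        train_sets = [frozenset(fold_videos(trials, f)[0]) for f in folds]
        all_vids = frozenset(range(1, 9))
        for ts in train_sets:
            assert all_vids - ts in train_sets

    def test_missing_video_rejected(self):
        trials = design(reps=4)
        with pytest.raises(ValueError, match="missing"):
            folds_object_xmaterial(trials[trials["video_id"] != 3])


class TestMaterialAcrossObjects:
    def test_sixteen_folds_four_classes(self):
        folds = folds_material_xobject(design(reps=4))
        assert len(folds) == 16
        for f in folds:
            assert set(np.unique(f.train_labels)) == set(md.synth.MATERIALS)
        assert chance_level("material_xobject") == 0.25

    def test_expected_exhibitor_assignment_and_its_complement(self):
        """Training on each behavior's real-world exhibitor tests on the
        swapped exhibitor (glass shattering -> custard shattering etc.)."""
        trials = design(reps=4)
        folds = folds_material_xobject(trials)
        expected_side = frozenset(
            VIDEO_INFO.index[VIDEO_INFO["expectation"] == "expected"]
        )
        pairs = [fold_videos(trials, f) for f in folds]
        train_sets = [frozenset(tr) for tr, _ in pairs]
        assert expected_side in train_sets
        te = dict(zip(train_sets, [frozenset(t) for _, t in pairs]))[expected_side]
        assert te == frozenset(range(1, 9)) - expected_side

    def test_no_video_on_both_sides(self):
        trials = design(reps=4)
        for f in folds_material_xobject(trials):
            tr, te = fold_videos(trials, f)
            assert not tr & te


class TestExpectationAcrossPairs:
    def test_two_directed_folds(self):
        trials = design(reps=4)
        folds = folds_expectation_xpair(trials)
        assert len(folds) == 2
        pair_of = trials["pair"].to_numpy()
        assert set(pair_of[folds[0].train_idx]) == {"pair1"}
        assert set(pair_of[folds[0].test_idx]) == {"pair2"}
        assert set(pair_of[folds[1].train_idx]) == {"pair2"}

    def test_each_side_balanced_in_expectation(self):
        trials = design(reps=4)
        for f in folds_expectation_xpair(trials):
            for labels in (f.train_labels, f.test_labels):
                vals, counts = np.unique(labels, return_counts=True)
                assert set(vals) == {"expected", "unexpected"}
                assert counts[0] == counts[1]
        assert chance_level("expectation_xpair") == 0.5

    def test_missing_pair_rejected(self):
        trials = design(reps=4)
        with pytest.raises(ValueError, match="pair2"):
            folds_expectation_xpair(trials[trials["pair"] == "pair1"])


class TestRegistry:
    @pytest.mark.parametrize("name,chance", [
        ("object_uncontrolled", 0.25),
        ("material_xobject", 0.25),
        ("video_unexpected", 0.25),
        ("expectation_uncontrolled", 0.5),
        ("expectation_xpair", 0.5),
    ])
    def test_chance_levels(self, name, chance):
        assert chance_level(name) == chance
        assert SCHEMES[name].chance == chance

    def test_make_folds_dispatches_every_scheme(self):
        trials = design(reps=6)
        for name in SCHEMES:
            folds = make_folds(trials, name, n_folds=3, seed=0)
            assert folds, name

    def test_folds_depend_only_on_table_and_seed(self):
        trials = design(reps=6)
        a = make_folds(trials, "object_uncontrolled", n_folds=3, seed=9)
        b = make_folds(trials, "object_uncontrolled", n_folds=3, seed=9)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.train_idx, fb.train_idx)
            assert np.array_equal(fa.test_idx, fb.test_idx)

    def test_audit_table_covers_all_folds(self):
        trials = design(reps=4)
        folds = folds_expectation_xpair(trials)
        frame = folds_to_frame(folds)
        assert set(frame["fold"]) == {0, 1}
        assert set(frame["side"]) == {"train", "test"}
        assert len(frame) == sum(len(f.train_idx) + len(f.test_idx) for f in folds)
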