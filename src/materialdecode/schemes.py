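"""Train/test fold construction for the eight decoding schemes.

Folds are built from the trial table alone (never from EEG values), using
row *positions* into the analysis trial table, which must align with the
trial axis of the epoched array.

Within-video k-fold schemes partition each video's trials into near-equal
chunks; cross-generalization schemes keep whole videos on one side so that
train and test never share a stimulus:

- ``object_xmaterial``: train on one material behavior per object, test on
  the complementary behaviors (all 2^4 = 16 assignments; the enumeration
  contains both train/test directions since complementation is an
  involution on the set).
- ``material_xobject``: the mirror construction, one exhibiting object per
  material behavior (4-way by default; a pairwise 2-way reading of the same
  split can be had by restricting labels downstream).
- ``expectation_xpair``: train on one object/material pair, test on the
  other, both directions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import EXPECTED_MATERIAL, MATERIALS, OBJECTS, video_table


@dataclass(frozen=True)
class DecodingScheme:
    name: str
    label_column: str
    n_classes: int
    fold_kind: str  # 'within' | 'xmaterial' | 'xobject' | 'xpair'
    subset: str | None = None  # restrict to expected/unexpected videos

    @property
    def chance(self) -> float:
        return 1.0 / self.n_classes


SCHEMES: dict[str, DecodingScheme] = {
    s.name: s
    for s in [
        DecodingScheme("object_uncontrolled", "object", 4, "within"),
        DecodingScheme("object_xmaterial", "object", 4, "xmaterial"),
        DecodingScheme("material_uncontrolled", "material", 4, "within"),
        DecodingScheme("material_xobject", "material", 4, "xobject"),
        DecodingScheme("video_expected", "video_id", 4, "within", subset="expected"),
        DecodingScheme("video_unexpected", "video_id", 4, "within", subset="unexpected"),
        DecodingScheme("expectation_uncontrolled", "expectation", 2, "within"),
        DecodingScheme("expectation_xpair", "expectation", 2, "xpair"),
    ]
}


@dataclass
class FoldSpec:
    """One train/test split; indices are row positions into the trial table."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    train_labels: np.ndarray
    test_labels: np.ndarray

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test indices overlap")
        tr, te = set(np.unique(self.train_labels)), set(np.unique(self.test_labels))
        if tr != te:
            raise ValueError(f"class sets differ between sides: {tr} vs {te}")


def chance_level(scheme: str | DecodingScheme) -> float:
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    return scheme.chance


def _analysis(trials: pd.DataFrame) -> pd.DataFrame:
    if "is_target" in trials:
        return trials[~trials["is_target"].astype(bool)]
    return trials


def folds_within(
    trials: pd.DataFrame,
    scheme: str | DecodingScheme,
    n_folds: int = 10,
    seed: int | None = None,
) -> list[FoldSpec]:
    """Stratified k-fold within videos: each video's trials are shuffled and
    split into ``n_folds`` near-equal chunks; fold k tests on chunk k."""
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    tab = _analysis(trials)
    if scheme.subset is not None:
        tab = tab[tab["expectation"] == scheme.subset]
    rng = np.random.default_rng(seed)
    labels = trials[scheme.label_column].to_numpy()

    chunks_per_video = []
    for vid in sorted(tab["video_id"].unique()):
        pos = np.flatnonzero((trials["video_id"] == vid).to_numpy() & trials.index.isin(tab.index))
        if len(pos) < n_folds:
            raise ValueError(f"video {vid} has {len(pos)} trials; need >= {n_folds} for {n_folds}-fold")
        pos = pos[rng.permutation(len(pos))]
        chunks_per_video.append(np.array_split(pos, n_folds))

    folds = []
    for k in range(n_folds):
        test = np.sort(np.concatenate([ch[k] for ch in chunks_per_video]))
        train = np.sort(np.concatenate([c for ch in chunks_per_video for j, c in enumerate(ch) if j != k]))
        folds.append(FoldSpec(train, test, labels[train], labels[test]))
    return folds


def _video_split_folds(
    trials: pd.DataFrame, assignments: list[set[int]], label_column: str
) -> list[FoldSpec]:
    tab = _analysis(trials)
    present = set(tab["video_id"].unique())
    if present < set(range(1, 9)):
        raise ValueError(f"all 8 videos required; missing {sorted(set(range(1, 9)) - present)}")
    labels = trials[label_column].to_numpy()
    vid = trials["video_id"].to_numpy()
    in_analysis = trials.index.isin(tab.index)
    folds = []
    for train_videos in assignments:
        train = np.sort(np.flatnonzero(np.isin(vid, list(train_videos)) & in_analysis))
        test = np.sort(np.flatnonzero(~np.isin(vid, list(train_videos)) & in_analysis))
        folds.append(FoldSpec(train, test, labels[train], labels[test]))
    return folds


def folds_object_xmaterial(trials: pd.DataFrame, seed: int | None = None) -> list[FoldSpec]:
    """16 folds; each trains on one material behavior per object and tests on
    the complementary behaviors (object labels on both sides)."""
    vids = video_table()
    by_object = {o: vids.loc[vids["object"] == o, "video_id"].tolist() for o in OBJECTS}
    assignments = [
        {by_object[o][bit] for o, bit in zip(OBJECTS, bits)}
        for bits in itertools.product((0, 1), repeat=4)
    ]
    return _video_split_folds(trials, assignments, "object")


def folds_material_xobject(trials: pd.DataFrame, seed: int | None = None) -> list[FoldSpec]:
    """16 folds; each trains on one exhibiting object per material behavior
    and tests on the other exhibitor (material labels on both sides)."""
    vids = video_table()
    by_material = {m: vids.loc[vids["material"] == m, "video_id"].tolist() for m in MATERIALS}
    assignments = [
        {by_material[m][bit] for m, bit in zip(MATERIALS, bits)}
        for bits in itertools.product((0, 1), repeat=4)
    ]
    return _video_split_folds(trials, assignments, "material")


def folds_expectation_xpair(trials: pd.DataFrame) -> list[FoldSpec]:
    """Two folds: train on pair1 (chair/milk) videos and test on pair2
    (custard/glass) videos, and vice versa; expectation labels."""
    tab = _analysis(trials)
    labels = trials["expectation"].to_numpy()
    in_analysis = trials.index.isin(tab.index)
    pair = trials["pair"].to_numpy()
    for p in ("pair1", "pair2"):
        if not ((pair == p) & in_analysis).any():
            raise ValueError(f"no analysis trials for {p}")
    folds = []
    for train_pair, test_pair in (("pair1", "pair2"), ("pair2", "pair1")):
        train = np.sort(np.flatnonzero((pair == train_pair) & in_analysis))
        test = np.sort(np.flatnonzero((pair == test_pair) & in_analysis))
        folds.append(FoldSpec(train, test, labels[train], labels[test]))
    return folds


def make_folds(
    trials: pd.DataFrame,
    scheme: str | DecodingScheme,
    n_folds: int = 10,
    seed: int | None = None,
) -> list[FoldSpec]:
    """Build the fold list for any registered scheme."""
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    if scheme.fold_kind == "within":
        return folds_within(trials, scheme, n_folds=n_folds, seed=seed)
    if scheme.fold_kind == "xmaterial":
        return folds_object_xmaterial(trials, seed=seed)
    if scheme.fold_kind == "xobject":
        return folds_material_xobject(trials, seed=seed)
    if scheme.fold_kind == "xpair":
        return folds_expectation_xpair(trials)
    raise ValueError(f"unknown fold kind {scheme.fold_kind!r}")


def folds_to_frame(folds: list[FoldSpec]) -> pd.DataFrame:
    """Audit table: one row per (fold, side, trial)."""
    rows = []
    for k, f in enumerate(folds):
        for side, idx, lab in (("train", f.train_idx, f.train_labels), ("test", f.test_idx, f.test_labels)):
            for i, l in zip(idx, lab):
                rows.append({"fold": k, "side": side, "trial_pos": int(i), "label": l})
    return pd.DataFrame(rows)
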