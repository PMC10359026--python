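"""Simulation-based validation suites for the decoding pipeline.

Two suites characterize the pipeline on cohorts with known ground truth:

- :func:`null_calibration_suite` — cohorts with no injected effects.  For
  every decoding scheme it estimates the family-wise rate of reporting any
  post-onset significant interval (which FDR control across time should
  keep near or below alpha) and checks that grand-mean accuracy sits at
  the chance level.
- :func:`onset_recovery_suite` — cohorts with the default latency-
  controlled effects.  It measures how precisely the group analysis
  recovers each injected effect onset (object identity, pair-general
  expectation signal, unexpected-boost difference, object-general material
  signal) and whether the recovered latencies reproduce the expected
  cascade: expectation signal, then unexpected>expected enhancement, then
  cross-object material information.

Both suites run at deliberately reduced trial counts per participant so
that hundreds of replicate cohorts stay tractable on one CPU; the
participant count, channel count, and time grid match the full paradigm.
"""

from __future__ import annotations

import numpy as np

from .pipeline import decode_all
from .preprocess import preprocess
from .schemes import SCHEMES, chance_level
from .stats import paired_ttest, ttest_vs_chance
from .synth import SynthConfig, default_effects, simulate_cohort

#: injected ground-truth onsets (ms) of the default effect set and the
#: scheme/contrast that should recover each of them
RECOVERY_TARGETS = {
    "object_uncontrolled": 90.0,
    "expectation_xpair": 862.0,
    "unexpected_vs_expected": 902.0,
    "material_xobject": 952.0,
}

_RECOVERY_SCHEMES = [
    "object_uncontrolled",
    "expectation_xpair",
    "video_expected",
    "video_unexpected",
    "material_xobject",
]


def _null_cohort_kwargs(n_participants, reps_per_video):
    return dict(
        n_participants=n_participants,
        reps_per_video=reps_per_video,
        target_fraction=0.0,
        effects=[],
    )


def null_calibration_suite(
    n_cohorts: int = 200,
    n_participants: int = 25,
    reps_per_video: int = 4,
    n_folds: int = 2,
    alpha: float = 0.05,
    seed: int = 0,
    schemes: list[str] | None = None,
) -> dict[str, dict]:
    """False-positive calibration on pure-noise cohorts.

    Returns, per scheme: the number of replicate cohorts with at least one
    post-onset significant interval, the grand-mean accuracy across all
    participants and cohorts with its standard error, and the chance level.
    """
    schemes = list(SCHEMES) if schemes is None else schemes
    hits = {s: 0 for s in schemes}
    means: dict[str, list[float]] = {s: [] for s in schemes}
    for r in range(n_cohorts):
        cfg = SynthConfig(**_null_cohort_kwargs(n_participants, reps_per_video))
        cohort = [preprocess(d) for d in simulate_cohort(cfg, seed=seed + r)]
        accs = decode_all(cohort, schemes, n_folds=n_folds, seed=seed + n_cohorts + r)
        for s, tcs in accs.items():
            gs = ttest_vs_chance(tcs, chance=chance_level(s), alpha=alpha)
            hits[s] += bool(gs.intervals)
            means[s].extend(float(tc.accuracy.mean()) for tc in tcs)
    out = {}
    for s in schemes:
        m = np.asarray(means[s])
        out[s] = {
            "false_positive_cohorts": hits[s],
            "n_cohorts": n_cohorts,
            "family_wise_rate": hits[s] / n_cohorts,
            "mean_accuracy": float(m.mean()),
            "accuracy_se": float(m.std(ddof=1) / np.sqrt(m.size)),
            "chance": chance_level(s),
        }
    return out


def recover_onsets_one_cohort(
    seed: int,
    n_participants: int = 25,
    reps_per_video: int = 6,
    n_folds: int = 3,
    alpha: float = 0.05,
) -> dict[str, float | None]:
    """Detected primary onsets for the four injected effects, one cohort."""
    cfg = SynthConfig(
        n_participants=n_participants,
        reps_per_video=reps_per_video,
        target_fraction=0.0,
        effects=default_effects(),
    )
    cohort = [preprocess(d) for d in simulate_cohort(cfg, seed=seed)]
    accs = decode_all(cohort, _RECOVERY_SCHEMES, n_folds=n_folds, seed=seed + 1)
    onsets: dict[str, float | None] = {}
    for s in ("object_uncontrolled", "expectation_xpair", "material_xobject"):
        gs = ttest_vs_chance(accs[s], chance=chance_level(s), alpha=alpha)
        onsets[s] = gs.summary()["primary_onset_ms"]
    gs = paired_ttest(accs["video_unexpected"], accs["video_expected"], alpha=alpha)
    onsets["unexpected_vs_expected"] = gs.summary()["primary_onset_ms"]
    return onsets


def onset_recovery_suite(
    n_cohorts: int = 50,
    n_participants: int = 25,
    reps_per_video: int = 6,
    n_folds: int = 3,
    tolerance_ms: float = 30.0,
    seed: int = 0,
) -> dict:
    """Onset recovery and latency ordering over replicate effect cohorts.

    For each target, counts replicates whose detected onset lies within
    ``tolerance_ms`` of the injected onset; also counts replicates showing
    the full latency cascade (expectation before boost before material).
    """
    per_target: dict[str, list] = {k: [] for k in RECOVERY_TARGETS}
    ordering_hits = 0
    for r in range(n_cohorts):
        onsets = recover_onsets_one_cohort(
            seed=seed + 1000 * r,
            n_participants=n_participants,
            reps_per_video=reps_per_video,
            n_folds=n_folds,
        )
        for k in RECOVERY_TARGETS:
            per_target[k].append(onsets[k])
        o = onsets
        if (
            o["expectation_xpair"] is not None
            and o["unexpected_vs_expected"] is not None
            and o["material_xobject"] is not None
            and o["expectation_xpair"] < o["unexpected_vs_expected"] < o["material_xobject"]
        ):
            ordering_hits += 1
    out: dict = {"n_cohorts": n_cohorts, "ordering_fraction": ordering_hits / n_cohorts}
    for k, injected in RECOVERY_TARGETS.items():
        det = per_target[k]
        hits = sum(1 for v in det if v is not None and abs(v - injected) <= tolerance_ms)
        found = [v for v in det if v is not None]
        out[k] = {
            "injected_onset_ms": injected,
            "recovery_fraction": hits / n_cohorts,
            "median_detected_ms": float(np.median(found)) if found else None,
            "detected_onsets_ms": det,
        }
    return out
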