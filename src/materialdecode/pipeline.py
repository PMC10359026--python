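"""End-to-end orchestration: simulate -> preprocess -> decode -> group stats.

A single :class:`RunConfig` drives a deterministic run that writes, under
``out_dir``:

- ``accuracy_<scheme>.csv`` — tidy long table (participant, scheme, time_ms,
  accuracy), smoothed per participant;
- ``stats_<scheme>.csv`` / ``stats_<scheme>.json`` — per-timepoint group
  statistics and an interval/peak summary;
- ``comparison_<a>_vs_<b>.csv/.json`` — paired scheme contrasts;
- ``summary.json`` — one table over all schemes (chance, onset, intervals,
  peak t/d, impact-relative latencies);
- ``manifest.json`` — config, seed, and every output path.

Latencies are reported in ms relative to stimulus onset; the summary also
carries them relative to the impact (material reveal) for direct comparison
with impact-locked effect descriptions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mdio
from .decode import AccuracyTimecourse, decode_timecourse, smooth_timecourse
from .preprocess import PreprocessConfig, preprocess
from .schemes import SCHEMES, chance_level, make_folds
from .stats import GroupStats, paired_ttest, ttest_vs_chance
from .synth import EffectSpec, EpochedData, ParadigmSpec, SynthConfig, simulate_cohort

DEFAULT_SCHEMES = list(SCHEMES)


@dataclass
class RunConfig:
    paradigm: ParadigmSpec = field(default_factory=ParadigmSpec)
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    schemes: list[str] = field(default_factory=lambda: list(DEFAULT_SCHEMES))
    n_folds: int = 10
    shrinkage: float = 0.01
    smooth_points: int = 3
    alpha: float = 0.05
    min_run: int = 2
    onset_ms: float = 0.0
    comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: [("video_unexpected", "video_expected")]
    )
    seed: int = 0
    out_dir: str = "results/run"

    def __post_init__(self) -> None:
        unknown = [s for s in self.schemes if s not in SCHEMES]
        if unknown:
            raise ValueError(f"unknown schemes: {unknown}; known: {list(SCHEMES)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "paradigm" in kwargs:
            kwargs["paradigm"] = ParadigmSpec(**kwargs["paradigm"])
        if "synth" in kwargs:
            synth = dict(kwargs["synth"])
            if "effects" in synth:
                synth["effects"] = [EffectSpec(**e) for e in synth["effects"]]
            kwargs["synth"] = SynthConfig(**synth)
        if "preprocess" in kwargs:
            pp = dict(kwargs["preprocess"])
            for key in ("baseline_window_ms", "downsample_chain", "excluded_channels"):
                if key in pp:
                    pp[key] = tuple(pp[key])
            kwargs["preprocess"] = PreprocessConfig(**pp)
        if "comparisons" in kwargs:
            kwargs["comparisons"] = [tuple(c) for c in kwargs["comparisons"]]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    config: RunConfig
    out_dir: Path
    accuracies: dict[str, list[AccuracyTimecourse]]
    group_stats: dict[str, GroupStats]
    comparisons: dict[str, GroupStats]
    manifest: dict


def decode_cohort(
    cohort: list[EpochedData],
    scheme: str,
    n_folds: int = 10,
    shrinkage: float = 0.01,
    smooth_points: int = 3,
    seed: int = 0,
) -> list[AccuracyTimecourse]:
    """Per-participant smoothed accuracy time courses for one scheme."""
    tcs = []
    root = np.random.SeedSequence(seed)
    for d, ss in zip(cohort, root.spawn(len(cohort))):
        folds = make_folds(d.trials, scheme, n_folds=n_folds, seed=ss)
        tc = decode_timecourse(d, folds, shrinkage=shrinkage, scheme_name=scheme)
        if smooth_points > 1:
            tc = smooth_timecourse(tc, smooth_points)
        tcs.append(tc)
    return tcs


def decode_all(
    cohort: list[EpochedData],
    schemes: list[str],
    n_folds: int = 10,
    shrinkage: float = 0.01,
    smooth_points: int = 3,
    seed: int = 0,
) -> dict[str, list[AccuracyTimecourse]]:
    """Decode several schemes, sharing each participant's Gram tensor.

    Equivalent to calling :func:`decode_cohort` per scheme (same fold
    seeds), but amortizes the channel-dimension products across schemes.
    """
    from .decode import _GRAM_MAX_TRIALS, compute_gram

    out: dict[str, list[AccuracyTimecourse]] = {s: [] for s in schemes}
    roots = {s: np.random.SeedSequence(seed + 10_000 + i) for i, s in enumerate(schemes)}
    spawned = {s: r.spawn(len(cohort)) for s, r in roots.items()}
    for j, d in enumerate(cohort):
        gram = compute_gram(d) if d.n_trials <= _GRAM_MAX_TRIALS and shrinkage > 0 else None
        for s in schemes:
            folds = make_folds(d.trials, s, n_folds=n_folds, seed=spawned[s][j])
            tc = decode_timecourse(d, folds, shrinkage=shrinkage, scheme_name=s, gram=gram)
            if smooth_points > 1:
                tc = smooth_timecourse(tc, smooth_points)
            out[s].append(tc)
    return out


def compare_schemes(
    accuracies: dict[str, list[AccuracyTimecourse]],
    scheme_a: str,
    scheme_b: str,
    alpha: float = 0.05,
    min_run: int = 2,
    onset_ms: float = 0.0,
) -> GroupStats:
    """Paired two-sided comparison of two schemes' per-participant accuracies."""
    for s in (scheme_a, scheme_b):
        if s not in accuracies:
            raise KeyError(f"no accuracies for scheme {s!r}")
    return paired_ttest(
        accuracies[scheme_a],
        accuracies[scheme_b],
        alpha=alpha,
        min_run=min_run,
        onset_ms=onset_ms,
    )


def _tidy_frame(tcs: list[AccuracyTimecourse]) -> pd.DataFrame:
    rows = []
    for tc in tcs:
        rows.append(
            pd.DataFrame(
                {
                    "participant": tc.participant_id,
                    "scheme": tc.scheme,
                    "time_ms": tc.times_ms,
                    "accuracy": tc.accuracy,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def run_all(cfg: RunConfig, write_epochs: bool = False) -> RunReport:
    """Execute the full pipeline deterministically for one seed."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_times: dict[str, float] = {}
    outputs: dict[str, str] = {}

    t0 = time.perf_counter()
    cohort = simulate_cohort(cfg.synth, cfg.paradigm, seed=cfg.seed)
    stage_times["simulate"] = time.perf_counter() - t0
    if write_epochs:
        mdio.save_cohort(cohort, out_dir / "epochs")
        outputs["epochs"] = str(out_dir / "epochs")

    t0 = time.perf_counter()
    cohort = [preprocess(d, cfg.preprocess) for d in cohort]
    stage_times["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    accuracies = decode_all(
        cohort,
        cfg.schemes,
        n_folds=cfg.n_folds,
        shrinkage=cfg.shrinkage,
        smooth_points=cfg.smooth_points,
        seed=cfg.seed,
    )
    group: dict[str, GroupStats] = {}
    for scheme, tcs in accuracies.items():
        path = out_dir / f"accuracy_{scheme}.csv"
        _tidy_frame(tcs).to_csv(path, index=False)
        outputs[f"accuracy_{scheme}"] = str(path)
    stage_times["decode"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    for scheme, tcs in accuracies.items():
        gs = ttest_vs_chance(
            tcs,
            chance=chance_level(scheme),
            alpha=cfg.alpha,
            min_run=cfg.min_run,
            onset_ms=cfg.onset_ms,
        )
        group[scheme] = gs
        gs.to_frame().to_csv(out_dir / f"stats_{scheme}.csv", index=False)
        (out_dir / f"stats_{scheme}.json").write_text(json.dumps(gs.summary(), indent=2))
        outputs[f"stats_{scheme}"] = str(out_dir / f"stats_{scheme}.csv")

    comparisons: dict[str, GroupStats] = {}
    for a, b in cfg.comparisons:
        if a in accuracies and b in accuracies:
            gs = compare_schemes(accuracies, a, b, cfg.alpha, cfg.min_run, cfg.onset_ms)
            key = f"{a}_vs_{b}"
            comparisons[key] = gs
            gs.to_frame().to_csv(out_dir / f"comparison_{key}.csv", index=False)
            (out_dir / f"comparison_{key}.json").write_text(json.dumps(gs.summary(), indent=2))
            outputs[f"comparison_{key}"] = str(out_dir / f"comparison_{key}.csv")
    stage_times["stats"] = time.perf_counter() - t0

    impact = cfg.paradigm.impact_time_ms()
    summary = {"impact_time_ms": impact, "schemes": {}, "comparisons": {}}
    for scheme, gs in group.items():
        s = gs.summary()
        s["chance"] = chance_level(scheme)
        if s["onset_ms"] is not None:
            s["onset_rel_impact_ms"] = s["onset_ms"] - impact
        s["peak"]["time_rel_impact_ms"] = s["peak"]["time_ms"] - impact
        summary["schemes"][scheme] = s
    for key, gs in comparisons.items():
        s = gs.summary()
        if s["onset_ms"] is not None:
            s["onset_rel_impact_ms"] = s["onset_ms"] - impact
        summary["comparisons"][key] = s
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    outputs["summary"] = str(out_dir / "summary.json")

    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    manifest = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "stage_seconds": stage_times,
        "outputs": outputs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return RunReport(cfg, out_dir, accuracies, group, comparisons, manifest)
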