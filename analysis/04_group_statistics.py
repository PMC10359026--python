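#!/usr/bin/env python
"""Group-level inference on the decoding time courses.

Tests each scheme's accuracies against chance (one-sided t across
participants, BH-FDR across time, runs of >= 2 consecutive post-onset
timepoints), and writes per-timepoint stats plus a one-row-per-scheme
summary (onset, intervals, peak t and Cohen's d) to ``results/04_stats``.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from materialdecode.schemes import SCHEMES, chance_level
from materialdecode.stats import ttest_vs_chance
from materialdecode.synth import ParadigmSpec


def load_wide(path: Path):
    df = pd.read_csv(path)
    wide = df.pivot_table(index="participant", columns="time_ms", values="accuracy")
    return wide.to_numpy(), wide.columns.to_numpy(float)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in-dir", default="results/03_accuracy")
    ap.add_argument("--out-dir", default="results/04_stats")
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    impact = ParadigmSpec().impact_time_ms()
    rows = []
    for scheme in SCHEMES:
        path = Path(args.in_dir) / f"accuracy_{scheme}.csv"
        if not path.exists():
            continue
        acc, times = load_wide(path)
        gs = ttest_vs_chance(acc, chance=chance_level(scheme), times_ms=times,
                             alpha=args.alpha)
        gs.to_frame().to_csv(out / f"stats_{scheme}.csv", index=False)
        s = gs.summary()
        (out / f"stats_{scheme}.json").write_text(json.dumps(s, indent=2))
        rows.append({
            "scheme": scheme,
            "chance": chance_level(scheme),
            "onset_ms": s["primary_onset_ms"],
            "onset_rel_impact_ms": (
                s["primary_onset_ms"] - impact if s["primary_onset_ms"] is not None else None
            ),
            "peak_time_ms": gs.peak["time_ms"],
            "peak_t": round(gs.peak["t"], 2),
            "peak_d": round(gs.peak["d"], 2),
            "n_intervals": len(gs.intervals),
        })
    table = pd.DataFrame(rows)
    table.to_csv(out / "summary.csv", index=False)
    print(table.to_string(index=False))
    print(f"\nstats written to {out} (impact at {impact:.0f} ms)")


if __name__ == "__main__":
    main()
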