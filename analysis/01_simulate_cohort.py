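#!/usr/bin/env python
"""Simulate a synthetic EEG cohort for the material-expectation paradigm.

Generates a demo-scale cohort (12 participants, 8 repetitions of each of
the 8 videos plus ~10% target trials, 64 channels, 100 Hz, epochs -500 to
2800 ms) with the default latency-controlled effects, and writes it to
``results/01_epochs`` in the package's epoched container format.
"""

import argparse

from materialdecode import io as mdio
from materialdecode.synth import SynthConfig, simulate_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n-participants", type=int, default=12)
    ap.add_argument("--reps-per-video", type=int, default=8)
    ap.add_argument("--out-dir", default="results/01_epochs")
    args = ap.parse_args()

    cfg = SynthConfig(
        n_participants=args.n_participants,
        reps_per_video=args.reps_per_video,
        target_fraction=0.10,
    )
    cohort = simulate_cohort(cfg, seed=args.seed)
    ids = mdio.save_cohort(cohort, args.out_dir)
    d = cohort[0]
    n_targets = int(d.trials["is_target"].sum())
    print(f"wrote {len(ids)} participants to {args.out_dir}")
    print(
        f"each: {d.n_trials} trials ({n_targets} targets), {d.n_channels} channels, "
        f"{d.n_times} timepoints at {d.rate_hz:.0f} Hz "
        f"({d.times_ms[0]:.0f}..{d.times_ms[-1]:.0f} ms)"
    )
    print("injected effects:")
    for eff in cfg.effects:
        boost = f", x{1 + eff.boost_on_unexpected:.1f} on unexpected" if eff.boost_on_unexpected else ""
        print(f"  {eff.factor:12s} from {eff.onset_ms:6.0f} ms, amplitude {eff.amplitude}{boost}")


if __name__ == "__main__":
    main()
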