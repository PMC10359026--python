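#!/usr/bin/env python
"""Preprocess the simulated cohort to analysis-ready epochs.

Applies the deterministic chain (line-noise notch where resolvable,
average reference, decimation to 100 Hz, prestimulus baseline correction,
removal of target trials) and writes ``results/02_preprocessed``.
"""

import argparse

from materialdecode import io as mdio
from materialdecode.preprocess import PreprocessConfig, preprocess


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in-dir", default="results/01_epochs")
    ap.add_argument("--out-dir", default="results/02_preprocessed")
    args = ap.parse_args()

    cfg = PreprocessConfig()
    n_in = n_out = 0
    for pid in mdio.list_participants(args.in_dir):
        d = mdio.load_epoched(args.in_dir, pid)
        out = preprocess(d, cfg)
        mdio.save_epoched(out, args.out_dir)
        n_in, n_out = d.n_trials, out.n_trials
    print(f"preprocessed cohort written to {args.out_dir}")
    print(f"per participant: {n_in} -> {n_out} trials (targets removed), "
          f"baseline {cfg.baseline_window_ms} ms, average reference")


if __name__ == "__main__":
    main()
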