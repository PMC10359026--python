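"""On-disk container for epoched data.

One participant is stored as three files sharing a stem:

``<pid>_data.npy``
    float32 array of shape (n_trials, n_channels, n_timepoints), C order.
``<pid>_trials.csv``
    the trial table, one row per trial in array order, columns
    ``trial_index, video_id, object, material, expectation, pair, is_target``.
``<pid>_header.json``
    ``{"participant_id", "rate_hz", "times_ms", "channel_ids"}``.

The array file is bit-exact (``numpy.save``); CSV and JSON round-trip the
labels and axes exactly (times are written with full float precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import EpochedData

TRIAL_COLUMNS = ["trial_index", "video_id", "object", "material", "expectation", "pair", "is_target"]


def save_epoched(d: EpochedData, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = out_dir / d.participant_id
    paths = {
        "data": stem.with_name(stem.name + "_data.npy"),
        "trials": stem.with_name(stem.name + "_trials.csv"),
        "header": stem.with_name(stem.name + "_header.json"),
    }
    np.save(paths["data"], np.asarray(d.data, dtype=np.float32))
    d.trials[TRIAL_COLUMNS].to_csv(paths["trials"], index=False)
    header = {
        "participant_id": d.participant_id,
        "rate_hz": float(d.rate_hz),
        "times_ms": [float(t) for t in d.times_ms],
        "channel_ids": list(d.channel_ids),
    }
    paths["header"].write_text(json.dumps(header))
    return paths


def load_epoched(out_dir: str | Path, participant_id: str) -> EpochedData:
    stem = Path(out_dir) / participant_id
    header = json.loads(stem.with_name(stem.name + "_header.json").read_text())
    trials = pd.read_csv(stem.with_name(stem.name + "_trials.csv"))
    data = np.load(stem.with_name(stem.name + "_data.npy"))
    return EpochedData(
        participant_id=header["participant_id"],
        data=data,
        times_ms=np.asarray(header["times_ms"], dtype=float),
        rate_hz=header["rate_hz"],
        channel_ids=header["channel_ids"],
        trials=trials,
    )


def save_cohort(cohort: list[EpochedData], out_dir: str | Path) -> list[str]:
    ids = []
    for d in cohort:
        save_epoched(d, out_dir)
        ids.append(d.participant_id)
    return ids


def list_participants(out_dir: str | Path) -> list[str]:
    return sorted(p.name[: -len("_header.json")] for p in Path(out_dir).glob("*_header.json"))


def load_cohort(out_dir: str | Path) -> list[EpochedData]:
    return [load_epoched(out_dir, pid) for pid in list_participants(out_dir)]
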