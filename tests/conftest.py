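import numpy as np
import pandas as pd
import pytest

from materialdecode.synth import EpochedData, video_table


def make_epoched(
    data: np.ndarray,
    rate_hz: float = 100.0,
    t0_ms: float = -500.0,
    trials: pd.DataFrame | None = None,
    participant_id: str = "sub-01",
) -> EpochedData:
    """Wrap a raw array into an EpochedData with a simple trial table."""
    n_trials, n_ch, n_t = data.shape
    if trials is None:
        vids = video_table()
        rows = vids.iloc[np.arange(n_trials) % 8].reset_index(drop=True)
        rows["is_target"] = False
        rows.insert(0, "trial_index", np.arange(n_trials))
        trials = rows
    times = t0_ms + (1000.0 / rate_hz) * np.arange(n_t)
    chans = [f"ch{i + 1:02d}" for i in range(n_ch)]
    return EpochedData(participant_id, data, times, rate_hz, chans, trials)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """Two preprocessed participants with the default effects, tiny trial counts."""
    import materialdecode as md

    cfg = md.SynthConfig(n_participants=2, reps_per_video=5, target_fraction=0.0, seed=99)
    return [md.preprocess(d) for d in md.simulate_cohort(cfg, seed=99)]
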