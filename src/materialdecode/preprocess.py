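"""Deterministic preprocessing from source-rate epochs to analysis epochs.

Chain order (each step optional per config): 50 Hz band-stop -> average
reference -> downsampling chain -> baseline correction -> trial/channel
selection.  No high- or low-pass filtering is applied anywhere: integer-rate
reduction uses block averaging, and the band-stop notch is the only
frequency-selective operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import signal

from .synth import EpochedData


@dataclass
class PreprocessConfig:
    baseline_window_ms: tuple[float, float] = (-500.0, 0.0)
    notch_hz: float | None = 50.0
    downsample_chain: tuple[float, ...] = (200.0, 100.0)
    excluded_channels: tuple[str, ...] = ()
    drop_target_trials: bool = True
    #: metadata: baseline is computed after re-referencing (fixed order)
    baseline_after_rereference: bool = True


def rereference_average(d: EpochedData) -> EpochedData:
    """Re-express each channel relative to the mean over all channels."""
    if d.n_channels < 2:
        raise ValueError("average reference requires >= 2 channels")
    data = d.data - d.data.mean(axis=1, keepdims=True)
    return d.copy_with(data=data)


def baseline_correct(d: EpochedData, window_ms: tuple[float, float] = (-500.0, 0.0)) -> EpochedData:
    """Subtract each trial/channel's mean over the (inclusive) baseline window."""
    lo, hi = window_ms
    mask = (d.times_ms >= lo) & (d.times_ms <= hi)
    if not mask.any():
        raise ValueError(f"baseline window [{lo}, {hi}] ms contains no samples")
    base = d.data[:, :, mask].mean(axis=2, keepdims=True)
    return d.copy_with(data=d.data - base)


def downsample(d: EpochedData, target_rate_hz: float) -> EpochedData:
    """Reduce the sampling rate by block averaging (integer factors only).

    Each output sample is the mean of ``rate/target`` consecutive input
    samples and carries the time stamp of the first sample in its block.
    Trailing samples that do not fill a block are dropped.
    """
    ratio = d.rate_hz / target_rate_hz
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise ValueError(
            f"target rate {target_rate_hz} Hz does not divide current rate {d.rate_hz} Hz; "
            "use resample_to() for rational ratios"
        )
    if factor == 1:
        return d
    n_blocks = d.n_times // factor
    data = d.data[:, :, : n_blocks * factor]
    data = data.reshape(d.n_trials, d.n_channels, n_blocks, factor).mean(axis=3)
    times = d.times_ms[: n_blocks * factor : factor]
    return d.copy_with(data=data, times_ms=times, rate_hz=target_rate_hz)


def resample_to(d: EpochedData, target_rate_hz: float) -> EpochedData:
    """Polyphase resampling for rational, non-integer rate ratios (e.g. 500->200)."""
    from fractions import Fraction

    frac = Fraction(target_rate_hz / d.rate_hz).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(d.data, up, down, axis=2)
    step = 1000.0 / target_rate_hz
    times = d.times_ms[0] + step * np.arange(data.shape[2])
    return d.copy_with(data=data, times_ms=times, rate_hz=target_rate_hz)


def notch_filter(d: EpochedData, freq_hz: float = 50.0, half_width_hz: float = 2.0) -> EpochedData:
    """Zero-phase second-order band-stop around ``freq_hz``."""
    nyq = d.rate_hz / 2.0
    if freq_hz >= nyq:
        raise ValueError(f"notch frequency {freq_hz} Hz is at or above Nyquist ({nyq} Hz)")
    lo = (freq_hz - half_width_hz) / nyq
    hi = min((freq_hz + half_width_hz) / nyq, 0.999)
    b, a = signal.butter(2, [lo, hi], btype="bandstop")
    data = signal.filtfilt(b, a, d.data, axis=2)
    return d.copy_with(data=data)


def select_analysis_trials(
    d: EpochedData,
    excluded_channels: tuple[str, ...] = (),
    drop_target_trials: bool = True,
) -> EpochedData:
    """Drop target (luminance-dim) trials and excluded channels."""
    keep_trials = np.ones(d.n_trials, dtype=bool)
    if drop_target_trials and "is_target" in d.trials:
        keep_trials = ~d.trials["is_target"].to_numpy(dtype=bool)
    keep_ch = np.array([c not in set(excluded_channels) for c in d.channel_ids])
    if not keep_trials.any():
        warnings.warn("no analysis trials remain after selection", stacklevel=2)
    data = d.data[keep_trials][:, keep_ch]
    return d.copy_with(
        data=data,
        channel_ids=[c for c, k in zip(d.channel_ids, keep_ch) if k],
        trials=d.trials.loc[keep_trials].reset_index(drop=True),
    )


def preprocess(d: EpochedData, cfg: PreprocessConfig | None = None) -> EpochedData:
    """Run the full chain.

    The notch is applied only when the line frequency is resolvable (below
    Nyquist at the current rate); data generated directly on the 100 Hz
    analysis grid therefore skip it.  Downsampling stages use block
    averaging for integer factors and polyphase resampling otherwise.
    """
    cfg = cfg or PreprocessConfig()
    if cfg.notch_hz is not None and cfg.notch_hz < d.rate_hz / 2.0:
        d = notch_filter(d, cfg.notch_hz)
    d = rereference_average(d)
    for target in cfg.downsample_chain:
        if target >= d.rate_hz:
            continue
        ratio = d.rate_hz / target
        if abs(ratio - round(ratio)) < 1e-9:
            d = downsample(d, target)
        else:
            d = resample_to(d, target)
    d = baseline_correct(d, cfg.baseline_window_ms)
    return select_analysis_trials(d, cfg.excluded_channels, cfg.drop_target_trials)
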