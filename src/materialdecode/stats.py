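"""Group-level inference on decoding-accuracy time courses.

Per timepoint, decoding accuracy is tested against chance with a one-sided
one-sample t test across participants (paired two-sided t tests for scheme
comparisons).  p values are corrected across time with the
Benjamini-Hochberg false-discovery-rate step-up (Benjamini-Yekutieli by
flag), and only timepoints after stimulus onset that belong to a run of at
least ``min_run`` consecutive significant timepoints are reported.  Effect
sizes use the one-sample convention d = t / sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def cohens_d_from_t(t: float | np.ndarray, n: int) -> float | np.ndarray:
    """One-sample effect size d = t / sqrt(n)."""
    return t / np.sqrt(n)


@dataclass
class GroupStats:
    times_ms: np.ndarray
    mean: np.ndarray  # group mean of the tested quantity (accuracy or difference)
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    sig: np.ndarray  # after FDR, onset and run rules
    intervals: list[tuple[float, float]]
    peak: dict
    n_participants: int
    sidedness: str
    alpha: float
    min_run: int
    onset_ms: float
    baseline: float  # chance level (one-sample) or 0 (paired difference)
    zero_variance: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.times_ms,
                "mean": self.mean,
                "t": self.t,
                "p": self.p,
                "q": self.q,
                "sig": self.sig,
            }
        )

    def primary_interval(self, gap_ms: float = 30.0) -> tuple[float, float] | None:
        """The (gap-merged) significant interval containing the peak.

        Isolated short runs can survive FDR by chance when a strong effect
        elevates the step-up threshold, so the interval holding the peak t
        is the robust summary of where the effect lives; its start is the
        reported effect onset.  Before selecting it, runs separated by
        gaps no longer than ``gap_ms`` are merged: the accuracy time
        courses are smoothed with a 30 ms moving average, so interruptions
        narrower than that window are not resolved features.  The raw
        ``intervals`` list is reported unmerged.
        """
        merged: list[list[float]] = []
        for a, b in self.intervals:
            if merged and a - merged[-1][1] <= gap_ms:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        pt = self.peak["time_ms"]
        for a, b in merged:
            if a <= pt <= b:
                return (a, b)
        return tuple(merged[0]) if merged else None

    def summary(self) -> dict:
        primary = self.primary_interval()
        return {
            "n_participants": self.n_participants,
            "sidedness": self.sidedness,
            "alpha": self.alpha,
            "min_run": self.min_run,
            "baseline": self.baseline,
            "intervals_ms": [[float(a), float(b)] for a, b in self.intervals],
            "onset_ms": float(self.intervals[0][0]) if self.intervals else None,
            "primary_interval_ms": list(primary) if primary else None,
            "primary_onset_ms": float(primary[0]) if primary else None,
            "peak": self.peak,
        }


def _tstats(diffs: np.ndarray, sided: str):
    """t, p per column of (n, T) differences; zero-variance columns flagged.

    With zero variance the t statistic is +/-inf (0 when the mean is also
    0), so the one-sided p is 0, 1, or 0.5 accordingly.
    """
    n, _ = diffs.shape
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(
        zero_var,
        np.where(mean > 0, np.inf, np.where(mean < 0, -np.inf, 0.0)),
        t,
    )
    df = n - 1
    if sided == "one":
        p = sps.t.sf(t, df)
    elif sided == "two":
        p = 2.0 * sps.t.sf(np.abs(t), df)
    else:
        raise ValueError("sidedness must be 'one' or 'two'")
    return mean, t, np.clip(p, 0.0, 1.0), zero_var


def fdr_correct(p: np.ndarray, alpha: float = 0.05, method: str = "bh"):
    """Benjamini-Hochberg (or -Yekutieli) adjusted p values and raw flags."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    sig_raw, q, _, _ = multipletests(p, alpha=alpha, method=sm_method)
    return q, sig_raw


def apply_selection_rules(
    sig_raw: np.ndarray,
    times_ms: np.ndarray,
    min_run: int = 2,
    onset_ms: float = 0.0,
):
    """Drop pre-onset timepoints and runs shorter than ``min_run``; return the
    final flags and the [first, last] ms interval of each surviving run."""
    sig_raw = np.asarray(sig_raw, dtype=bool)
    times_ms = np.asarray(times_ms, dtype=float)
    keep = sig_raw & (times_ms >= onset_ms)
    sig = np.zeros_like(keep)
    intervals: list[tuple[float, float]] = []
    i = 0
    n = len(keep)
    while i < n:
        if keep[i]:
            j = i
            while j + 1 < n and keep[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                sig[i : j + 1] = True
                intervals.append((float(times_ms[i]), float(times_ms[j])))
            i = j + 1
        else:
            i += 1
    return sig, intervals


def peak_stats(times_ms: np.ndarray, t: np.ndarray, sig: np.ndarray, n: int) -> dict:
    """Peak = timepoint of maximum t within significant intervals; falls back
    to the global maximum (flagged) when nothing is significant."""
    t = np.asarray(t, dtype=float)
    finite = np.where(np.isfinite(t), t, -np.inf)
    if sig.any():
        cand = np.where(sig, finite, -np.inf)
        in_sig = True
    else:
        cand = finite
        in_sig = False
    k = int(np.argmax(cand))
    tk = float(t[k])
    return {
        "time_ms": float(times_ms[k]),
        "t": tk,
        "d": float(cohens_d_from_t(tk, n)) if np.isfinite(tk) else float("inf") * np.sign(tk),
        "within_significant": in_sig,
    }


def _stack(tcs) -> tuple[np.ndarray, np.ndarray]:
    """Stack a list of AccuracyTimecourse-likes sharing one time grid."""
    first = tcs[0]
    times = np.asarray(first.times_ms, dtype=float)
    rows = []
    for tc in tcs:
        if not np.array_equal(np.asarray(tc.times_ms, dtype=float), times):
            raise ValueError("all time courses must share the same time grid")
        rows.append(np.asarray(tc.accuracy, dtype=float))
    return np.vstack(rows), times


def ttest_vs_chance(
    tcs,
    chance: float,
    times_ms: np.ndarray | None = None,
    sided: str = "one",
    alpha: float = 0.05,
    min_run: int = 2,
    onset_ms: float = 0.0,
    fdr_method: str = "bh",
) -> GroupStats:
    """One-sample t of (accuracy - chance) per timepoint, FDR across time.

    ``tcs`` is a list of per-participant time courses (shared grid) or a
    (n_participants, T) array with ``times_ms`` given explicitly.
    """
    if isinstance(tcs, np.ndarray):
        acc = np.asarray(tcs, dtype=float)
        if times_ms is None:
            raise ValueError("times_ms required with array input")
        times = np.asarray(times_ms, dtype=float)
    else:
        acc, times = _stack(tcs)
    n = acc.shape[0]
    if n < 2:
        raise ValueError("need >= 2 participants")
    mean_diff, t, p, zero_var = _tstats(acc - chance, sided)
    q, sig_raw = fdr_correct(p, alpha=alpha, method=fdr_method)
    sig, intervals = apply_selection_rules(sig_raw, times, min_run=min_run, onset_ms=onset_ms)
    peak = peak_stats(times, t, sig, n)
    return GroupStats(
        times_ms=times,
        mean=mean_diff + chance,
        t=t,
        p=p,
        q=q,
        sig=sig,
        intervals=intervals,
        peak=peak,
        n_participants=n,
        sidedness=sided,
        alpha=alpha,
        min_run=min_run,
        onset_ms=onset_ms,
        baseline=chance,
        zero_variance=zero_var,
    )


def paired_ttest(
    tcs_a,
    tcs_b,
    times_ms: np.ndarray | None = None,
    sided: str = "two",
    alpha: float = 0.05,
    min_run: int = 2,
    onset_ms: float = 0.0,
    fdr_method: str = "bh",
) -> GroupStats:
    """Paired t on (a - b) per timepoint; participants must match in order."""
    if isinstance(tcs_a, np.ndarray):
        a, b = np.asarray(tcs_a, float), np.asarray(tcs_b, float)
        if times_ms is None:
            raise ValueError("times_ms required with array input")
        times = np.asarray(times_ms, dtype=float)
    else:
        ids_a = [tc.participant_id for tc in tcs_a]
        ids_b = [tc.participant_id for tc in tcs_b]
        if ids_a != ids_b:
            raise ValueError(f"participant mismatch: {ids_a} vs {ids_b}")
        a, times = _stack(tcs_a)
        b, _ = _stack(tcs_b)
    if a.shape != b.shape:
        raise ValueError("conditions must have matching participants and grids")
    if a.shape[0] < 2:
        raise ValueError("need >= 2 participants")
    n = a.shape[0]
    mean_diff, t, p, zero_var = _tstats(a - b, sided)
    q, sig_raw = fdr_correct(p, alpha=alpha, method=fdr_method)
    sig, intervals = apply_selection_rules(sig_raw, times, min_run=min_run, onset_ms=onset_ms)
    peak = peak_stats(times, t, sig, n)
    return GroupStats(
        times_ms=times,
        mean=mean_diff,
        t=t,
        p=p,
        q=q,
        sig=sig,
        intervals=intervals,
        peak=peak,
        n_participants=n,
        sidedness=sided,
        alpha=alpha,
        min_run=min_run,
        onset_ms=onset_ms,
        baseline=0.0,
        zero_variance=zero_var,
    )
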