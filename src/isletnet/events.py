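"""Oscillation detection, binarization and classical activity parameters.

An oscillation is delimited by its *onset* (a significant positive excursion
of the smoothed derivative, refined back to the preceding local minimum of
the trace), its *peak* (maximum between onset and the next onset) and its
*end* (the first point after the peak where the signal decays to 50% of the
oscillation amplitude above the local inter-oscillation baseline, sub-sample
interpolated).
Measuring the half level relative to the local baseline makes the rule
invariant to additive offsets, so it behaves identically on raw pulses and on
band-passed, zero-mean signals; for a pulse rising from zero it coincides
with "50% of the maximum".

All detection thresholds are expressed in robust units of the trace itself
(median absolute deviations), so detection is invariant to amplitude
rescaling, and in seconds, so defaults transfer across sampling rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d


@dataclass(frozen=True)
class Oscillation:
    """One detected oscillation; times in seconds on the recording clock."""

    onset: float
    peak_time: float
    peak_value: float
    end: float
    base_value: float = 0.0
    censored: bool = False  # end capped at the recording end

    def __post_init__(self) -> None:
        if not (self.onset < self.peak_time <= self.end):
            raise ValueError("need onset < peak_time <= end")

    @property
    def duration(self) -> float:
        return self.end - self.onset

    @property
    def amplitude(self) -> float:
        return self.peak_value - self.base_value


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def detect_oscillations(
    trace: np.ndarray,
    fs: float,
    t0: float = 0.0,
    slope_k: float = 3.0,
    smooth_s: float = 0.3,
    min_prominence: float | None = None,
    min_prominence_mads: float = 2.0,
    lookback_s: float = 1.0,
    base_lookback_s: float = 10.0,
) -> list[Oscillation]:
    """Detect oscillations in a single trace.

    Parameters
    ----------
    trace : 1-D signal (band-passed for plateau analysis, or F/F0 for slow
        activation transients — the detector only assumes a locally flat
        baseline between oscillations).
    fs : sampling frequency (Hz).
    t0 : time of the first sample (s).
    slope_k : onset threshold on the smoothed derivative, in robust standard
        deviations (MAD-scaled) of the derivative.
    smooth_s : moving-average window for the derivative, in seconds.
    min_prominence : absolute minimum oscillation amplitude; when ``None`` it
        is ``min_prominence_mads`` robust standard deviations of the trace.
    lookback_s : how far behind the derivative crossing to search for the
        trace minimum that defines the onset.
    base_lookback_s : how far behind the onset (bounded by the previous
        oscillation's end) to search for the inter-oscillation minimum that
        defines the local baseline of the oscillation.

    Returns an onset-sorted list of non-overlapping :class:`Oscillation`.
    A flat trace yields an empty list.
    """
    x = np.asarray(trace, dtype=float)
    n = x.size
    if fs <= 0:
        raise ValueError("fs must be positive")
    if n < 3:
        return []

    w = max(int(round(smooth_s * fs)), 1)
    # the smoothed copy supports baseline/peak/level decisions; the moving
    # average is zero-phase, so event times are not shifted
    xs = uniform_filter1d(x, size=w, mode="nearest") if w > 1 else x
    d = np.gradient(x) * fs
    ds = uniform_filter1d(d, size=w, mode="nearest") if w > 1 else d

    dmax = float(np.max(np.abs(ds)))
    thr = max(slope_k * 1.4826 * _mad(ds), 0.05 * dmax)
    above = ds > thr if thr > 0 else ds > 0
    cross = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        cross = np.concatenate([[0], cross])
    if cross.size == 0:
        return []

    # refine each crossing back to the last local minimum of the trace,
    # then forward across any flat (sub-threshold-slope) stretch, so the
    # onset lands on the first genuinely rising sample
    lb = max(int(round(lookback_s * fs)), 1)
    onsets_i: list[int] = []
    for c in cross:
        j0 = max(c - lb, 0)
        seg = xs[j0 : c + 1]
        k = len(seg) - 1 - int(np.argmin(seg[::-1]))  # last index of the min
        oi = j0 + k
        # walk forward across the flat/shallow stretch until the rise reaches
        # a fixed fraction of this event's peak slope, so the onset lands on
        # the true rise corner rather than on filter-smeared foothills
        smax = float(np.max(ds[j0 : min(c + lb, n)]))
        thr_walk = max(0.3 * smax, 0.3 * thr)
        while oi < n - 1 and (x[oi + 1] - x[oi]) * fs < thr_walk:
            oi += 1
        if not onsets_i or oi > onsets_i[-1]:
            onsets_i.append(oi)

    amp_scale = 1.4826 * _mad(x)
    min_prom = (
        min_prominence if min_prominence is not None
        else min_prominence_mads * amp_scale
    )

    events: list[Oscillation] = []
    blb = max(int(round(base_lookback_s * fs)), 1)
    k = 0
    while k < len(onsets_i):
        oi = onsets_i[k]
        if events and t0 + oi / fs < events[-1].end:
            k += 1
            continue
        nxt0 = onsets_i[k + 1] if k + 1 < len(onsets_i) else n
        if nxt0 <= oi + 1:
            k += 1
            continue
        # local baseline: minimum over the inter-oscillation stretch before
        # the onset (never reaching into the previous oscillation)
        b0 = max(oi - blb, 0)
        if events:
            b0 = max(b0, int(round((events[-1].end - t0) * fs)))
        base = float(np.min(xs[min(b0, oi) : oi + 1]))
        if float(np.max(xs[oi:nxt0])) - base < min_prom:
            k += 1  # sub-threshold wiggle, not an oscillation
            continue
        # grow the event region across subsequent onsets until the signal
        # has decayed to the half-amplitude level: an oscillation only ends
        # at 50% decay, so an intervening derivative crossing is not a new
        # oscillation
        m = k + 1
        while True:
            nxt = onsets_i[m] if m < len(onsets_i) else n
            # the peak is the raw maximum; the smoothed copy only supports
            # the baseline estimate and the decay-crossing search
            pi = max(oi + int(np.argmax(x[oi:nxt])), oi + 1)
            peak = float(x[pi])
            level = base + 0.5 * (peak - base)
            end_t, found = _half_decay_time(xs, fs, pi, nxt, level)
            if found or m >= len(onsets_i):
                censored = not found
                events.append(
                    Oscillation(
                        onset=t0 + oi / fs,
                        peak_time=t0 + pi / fs,
                        peak_value=peak,
                        end=t0 + end_t,
                        base_value=base,
                        censored=censored,
                    )
                )
                k = m
                break
            m += 1
    return events


def _half_decay_time(
    x: np.ndarray, fs: float, pi: int, nxt: int, level: float
) -> tuple[float, bool]:
    """First time after the peak where the signal crosses ``level``,
    linearly interpolated.  Returns (time, crossing-found)."""
    n = x.size
    stop = min(nxt + 1, n)
    seg = x[pi:stop]
    below = np.flatnonzero(seg <= level)
    below = below[below > 0]
    if below.size:
        j = pi + int(below[0])
        x0, x1 = x[j - 1], x[j]
        frac = (x0 - level) / (x0 - x1) if x0 != x1 else 0.0
        return (j - 1 + frac) / fs, True
    return (n - 1) / fs, False


def binarize(
    events: list[Oscillation], n_samples: int, fs: float, t0: float = 0.0
) -> np.ndarray:
    """Binary activity vector: 1 on each [onset, end) interval, 0 between.

    Each event contributes exactly ``round(duration * fs)`` ones, so the sum
    of the vector equals the rounded total event length — the property the
    active-time parameter relies on.
    """
    b = np.zeros(n_samples, dtype=np.int8)
    t_end = t0 + n_samples / fs
    for ev in events:
        if ev.onset < t0 - 0.5 / fs or ev.end > t_end + 0.5 / fs:
            raise ValueError(
                f"event [{ev.onset}, {ev.end}) s lies outside the trace"
            )
        i0 = int(round((ev.onset - t0) * fs))
        cnt = int(round((ev.end - ev.onset) * fs))
        i0 = max(i0, 0)
        b[i0 : min(i0 + cnt, n_samples)] = 1
    return b


@dataclass(frozen=True)
class CellParams:
    """Classical per-cell activity parameters over an analysis window."""

    frequency: float  # onsets per second (Hz)
    mean_duration: float  # mean oscillation length (s)
    active_time: float  # fraction of the window spent active
    n_oscillations: int = 0


def classical_params(
    events: list[Oscillation],
    window: tuple[float, float],
    fs: float,
    mode: str = "binary",
    trace: np.ndarray | None = None,
    t0: float = 0.0,
) -> CellParams:
    """Frequency, mean duration and relative active time over ``window``.

    frequency = (number of onsets in the window) / window length;
    mean_duration averages end - onset over those oscillations; active_time
    is the fraction of window samples inside a binarized [onset, end)
    interval.  ``mode="above_half"`` instead counts samples where the trace
    exceeds the oscillation's half-amplitude level (requires ``trace``).
    """
    a, b = window
    if b <= a:
        raise ValueError("analysis window must have positive length")
    length = b - a
    in_win = [ev for ev in events if a <= ev.onset < b]
    freq = len(in_win) / length
    mean_dur = float(np.mean([ev.duration for ev in in_win])) if in_win else np.nan

    n_win = int(round(length * fs))
    active_samples = 0
    for ev in events:
        lo, hi = max(ev.onset, a), min(ev.end, b)
        if hi <= lo:
            continue
        if mode == "binary":
            active_samples += int(round((hi - lo) * fs))
        elif mode == "above_half":
            if trace is None:
                raise ValueError("mode='above_half' requires the trace")
            i0 = int(round((lo - t0) * fs))
            i1 = int(round((hi - t0) * fs))
            level = ev.base_value + 0.5 * ev.amplitude
            active_samples += int(np.sum(trace[i0:i1] >= level))
        else:
            raise ValueError(f"unknown active-time mode {mode!r}")
    at = min(active_samples / n_win, 1.0) if n_win else np.nan
    return CellParams(freq, mean_dur, at, len(in_win))


def events_to_frame(
    events_by_cell: dict[str, list[Oscillation]], islet_id: str = "islet"
) -> pd.DataFrame:
    """Flatten per-cell event lists into a tidy table."""
    rows = [
        {
            "islet_id": islet_id,
            "cell_id": cid,
            "onset_s": ev.onset,
            "peak_s": ev.peak_time,
            "end_s": ev.end,
            "peak_value": ev.peak_value,
            "censored": ev.censored,
        }
        for cid, evs in events_by_cell.items()
        for ev in evs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "islet_id", "cell_id", "onset_s", "peak_s", "end_s",
            "peak_value", "censored",
        ],
    )
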