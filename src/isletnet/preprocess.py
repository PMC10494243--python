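"""Trace preprocessing: F/F0 normalization, photobleaching correction,
artifact-based cell exclusion, and zero-phase band-pass filtering.

The pipeline order is normalize -> de-bleach -> exclude -> band-pass.  The
band-passed signal feeds oscillation detection and network construction; the
de-bleached F/F0 signal is kept for delay analysis, where the slow activation
transient must survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .protocol import Protocol
from .traces import TraceSet

log = logging.getLogger(__name__)


def _mad_sigma(x: np.ndarray) -> float:
    """Robust standard deviation via the median absolute deviation."""
    x = np.asarray(x, dtype=float)
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


# --------------------------------------------------------------------------
# F/F0 normalization
# --------------------------------------------------------------------------

def default_baseline_window(
    protocol: Protocol, length_s: float = 60.0
) -> tuple[float, float]:
    """First ``length_s`` seconds of the initial substimulatory segment."""
    seg = protocol.segments[0]
    if seg.active:
        raise ValueError("protocol does not start with an inactive segment")
    return (seg.start, min(seg.start + length_s, seg.end))


def normalize_f0(
    traces: TraceSet, baseline_window: tuple[float, float] | None = None
) -> TraceSet:
    """Express each trace as F/F0, with F0 the mean over a baseline window.

    The window must lie inside an inactive (substimulatory) protocol
    segment — normalizing against stimulated activity would be meaningless.
    """
    if baseline_window is None:
        baseline_window = default_baseline_window(traces.protocol)
    a, b = baseline_window
    if b <= a:
        raise ValueError("baseline window must have positive length")
    if a < traces.t0 - 1e-9 or b > traces.t_end + 1e-9:
        raise ValueError("baseline window lies outside the recording")
    seg = traces.protocol.segment_at(a)
    if seg.active or b > seg.end + 1e-9:
        raise ValueError(
            "baseline window must lie within a single inactive segment"
        )
    i0, i1 = traces.index_at(a), traces.index_at(b)
    f0 = traces.F[i0 : max(i1, i0 + 1)].mean(axis=0)
    if np.any(f0 <= 0):
        raise ValueError("baseline mean is zero or negative for some cell")
    return traces.with_matrix(traces.F / f0)


# --------------------------------------------------------------------------
# Photobleaching correction
# --------------------------------------------------------------------------

def _baseline_samples(
    x: np.ndarray, fs: float, block_s: float = 30.0, q: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Running lower-percentile baseline on non-overlapping blocks.

    The q-th percentile within each block tracks the inter-oscillation
    baseline even when the cell is active for a sizeable duty cycle, which a
    plain low-pass of the trace would not (it mixes in the oscillation mean).
    """
    n = len(x)
    block = max(int(round(block_s * fs)), 2)
    n_blocks = max(n // block, 1)
    tb = np.empty(n_blocks)
    vb = np.empty(n_blocks)
    for k in range(n_blocks):
        i0 = k * block
        i1 = n if k == n_blocks - 1 else (k + 1) * block
        tb[k] = 0.5 * (i0 + i1 - 1) / fs
        vb[k] = np.percentile(x[i0:i1], q)
    return tb, vb


def _bleach_model(t: np.ndarray, a: float, tau: float, b: float, c: float):
    return a * np.exp(-t / tau) + b * t + c


def correct_bleaching(
    traces: TraceSet, block_s: float = 30.0
) -> tuple[TraceSet, pd.DataFrame]:
    """Fit ``b(t) = A exp(-t/tau) + B t + C`` to each trace's baseline and
    divide the trace by ``b(t)/b(0)``.

    Photobleaching scales fluorescence, so the correction is multiplicative.
    Cells whose exponential fit fails fall back to a linear-only fit and are
    flagged in the returned per-cell report (columns: cell_id, method, a,
    tau, b, c).
    """
    t = traces.time - traces.t0
    total = t[-1] if len(t) > 1 else 1.0
    corrected = np.empty_like(traces.F)
    rows = []
    for j in range(traces.n_cells):
        x = traces.F[:, j]
        tb, vb = _baseline_samples(x, traces.fs, block_s=block_s)
        method = "exp+linear"
        try:
            if len(tb) < 4:
                raise RuntimeError("too few baseline blocks")
            p0 = (vb[0] - vb[-1], max(total / 3.0, 1.0), 0.0, vb[-1])
            popt, _ = optimize.curve_fit(
                _bleach_model, tb, vb, p0=p0, maxfev=10000,
                bounds=([-np.inf, 1e-3, -np.inf, -np.inf],
                        [np.inf, 1e4 * max(total, 1.0), np.inf, np.inf]),
            )
            b_t = _bleach_model(t, *popt)
            a, tau, b, c = popt
        except (RuntimeError, ValueError):
            coef = np.polyfit(tb, vb, 1)
            b_t = np.polyval(coef, t)
            a, tau, b, c = 0.0, np.inf, coef[0], coef[1]
            method = "linear-fallback"
        if b_t[0] <= 0 or np.any(b_t <= 0):
            log.warning(
                "cell %s: non-positive bleach baseline, trace left unchanged",
                traces.cell_ids[j],
            )
            corrected[:, j] = x
            method = "none"
        else:
            corrected[:, j] = x / (b_t / b_t[0])
        rows.append(
            {"cell_id": traces.cell_ids[j], "method": method,
             "a": a, "tau": tau, "b": b, "c": c}
        )
    return traces.with_matrix(corrected), pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Artifact / non-beta-cell exclusion
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionRules:
    """Automated stand-ins for the manual removal of distorted and
    non-beta-cell-like traces.

    low_glucose_active_frac : a cell spending more than this fraction of the
        substimulatory segment above the activity threshold is excluded
        ("low-glucose-active", suggestive of alpha/delta cells).
    high_glucose_active_min : a cell spending less than this fraction of the
        stimulatory segment above the activity threshold is excluded
        ("high-glucose-inactive").
    jump_z : robust z-score of the largest single-frame spike (deviation from
        the mean of its two neighbours) above which a movement/acquisition
        artifact is declared.
    amp_floor : minimum activity amplitude in F/F0 units, so that noise-free
        flat traces do not trip the threshold.
    """

    low_glucose_active_frac: float = 0.10
    high_glucose_active_min: float = 0.05
    jump_z: float = 6.0
    amp_floor: float = 0.05


def exclude_artifacts(
    traces: TraceSet, rules: ExclusionRules | None = None
) -> tuple[TraceSet, list[tuple[str, str]]]:
    """Drop cells violating the exclusion rules.

    Expects F/F0-normalized, de-bleached traces.  Returns the kept subset and
    a list of ``(cell_id, reason)`` pairs; reasons are
    ``"low-glucose-active"``, ``"high-glucose-inactive"`` and ``"artifact"``.
    """
    rules = rules or ExclusionRules()
    prot = traces.protocol
    inactive = [s for s in prot.segments if not s.active]
    active = [s for s in prot.segments if s.active]
    if not inactive:
        raise ValueError("protocol has no substimulatory segment")
    sub = inactive[0]
    i0, i1 = traces.index_at(sub.start), traces.index_at(sub.end)

    excluded: list[tuple[str, str]] = []
    keep: list[int] = []
    for j in range(traces.n_cells):
        x = traces.F[:, j]
        base = x[i0:i1]
        noise = _mad_sigma(np.diff(base)) / np.sqrt(2.0)
        level = float(np.median(base))
        thr = max(5.0 * noise, rules.amp_floor)

        reason = None
        frac_low = float(np.mean(base - level > thr))
        if frac_low > rules.low_glucose_active_frac:
            reason = "low-glucose-active"
        if reason is None and active:
            a0 = traces.index_at(active[0].start)
            a1 = traces.index_at(active[-1].end)
            frac_high = float(np.mean(x[a0:a1] - level > thr))
            if frac_high < rules.high_glucose_active_min:
                reason = "high-glucose-inactive"
        if reason is None:
            # isolated single-frame spikes: deviation from the neighbour mean,
            # in robust sd units of that (signed, ~symmetric) quantity
            dev = x[1:-1] - 0.5 * (x[:-2] + x[2:])
            denom = max(_mad_sigma(dev), 0.01)
            if dev.size and float(np.abs(dev).max()) / denom > rules.jump_z:
                reason = "artifact"

        if reason is None:
            keep.append(j)
        else:
            excluded.append((traces.cell_ids[j], reason))
    if not keep:
        raise ValueError("all cells excluded: empty islet")
    return traces.subset(keep), excluded


# --------------------------------------------------------------------------
# Zero-phase band-pass filter
# --------------------------------------------------------------------------

def bandpass_zero_lag(
    F: np.ndarray, fs: float, f_lo: float = 0.03, f_hi: float = 1.5,
    order: int = 4,
) -> np.ndarray:
    """Forward-backward Butterworth band-pass (zero phase lag).

    The default corners (0.03, 1.5) Hz sit at the midpoints of the empirical
    ranges used for islet recordings (0.02-0.04 Hz lower, 1-2 Hz upper);
    forward-backward application doubles the effective order and cancels the
    phase response exactly.
    """
    if not 0 < f_lo < f_hi:
        raise ValueError("need 0 < f_lo < f_hi")
    if f_hi >= fs / 2:
        raise ValueError("upper cutoff must be below the Nyquist frequency")
    sos = signal.butter(order, [f_lo, f_hi], btype="bandpass", fs=fs,
                        output="sos")
    return signal.sosfiltfilt(sos, np.asarray(F, dtype=float), axis=0)


# --------------------------------------------------------------------------
# Assembled preprocessing
# --------------------------------------------------------------------------

@dataclass
class CleanTraceSet:
    """Preprocessed islet: F/F0 (de-bleached) and band-passed matrices for
    the kept cells, plus the exclusion and bleach-fit reports."""

    f_norm: np.ndarray
    f_filt: np.ndarray
    fs: float
    t0: float
    positions: np.ndarray
    cell_ids: list[str]
    islet_id: str
    protocol: Protocol
    band: tuple[float, float]
    excluded: list[tuple[str, str]] = field(default_factory=list)
    bleach_report: pd.DataFrame | None = None

    @property
    def n_cells(self) -> int:
        return self.f_filt.shape[1]

    @property
    def n_samples(self) -> int:
        return self.f_filt.shape[0]

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + (self.n_samples - 1) / self.fs

    def index_at(self, t: float) -> int:
        i = int(round((t - self.t0) * self.fs))
        return min(max(i, 0), self.n_samples - 1)

    def slice_interval(
        self, interval: tuple[float, float], which: str = "filt"
    ) -> np.ndarray:
        a, b = interval
        i0, i1 = self.index_at(a), self.index_at(b)
        if i1 <= i0:
            raise ValueError("interval does not cover any samples")
        M = self.f_filt if which == "filt" else self.f_norm
        return M[i0:i1]


def preprocess_traces(
    traces: TraceSet,
    band: tuple[float, float] = (0.03, 1.5),
    baseline_window: tuple[float, float] | None = None,
    rules: ExclusionRules | None = None,
    correct_bleach: bool = True,
) -> CleanTraceSet:
    """Full preprocessing chain: F/F0 -> de-bleach -> exclude -> band-pass."""
    ts = normalize_f0(traces, baseline_window)
    report = None
    if correct_bleach:
        ts, report = correct_bleaching(ts)
    ts, excluded = exclude_artifacts(ts, rules)
    f_filt = bandpass_zero_lag(ts.F, ts.fs, band[0], band[1])
    return CleanTraceSet(
        f_norm=ts.F,
        f_filt=f_filt,
        fs=ts.fs,
        t0=ts.t0,
        positions=ts.positions,
        cell_ids=list(ts.cell_ids),
        islet_id=ts.islet_id,
        protocol=ts.protocol,
        band=band,
        excluded=excluded,
        bleach_report=report,
    )
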