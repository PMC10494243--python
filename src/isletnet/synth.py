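"""Synthetic islet generator.

Emulates multicellular Ca2+ fluorescence recordings of pancreatic islets:
heterogeneous bursting cells that activate in a wave spreading from a
pacemaker region, oscillate with condition-dependent frequency and duration
during stimulation, keep oscillating for a cell-specific delay after stimulus
withdrawal, and are observed through a photobleaching, noisy fluorescence
channel.  Every islet comes with a :class:`GroundTruth` recording the true
event times and per-cell parameters, so downstream estimators can be checked
against a known answer.

Model summary
-------------
* Cells are placed uniformly in a square field; activation time is
  ``episode start + distance-to-pacemaker / wave speed + log-normal delay``.
  Log-normal delays reflect the positive, right-skewed activation and
  deactivation delay distributions seen in glucose-stimulated islets.
* Each stimulation episode has one master burst clock per community
  (regular onsets at the segment period).  A cell follows the master clock
  on a given beat with probability ``sync`` and otherwise falls back to a
  private clock with its own period and phase; ``sync`` therefore maps
  directly onto pairwise trace correlation (1 = fully synchronized islet,
  0 = independent oscillators).
* An oscillation is a pulse with a linear rise over the first 20% of its
  duration and an exponential decay that crosses 50% of the peak exactly at
  the configured duration (so a half-amplitude end rule recovers the
  configured duration by construction), followed by a linear return to
  baseline over a further 60% of the duration.
* Fluorescence: ``F = F0 * (exp(-t/tau_bleach) + slope*t) * (1 + gain*c(t))
  + noise``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .protocol import Protocol, Segment
from .traces import TraceSet

_LN2 = float(np.log(2.0))


@dataclass
class IsletConfig:
    """Parameters of one synthetic islet.

    Distances are in micrometers, times in seconds, rates in Hz.  The delay
    medians/dispersions parametrize log-normal distributions (dispersion is
    the standard deviation of the log).  ``sync`` in [0, 1] is the
    probability per oscillation that a cell follows the islet's master burst
    clock instead of its private clock.  ``noise_sd`` is the additive noise
    standard deviation as a fraction of the baseline fluorescence ``f0``.
    """

    n_cells: int = 50
    field_size_um: float = 200.0
    pacemaker_xy: tuple[float, float] = (0.0, 0.0)
    wave_speed_um_s: float = 100.0
    act_delay_median_s: float = 168.0
    act_delay_sigma: float = 0.45
    deact_delay_median_s: float = 348.0
    deact_delay_sigma: float = 0.5
    freq_cv: float = 0.1
    dur_cv: float = 0.1
    sync: float = 0.9
    n_communities: int = 1
    noise_sd: float = 0.05
    bleach_tau_s: float = 10000.0
    bleach_slope_per_s: float = -1e-5
    f0: float = 100.0
    gain: float = 1.0
    fs_hz: float = 10.0
    seed: int = 0
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("an islet needs at least 2 cells")
        if not 0.0 <= self.sync <= 1.0:
            raise ValueError("sync must lie in [0, 1]")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.wave_speed_um_s <= 0 or self.field_size_um <= 0:
            raise ValueError("field size and wave speed must be positive")
        if self.n_communities < 1 or self.n_communities > self.n_cells:
            raise ValueError("n_communities must be in [1, n_cells]")
        if min(self.freq_cv, self.dur_cv) < 0:
            raise ValueError("jitter coefficients of variation must be >= 0")
        if self.f0 <= 0 or self.gain < 0:
            raise ValueError("f0 must be > 0 and gain >= 0")


@dataclass
class GroundTruth:
    """True event times and per-cell parameters of a synthetic islet.

    ``segment_params`` maps each active segment name to per-cell arrays of
    the true oscillation frequency (Hz), mean duration (s) and active-time
    fraction, measured over that cell's active window in the segment.
    """

    activation_time: np.ndarray
    deactivation_time: np.ndarray
    onsets: list[np.ndarray]
    ends: list[np.ndarray]
    segment_params: dict[str, dict[str, np.ndarray]]
    communities: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.onsets)

    def to_json(self) -> str:
        return json.dumps(
            {
                "activation_time": self.activation_time.tolist(),
                "deactivation_time": self.deactivation_time.tolist(),
                "onsets": [o.tolist() for o in self.onsets],
                "ends": [e.tolist() for e in self.ends],
                "segment_params": {
                    name: {k: v.tolist() for k, v in d.items()}
                    for name, d in self.segment_params.items()
                },
                "communities": self.communities.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            activation_time=np.asarray(d["activation_time"], float),
            deactivation_time=np.asarray(d["deactivation_time"], float),
            onsets=[np.asarray(o, float) for o in d["onsets"]],
            ends=[np.asarray(e, float) for e in d["ends"]],
            segment_params={
                name: {k: np.asarray(v, float) for k, v in sub.items()}
                for name, sub in d["segment_params"].items()
            },
            communities=np.asarray(d["communities"], int),
        )


def _lognormal_delays(
    rng: np.random.Generator, median: float, sigma: float, n: int
) -> np.ndarray:
    z = rng.standard_normal(n)  # always drawn, keeps the stream aligned
    if median <= 0:
        return np.zeros(n)
    return median * np.exp(sigma * z)


def _validate(config: IsletConfig, protocol: Protocol) -> None:
    for seg in protocol.active_segments:
        if seg.length < 1.0 / seg.freq_hz:
            raise ValueError(
                f"active segment {seg.name!r} is shorter than one "
                f"oscillation period ({1.0 / seg.freq_hz:.1f} s)"
            )


def generate_islet(
    config: IsletConfig, protocol: Protocol, islet_id: str = "islet00"
) -> tuple[TraceSet, GroundTruth]:
    """Simulate one islet under ``protocol``.

    Returns the fluorescence :class:`TraceSet` (time x cells, sampled at
    ``config.fs_hz``) and the matching :class:`GroundTruth`.  Identical
    (config, protocol) pairs give bit-identical output; the follow/private
    clock choices are drawn independently of ``sync`` (a fixed uniform per
    beat, compared against ``sync``), so raising ``sync`` at a fixed seed
    only ever converts private beats into synchronized ones.
    """
    _validate(config, protocol)
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    fs = config.fs_hz

    if config.positions is not None:
        pos = np.asarray(config.positions, dtype=float)
        if pos.shape != (n, 2):
            raise ValueError("positions must have shape (n_cells, 2)")
        rng.uniform(0.0, config.field_size_um, (n, 2))  # keep stream aligned
    else:
        pos = rng.uniform(0.0, config.field_size_um, (n, 2))

    if config.n_communities > 1:
        order = np.argsort(pos[:, 0], kind="stable")
        comm = np.empty(n, dtype=int)
        for k, chunk in enumerate(np.array_split(order, config.n_communities)):
            comm[chunk] = k
    else:
        comm = np.zeros(n, dtype=int)

    dist = np.linalg.norm(pos - np.asarray(config.pacemaker_xy), axis=1)
    wave_lag = dist / config.wave_speed_um_s

    n_samples = int(round(protocol.duration * fs)) + 1
    t = protocol.start + np.arange(n_samples) / fs
    trace_end = float(t[-1])

    episodes = protocol.episodes()
    events: list[list[tuple[float, float, str]]] = [[] for _ in range(n)]
    activation = np.full(n, np.nan)
    act_by_episode: list[np.ndarray] = []

    for e_idx, ep in enumerate(episodes):
        ep_start, ep_end = ep[0].start, ep[-1].end
        next_start = (
            episodes[e_idx + 1][0].start if e_idx + 1 < len(episodes) else np.inf
        )
        act_jit = _lognormal_delays(
            rng, config.act_delay_median_s, config.act_delay_sigma, n
        )
        deact = _lognormal_delays(
            rng, config.deact_delay_median_s, config.deact_delay_sigma, n
        )
        act_c = ep_start + wave_lag + act_jit
        act_by_episode.append(act_c)
        tail_cap = min(next_start, trace_end)
        limit_c = np.minimum(ep_end + deact, tail_cap)

        cand: list[list[tuple[float, float, str]]] = [[] for _ in range(n)]
        dur_first: np.ndarray | None = None
        for s_i, seg in enumerate(ep):
            period = 1.0 / seg.freq_hz
            sync = config.sync if seg.sync is None else seg.sync
            last = s_i == len(ep) - 1
            hard_end = tail_cap if last else seg.end
            n_slots = int(np.ceil((hard_end - seg.start) / period)) + 2
            u = rng.random((n, n_slots))
            period_c = period * np.exp(config.freq_cv * rng.standard_normal(n))
            dur_c = seg.duration_s * np.exp(config.dur_cv * rng.standard_normal(n))
            dur_c = np.clip(dur_c, 2.0 / fs, 0.95 * period)
            phi = rng.uniform(0.0, period, n)
            if s_i == 0:
                dur_first = dur_c
            for c in range(n):
                lim = limit_c[c] if last else seg.end
                phase_master = comm[c] * period / config.n_communities
                for j in range(n_slots):
                    if u[c, j] < sync:
                        onset = seg.start + phase_master + j * period
                    else:
                        onset = seg.start + phi[c] + j * period_c[c]
                    if onset < seg.start or onset < act_c[c]:
                        continue
                    if onset + dur_c[c] > lim:
                        continue
                    if not last and onset >= seg.end:
                        continue
                    cand[c].append((onset, dur_c[c], seg.name))

        assert dur_first is not None
        # pulses occupy 1.6x their duration (decay tail included); keeping
        # onsets at least that far apart means every pulse rises from true
        # baseline, so the half-decay end rule is exact by construction
        for c in range(n):
            ev = sorted(cand[c])
            # the first oscillation of an episode happens exactly at the
            # cell's activation time
            if act_c[c] + dur_first[c] <= limit_c[c]:
                ev = [(act_c[c], dur_first[c], ep[0].name)] + ev
            elif not ev:
                continue  # activated too late: non-responder for this episode
            pruned: list[tuple[float, float, str]] = []
            for onset, dur, name in ev:
                if pruned and onset < pruned[-1][0] + 1.6 * pruned[-1][1] + 2.0 / fs:
                    continue
                pruned.append((onset, dur, name))
            events[c].extend(pruned)
            if e_idx == 0 and pruned:
                activation[c] = pruned[0][0]

    onsets = [np.array([e[0] for e in ev]) for ev in events]
    ends = [np.array([e[0] + e[1] for e in ev]) for ev in events]
    deactivation = np.array(
        [float(e[-1]) if e.size else np.nan for e in ends]
    )

    segment_params = _segment_ground_truth(
        episodes, act_by_episode, events, n
    )

    cal = _calcium_matrix(events, t, fs, trace_end, n_samples, n)
    bleach = np.exp(-(t - protocol.start) / config.bleach_tau_s)
    bleach = bleach + config.bleach_slope_per_s * (t - protocol.start)
    F = config.f0 * bleach[:, None] * (1.0 + config.gain * cal)
    if config.noise_sd > 0:
        F = F + config.noise_sd * config.f0 * rng.standard_normal(F.shape)

    traces = TraceSet(
        F=F, fs=fs, positions=pos, protocol=protocol, islet_id=islet_id,
        t0=protocol.start,
    )
    truth = GroundTruth(
        activation_time=activation,
        deactivation_time=deactivation,
        onsets=onsets,
        ends=ends,
        segment_params=segment_params,
        communities=comm,
    )
    return traces, truth


def _segment_ground_truth(
    episodes: list[tuple[Segment, ...]],
    act_by_episode: list[np.ndarray],
    events: list[list[tuple[float, float, str]]],
    n: int,
) -> dict[str, dict[str, np.ndarray]]:
    """True frequency/duration/active time per active segment.

    The per-cell window runs from the later of the cell's activation and the
    segment start to the segment end (or, for the closing segment of an
    episode, to the cell's last oscillation end, which may extend past the
    stimulus by the deactivation delay).  Within such a window active time
    equals frequency x mean duration by construction.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for ep, act_c in zip(episodes, act_by_episode):
        for s_i, seg in enumerate(ep):
            last = s_i == len(ep) - 1
            freq = np.zeros(n)
            dur = np.full(n, np.nan)
            at = np.zeros(n)
            for c in range(n):
                evs = [e for e in events[c] if e[2] == seg.name]
                if not evs:
                    continue
                w0 = max(act_c[c], seg.start)
                w1 = (evs[-1][0] + evs[-1][1]) if last else seg.end
                w = w1 - w0
                if w <= 0:
                    continue
                freq[c] = len(evs) / w
                dur[c] = float(np.mean([e[1] for e in evs]))
                at[c] = sum(e[1] for e in evs) / w
            out[seg.name] = {
                "frequency": freq, "duration": dur, "active_time": at,
            }
    return out


def _calcium_matrix(
    events: list[list[tuple[float, float, str]]],
    t: np.ndarray,
    fs: float,
    trace_end: float,
    n_samples: int,
    n: int,
) -> np.ndarray:
    """Render oscillation pulses into a calcium matrix.

    Pulse shape: linear rise over 20% of the duration; exponential decay
    with half-life 0.8*duration, so the pulse sits at exactly 50% of peak at
    onset + duration; then a linear return to zero over a further
    0.6*duration, so the inter-oscillation baseline is genuinely zero.
    Overlapping tails combine by maximum, keeping the trace continuous.
    """
    t0 = float(t[0])
    cal = np.zeros((n_samples, n))
    for c, evs in enumerate(events):
        for onset, dur, _name in evs:
            t_peak = onset + 0.2 * dur
            tau = 0.8 * dur / _LN2
            t_half = onset + dur  # 50% of peak here by construction
            stop = min(t_half + 0.6 * dur, trace_end)
            i0 = int(np.ceil((onset - t0) * fs))
            i1 = min(int(np.floor((stop - t0) * fs)) + 1, n_samples)
            if i1 <= i0:
                continue
            tt = t[i0:i1]
            pulse = np.where(
                tt < t_peak,
                (tt - onset) / (0.2 * dur),
                np.exp(-(np.maximum(tt - t_peak, 0.0)) / tau),
            )
            late = tt >= t_half
            pulse[late] = 0.5 * (1.0 - (tt[late] - t_half) / (0.6 * dur))
            np.maximum(cal[i0:i1, c], np.maximum(pulse, 0.0),
                       out=cal[i0:i1, c])
    return cal


def generate_cohort(
    n_islets: int,
    config: IsletConfig,
    protocol: Protocol,
    seed: int = 0,
    islet_cv: float = 0.15,
) -> list[tuple[TraceSet, GroundTruth]]:
    """Simulate ``n_islets`` independent islets.

    Islet-level variability: the activation and deactivation delay medians of
    islet *i* are scaled by independent log-normal factors with unit median
    and log-sd ``islet_cv``, so the configured medians are the medians of the
    islet-median distribution.  Islet *i* is generated with seed
    ``seed + i``; with ``islet_cv=0`` the first islet is bit-identical to
    ``generate_islet`` called directly with that seed.
    """
    if n_islets < 1:
        raise ValueError("n_islets must be >= 1")
    factor_rng = np.random.default_rng([int(seed), 917])
    out = []
    for i in range(n_islets):
        fa, fd = np.exp(islet_cv * factor_rng.standard_normal(2))
        cfg = replace(
            config,
            seed=int(seed) + i,
            act_delay_median_s=config.act_delay_median_s * fa,
            deact_delay_median_s=config.deact_delay_median_s * fd,
        )
        out.append(generate_islet(cfg, protocol, islet_id=f"islet{i:02d}"))
    return out
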