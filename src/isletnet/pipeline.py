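"""End-to-end orchestration over islet cohorts.

``run_study`` takes a study configuration plus one cohort of recordings per
group, pushes every islet through preprocessing, oscillation detection,
delay extraction and network construction, pools the per-cell and per-islet
results, and runs the group-comparison statistics (Mann-Whitney U for two
groups, Kruskal-Wallis + Dunn's for more).

Analysis intervals: the plateau phase is compared between a *first* interval
(early sustained activity under glucose only, used to calibrate the network
threshold to <k> = k_target) and a *second* interval (either prolonged
glucose or glucose + forskolin, analyzed with the first interval's
threshold).  Defaults place the first interval ``settle_s`` after stimulus
onset and the second interval either ``second_offset_s`` into the second
active segment (forskolin-style protocols) or at the tail of the single
active segment (control protocols); both are configurable assumptions.

Pooling unit is the cell for classical parameters and delays (as in the
underlying experimental design) and the islet for network metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .delays import build_delay_table
from .events import CellParams, Oscillation, classical_params, detect_oscillations
from .funcnet import build_network
from .preprocess import CleanTraceSet, ExclusionRules, preprocess_traces
from .protocol import Protocol
from .stats import group_compare, quartile_table
from .traces import TraceSet

_DELAY_MEASURES = [
    "delay_a_s", "delay_a1_s", "rel_delay_a",
    "delay_d_s", "delay_d1_s", "rel_delay_d",
]
_PARAM_MEASURES = ["frequency", "mean_duration", "active_time"]
_NET_MEASURES = [
    "avg_degree", "avg_correlation", "modularity",
    "relative_largest_component",
]


@dataclass
class StudyConfig:
    """Analysis parameters shared by every islet in a study.

    ``band`` is the zero-phase filter pass band in Hz; the default lower
    corner (0.02 Hz) sits at the bottom of the empirical range so that the
    slowest physiological oscillations (~0.03 Hz) pass undistorted.
    ``k_target`` is the first-interval average-degree setpoint for network
    thresholding.
    """

    band: tuple[float, float] = (0.02, 1.5)
    k_target: float = 8.0
    f0_window_s: float = 60.0
    settle_s: float = 300.0
    interval_len_s: float = 300.0
    second_offset_s: float = 180.0
    rules: ExclusionRules = field(default_factory=ExclusionRules)
    active_time_mode: str = "binary"
    correlation: str = "pearson"
    community_method: str = "greedy"
    correct_bleach: bool = True
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "band" in d:
            d["band"] = tuple(d["band"])
        if "rules" in d and isinstance(d["rules"], dict):
            d["rules"] = ExclusionRules(**d["rules"])
        return cls(**d)


def plateau_intervals(
    protocol: Protocol, cfg: StudyConfig
) -> tuple[tuple[float, float], tuple[float, float]]:
    """(first, second) plateau analysis windows for a protocol.

    First: ``settle_s`` after stimulus onset, ``interval_len_s`` long,
    inside the first active segment.  Second: ``second_offset_s`` into the
    second active segment when there is one, else the last
    ``interval_len_s`` of the single active segment.
    """
    eps = protocol.episodes()
    if not eps:
        raise ValueError("protocol has no active segment")
    ep = eps[0]
    seg1 = ep[0]
    a1 = seg1.start + cfg.settle_s
    b1 = min(a1 + cfg.interval_len_s, seg1.end)
    if b1 <= a1:
        raise ValueError("first analysis interval does not fit the plateau")
    if len(ep) > 1:
        seg2 = ep[1]
        a2 = seg2.start + cfg.second_offset_s
        b2 = min(a2 + cfg.interval_len_s, seg2.end)
    else:
        b2 = seg1.end
        a2 = max(b2 - cfg.interval_len_s, b1)
    if b2 <= a2:
        raise ValueError("second analysis interval does not fit the plateau")
    return (a1, b1), (a2, b2)


@dataclass
class IsletResult:
    """Everything computed for one islet."""

    islet_id: str
    clean: CleanTraceSet
    events: dict[str, list[Oscillation]]  # on the band-passed signal
    events_slow: dict[str, list[Oscillation]]  # on F/F0, for delays
    params: pd.DataFrame  # per cell x interval
    delay_table: pd.DataFrame
    network: pd.DataFrame  # per interval metric rows
    intervals: tuple[tuple[float, float], tuple[float, float]]
    threshold: float


def analyze_islet(traces: TraceSet, cfg: StudyConfig) -> IsletResult:
    """Run the full single-islet analysis chain."""
    clean = preprocess_traces(
        traces,
        band=cfg.band,
        rules=cfg.rules,
        correct_bleach=cfg.correct_bleach,
    )
    int1, int2 = plateau_intervals(traces.protocol, cfg)

    events: dict[str, list[Oscillation]] = {}
    events_slow: dict[str, list[Oscillation]] = {}
    rows = []
    for j, cid in enumerate(clean.cell_ids):
        evs = detect_oscillations(clean.f_filt[:, j], clean.fs, t0=clean.t0)
        events[cid] = evs
        # slow-trace pass for delays: most of this signal is quiet baseline,
        # so its MAD underestimates the oscillation scale — demand a larger
        # prominence to keep washout noise from mimicking late activity
        events_slow[cid] = detect_oscillations(
            clean.f_norm[:, j], clean.fs, t0=clean.t0,
            min_prominence_mads=4.0,
        )
        for name, window in (("first", int1), ("second", int2)):
            trace = clean.f_filt[:, j] if cfg.active_time_mode == "above_half" else None
            p = classical_params(
                evs, window, clean.fs, mode=cfg.active_time_mode,
                trace=trace, t0=clean.t0,
            )
            rows.append(
                {
                    "islet_id": clean.islet_id,
                    "cell_id": cid,
                    "interval": name,
                    "frequency": p.frequency,
                    "mean_duration": p.mean_duration,
                    "active_time": p.active_time,
                    "n_oscillations": p.n_oscillations,
                }
            )
    params = pd.DataFrame(rows)

    prot = traces.protocol
    delay_table = build_delay_table(
        events_slow, prot.stim_onset, prot.stim_offset, islet_id=clean.islet_id
    )

    net1, corr1, m1 = build_network(
        clean, int1, k_target=cfg.k_target, method=cfg.correlation
    )
    # same threshold, second interval of the same islet
    net2, corr2, m2 = build_network(
        clean, int2, r_th=net1.threshold, method=cfg.correlation
    )
    net_rows = []
    for name, m, r_th in (("first", m1, net1.threshold), ("second", m2, net2.threshold)):
        net_rows.append(
            {
                "islet_id": clean.islet_id,
                "interval": name,
                "r_th": r_th,
                "avg_degree": m.avg_degree,
                "avg_correlation": m.avg_correlation,
                "modularity": m.modularity,
                "relative_largest_component": m.relative_largest_component,
                "n_cells": clean.n_cells,
            }
        )
    return IsletResult(
        islet_id=clean.islet_id,
        clean=clean,
        events=events,
        events_slow=events_slow,
        params=params,
        delay_table=delay_table,
        network=pd.DataFrame(net_rows),
        intervals=(int1, int2),
        threshold=net1.threshold,
    )


@dataclass
class ResultsBundle:
    """Pooled study outputs: tidy tables plus the comparison statistics."""

    cell_params: pd.DataFrame
    delays: pd.DataFrame
    network: pd.DataFrame
    comparisons: pd.DataFrame
    quartiles: pd.DataFrame
    exclusions: pd.DataFrame
    counts: pd.DataFrame

    def save(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in (
            "cell_params", "delays", "network", "comparisons", "quartiles",
            "exclusions", "counts",
        ):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)


def run_study(
    cfg: StudyConfig, cohorts: dict[str, list[TraceSet]]
) -> ResultsBundle:
    """Analyze every islet of every group and pool the results.

    ``cohorts`` maps group labels (e.g. ``"WT"``, ``"KO"``) to lists of
    recordings.  Deterministic: identical inputs and configuration yield an
    identical bundle.
    """
    if not cohorts or any(len(v) == 0 for v in cohorts.values()):
        raise ValueError("every group needs at least one islet")
    params_all, delays_all, net_all, excl_rows, count_rows = [], [], [], [], []
    for group, islets in cohorts.items():
        n_cells_in = n_kept = n_censored = 0
        for ts in islets:
            try:
                res = analyze_islet(ts, cfg)
            except Exception as exc:  # tag the failing stage/islet
                raise RuntimeError(
                    f"analysis failed for group {group!r}, islet "
                    f"{ts.islet_id!r}: {exc}"
                ) from exc
            n_cells_in += ts.n_cells
            n_kept += res.clean.n_cells
            n_censored += int(res.delay_table["censored"].sum())
            params_all.append(res.params.assign(group=group))
            delays_all.append(res.delay_table.assign(group=group))
            net_all.append(res.network.assign(group=group))
            for cid, reason in res.clean.excluded:
                excl_rows.append(
                    {
                        "group": group,
                        "islet_id": ts.islet_id,
                        "cell_id": cid,
                        "reason": reason,
                    }
                )
        count_rows.append(
            {
                "group": group,
                "n_islets": len(islets),
                "n_cells_in": n_cells_in,
                "n_cells_kept": n_kept,
                "n_cells_excluded": n_cells_in - n_kept,
                "n_censored": n_censored,
            }
        )

    cell_params = pd.concat(params_all, ignore_index=True)
    delays = pd.concat(delays_all, ignore_index=True)
    network = pd.concat(net_all, ignore_index=True)

    comp_rows, quart_rows = [], []
    groups = list(cohorts)
    for interval in ("first", "second"):
        sub = cell_params[cell_params["interval"] == interval]
        for measure in _PARAM_MEASURES:
            data = {g: sub.loc[sub["group"] == g, measure].to_numpy()
                    for g in groups}
            _collect(comp_rows, quart_rows, f"{measure}[{interval}]", data)
        nsub = network[network["interval"] == interval]
        for measure in _NET_MEASURES:
            data = {g: nsub.loc[nsub["group"] == g, measure].to_numpy()
                    for g in groups}
            _collect(comp_rows, quart_rows, f"{measure}[{interval}]", data)
    for measure in _DELAY_MEASURES:
        data = {g: delays.loc[delays["group"] == g, measure].to_numpy()
                for g in groups}
        _collect(comp_rows, quart_rows, measure, data)

    comparisons = pd.DataFrame(comp_rows)
    quartiles = pd.DataFrame(quart_rows)
    exclusions = pd.DataFrame(
        excl_rows, columns=["group", "islet_id", "cell_id", "reason"]
    )
    counts = pd.DataFrame(count_rows)
    return ResultsBundle(
        cell_params=cell_params,
        delays=delays,
        network=network,
        comparisons=comparisons,
        quartiles=quartiles,
        exclusions=exclusions,
        counts=counts,
    )


def _collect(comp_rows, quart_rows, measure, data) -> None:
    clean = {
        g: v[np.isfinite(v)] for g, v in data.items()
    }
    usable = {g: v for g, v in clean.items() if v.size}
    for g, v in usable.items():
        q = quartile_table({g: v}).iloc[0]
        quart_rows.append(
            {
                "measure": measure, "group": g, "n": int(q["n"]),
                "q1": q["q1"], "median": q["median"], "q3": q["q3"],
            }
        )
    if len(usable) >= 2:
        try:
            tab = group_compare(usable)
        except ValueError:
            return
        for _, r in tab.iterrows():
            comp_rows.append({"measure": measure, **r.to_dict()})
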