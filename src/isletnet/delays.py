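"""Activation and deactivation delay statistics.

For each cell, the activation time is the onset of its first oscillation
after stimulus onset and the deactivation time is the end of its last
oscillation after stimulus offset.  Three forms of each delay are computed:

* ``delay_a`` / ``delay_d`` — seconds from stimulus onset/offset;
* ``delay_a1`` / ``delay_d1`` — any-cell-first-responder form: the delay
  minus the smallest delay in the islet (the first responder / first
  deactivator sits at 0 by construction);
* ``rel_delay_a`` / ``rel_delay_d`` — first-responder delay divided by the
  islet median first-responder delay, a dimensionless heterogeneity measure
  whose islet median is 1 whenever it is defined.

Cells still above half-amplitude at the end of the recording are
right-censored: their deactivation delay is unknown and they are excluded
from deactivation statistics (and counted in the censoring report).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .events import Oscillation

log = logging.getLogger(__name__)

_COLUMNS = [
    "islet_id", "cell_id", "activation_s", "delay_a_s", "delay_a1_s",
    "rel_delay_a", "deactivation_s", "delay_d_s", "delay_d1_s",
    "rel_delay_d", "censored",
]


def activation_times(
    events_by_cell: dict[str, list[Oscillation]], stim_onset: float
) -> dict[str, float]:
    """Onset of each cell's first oscillation at/after stimulus onset.

    Cells without a post-stimulus oscillation map to NaN (non-responders).
    """
    out: dict[str, float] = {}
    for cid, evs in events_by_cell.items():
        post = [ev.onset for ev in evs if ev.onset >= stim_onset]
        out[cid] = min(post) if post else np.nan
    return out


def deactivation_times(
    events_by_cell: dict[str, list[Oscillation]], stim_offset: float
) -> tuple[dict[str, float], dict[str, bool]]:
    """End of each cell's last oscillation after stimulus offset.

    A cell with no activity past the offset deactivated with the stimulus
    (time = offset, i.e. zero delay).  Returns (times, censored flags).
    """
    times: dict[str, float] = {}
    censored: dict[str, bool] = {}
    for cid, evs in events_by_cell.items():
        post = [ev for ev in evs if ev.end > stim_offset]
        if post:
            last = max(post, key=lambda ev: ev.end)
            times[cid] = last.end
            censored[cid] = bool(last.censored)
        else:
            times[cid] = stim_offset if evs else np.nan
            censored[cid] = False
    return times, censored


def first_responder_delays(delays: np.ndarray) -> np.ndarray:
    """Delay of every cell relative to the islet's first responder.

    Requires at least two responding (finite) cells; the minimum of the
    result over responders is exactly 0.
    """
    delays = np.asarray(delays, dtype=float)
    finite = np.isfinite(delays)
    if finite.sum() < 2:
        raise ValueError("need at least two responding cells in the islet")
    return delays - np.nanmin(delays)


def relative_delays(delays1: np.ndarray) -> np.ndarray:
    """First-responder delays normalized by their islet median.

    A perfectly synchronous islet (median 0) has no meaningful relative
    delays; it is excluded with a warning (all-NaN result).
    """
    delays1 = np.asarray(delays1, dtype=float)
    med = np.nanmedian(delays1)
    if not np.isfinite(med) or med <= 0:
        log.warning(
            "islet median first-responder delay is zero; relative delays "
            "undefined, islet excluded from relative statistics"
        )
        return np.full_like(delays1, np.nan)
    return delays1 / med


def build_delay_table(
    events_by_cell: dict[str, list[Oscillation]],
    stim_onset: float,
    stim_offset: float,
    islet_id: str = "islet",
) -> pd.DataFrame:
    """Per-cell delay table for one islet (see module docstring for columns).

    First-responder and relative forms are left NaN when fewer than two
    cells respond (activation) or deactivate uncensored (deactivation).
    """
    cids = list(events_by_cell)
    act = activation_times(events_by_cell, stim_onset)
    deact, cens = deactivation_times(events_by_cell, stim_offset)

    a = np.array([act[c] for c in cids])
    d = np.array([deact[c] for c in cids])
    c_flag = np.array([cens[c] for c in cids], dtype=bool)

    delay_a = a - stim_onset
    delay_d = d - stim_offset
    delay_d = np.where(c_flag, np.nan, delay_d)  # censored: delay unknown

    try:
        delay_a1 = first_responder_delays(delay_a)
        rel_a = relative_delays(delay_a1)
    except ValueError:
        delay_a1 = np.full_like(delay_a, np.nan)
        rel_a = np.full_like(delay_a, np.nan)
    try:
        delay_d1 = first_responder_delays(delay_d)
        rel_d = relative_delays(delay_d1)
    except ValueError:
        delay_d1 = np.full_like(delay_d, np.nan)
        rel_d = np.full_like(delay_d, np.nan)

    return pd.DataFrame(
        {
            "islet_id": islet_id,
            "cell_id": cids,
            "activation_s": a,
            "delay_a_s": delay_a,
            "delay_a1_s": delay_a1,
            "rel_delay_a": rel_a,
            "deactivation_s": d,
            "delay_d_s": delay_d,
            "delay_d1_s": delay_d1,
            "rel_delay_d": rel_d,
            "censored": c_flag,
        },
        columns=_COLUMNS,
    )
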