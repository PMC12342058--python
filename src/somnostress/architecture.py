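"""Sleep architecture: bouts, state-time accounting, sleep lost, recovery.

Conventions (documented defaults):

* All ZT windows are half-open ``[start, end)``; an epoch belongs to the
  window containing its start time.
* A bout is a maximal run of identical state. ARTIFACT epochs terminate
  bouts and are excluded from state minutes (reported separately).
* A bout spanning the light/dark boundary is assigned to the phase
  containing its onset; per-phase minute totals use epoch-level phase, so
  they are unaffected by this choice.
* "Total sleep" = NREM + REM.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import ARTIFACT, NREM, REM, WAKE, Hypnogram, LightSchedule

logger = logging.getLogger(__name__)


def segment_bouts(hyp: Hypnogram, light: LightSchedule | None = None) -> pd.DataFrame:
    """Segment a hypnogram into maximal same-state runs.

    Returns a DataFrame with columns ``state``, ``start_epoch``,
    ``n_epochs``, ``duration_s`` and ``phase`` (phase of the bout onset).
    Concatenating the bouts reproduces the hypnogram exactly.
    """
    light = light or LightSchedule()
    states = hyp.states
    if states.size == 0:
        raise ValueError("empty hypnogram")
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [states.size]))
    zt = hyp.epoch_zt_s()
    return pd.DataFrame(
        {
            "state": states[starts],
            "start_epoch": starts,
            "n_epochs": ends - starts,
            "duration_s": (ends - starts) * hyp.epoch_s,
            "phase": [light.phase_at(zt[s]) for s in starts],
        }
    )


def bout_stats(bouts: pd.DataFrame, by=("state", "phase"),
               include_artifact: bool = False) -> pd.DataFrame:
    """Bout counts and durations grouped by the given columns.

    Empty groups (e.g. no REM bouts) are reported with ``n_bouts = 0``
    and missing (NaN) mean duration — never zero.
    """
    df = bouts if include_artifact else bouts[bouts["state"] != ARTIFACT]
    by = list(by)
    grouped = df.groupby(by, observed=False)["duration_s"].agg(
        n_bouts="count", mean_duration_s="mean", total_duration_s="sum"
    ).reset_index()
    grouped.loc[grouped["n_bouts"] == 0, ["mean_duration_s"]] = np.nan
    grouped.loc[grouped["n_bouts"] == 0, ["total_duration_s"]] = 0.0
    return grouped


def _window_mask(hyp: Hypnogram, window_zt_h: tuple[float, float]) -> np.ndarray:
    lo, hi = window_zt_h
    zt_h = hyp.epoch_zt_s() / 3600.0
    total_h = hyp.duration_s / 3600.0
    if lo < hyp.zt_start_s / 3600.0 - 1e-9 or hi > hyp.zt_start_s / 3600.0 + total_h + 1e-9:
        raise ValueError(f"window {window_zt_h} outside recording span")
    return (zt_h >= lo) & (zt_h < hi)


def state_minutes(hyp: Hypnogram, window_zt_h: tuple[float, float] = (0.0, 24.0)) -> pd.Series:
    """Minutes of WAKE/NREM/REM (and artifact, separately) in a ZT window.

    State minutes plus artifact minutes always sum to the window length.
    """
    mask = _window_mask(hyp, window_zt_h)
    states = hyp.states[mask]
    mins = hyp.epoch_s / 60.0
    out = {s: float(np.sum(states == s)) * mins for s in (WAKE, NREM, REM)}
    out["ARTIFACT"] = float(np.sum(states == ARTIFACT)) * mins
    out["total_sleep"] = out[NREM] + out[REM]
    return pd.Series(out)


def sleep_lost(baseline_hyp: Hypnogram, sr_hyp: Hypnogram,
               window_zt_h: tuple[float, float] = (0.0, 6.0)) -> pd.Series:
    """Sleep lost during restriction: baseline minus restriction-day
    minutes per state over the same ZT window (default ZT0–6).

    Negative losses are possible in principle and trigger a warning.
    """
    base = state_minutes(baseline_hyp, window_zt_h)
    sr = state_minutes(sr_hyp, window_zt_h)
    lost = pd.Series(
        {s: base[s] - sr[s] for s in (NREM, REM)} | {
            "total_sleep": base["total_sleep"] - sr["total_sleep"]}
    )
    if (lost < 0).any():
        logger.warning("negative sleep lost: restriction day had more sleep "
                       "than baseline in %s", window_zt_h)
    return lost


def recovery_sleep(baseline_hyp: Hypnogram, post_sr_hyp: Hypnogram,
                   window_zt_h: tuple[float, float] = (6.0, 24.0),
                   bin_h: float = 1.0) -> pd.DataFrame:
    """Cumulative recovery-sleep gain across the post-restriction window.

    Returns per-hour cumulative (post-restriction − baseline) minutes per
    state; the curve endpoint equals the state-minute difference over the
    full window.
    """
    lo, hi = window_zt_h
    edges = np.arange(lo, hi + bin_h, bin_h)
    rows = []
    cum = {NREM: 0.0, REM: 0.0}
    for a, b in zip(edges[:-1], edges[1:]):
        base = state_minutes(baseline_hyp, (a, b))
        post = state_minutes(post_sr_hyp, (a, b))
        for s in (NREM, REM):
            cum[s] += post[s] - base[s]
        rows.append({"zt_end_h": b, "cum_nrem_gain_min": cum[NREM],
                     "cum_rem_gain_min": cum[REM],
                     "cum_total_gain_min": cum[NREM] + cum[REM]})
    return pd.DataFrame(rows)


def pre_post_change(pre: dict[str, Hypnogram], post: dict[str, Hypnogram],
                    metric: str = "nrem_minutes",
                    window_zt_h: tuple[float, float] = (0.0, 24.0)) -> pd.DataFrame:
    """Per-subject paired differences (post − pre) of a sleep metric.

    ``metric`` is one of ``nrem_minutes``, ``rem_minutes``,
    ``total_sleep_minutes``, ``nrem_bout_duration_s``,
    ``rem_bout_duration_s``, ``nrem_bout_count``. Output feeds the stats
    module directly.
    """
    if set(pre) != set(post):
        raise ValueError("pre and post must cover the same subjects")

    def value(hyp: Hypnogram) -> float:
        if metric.endswith("_minutes"):
            key = {"nrem_minutes": NREM, "rem_minutes": REM,
                   "total_sleep_minutes": "total_sleep"}[metric]
            return float(state_minutes(hyp, window_zt_h)[key])
        bouts = segment_bouts(hyp)
        state = NREM if metric.startswith("nrem") else REM
        sel = bouts[bouts["state"] == state]
        if metric.endswith("_count"):
            return float(len(sel))
        return float(sel["duration_s"].mean()) if len(sel) else np.nan

    rows = []
    for sid in sorted(pre):
        v_pre, v_post = value(pre[sid]), value(post[sid])
        rows.append({"subject_id": sid, "pre": v_pre, "post": v_post,
                     "delta": v_post - v_pre})
    return pd.DataFrame(rows)
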