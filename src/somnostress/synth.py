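"""Synthetic polysomnography and behavior cohorts.

This module generates the inputs the rest of the pipeline consumes —
hypnograms, raw EEG/EMG signals, sleep-restriction/defeat protocol
schedules and arena trajectories — with the statistical structure the
analysis assumes:

* Hypnograms come from a semi-Markov chain over {WAKE, NREM, REM} with
  geometric (per-epoch) dwell times whose means depend on state and light
  phase, reproducing the 12:12 LD mouse pattern of more sleep in the light
  phase. REM is entered only from NREM, the standard rodent staging
  constraint.
* A homeostatic Process-S variable rises exponentially during wake and
  discharges during NREM; it scales the delta-band amplitude of NREM EEG
  so that slow-wave activity rebounds after 6 h forced wakefulness.
* EEG is a sum of band-limited Gaussian noise components (delta 0.5–4 Hz,
  theta 6–10 Hz, broadband 10.5–30 Hz) plus a theta oscillator in REM;
  EMG is white noise with state-ordered amplitude (wake > NREM > REM).
* Arena trajectories are biased random walks in a 30x30 cm arena holding
  a 9x9 cm cage; the attraction bias controls the expected
  social-interaction ratio.

Phenotype presets (``male_resilient``, ``male_susceptible``,
``female_resilient``, ``female_susceptible``) encode the qualitative
group contrasts the analysis is meant to detect: males have more, shorter
NREM bouts (especially in the dark phase) and higher SWA; females have
longer REM bouts; after defeat, susceptible females and resilient males
increase NREM sleep time; post-defeat arena bias is positive for
resilient and negative for susceptible animals.

All outputs are pure functions of (parameters, schedule, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ARTIFACT,
    DARK,
    EPOCH_S,
    LIGHT,
    NREM,
    REM,
    STATES,
    WAKE,
    ArenaSpec,
    Hypnogram,
    LightSchedule,
    Recording,
    Trajectory,
    hypnogram_to_frame,
)

EPOCHS_PER_DAY = int(24 * 3600 / EPOCH_S)  # 8640

DAY_KINDS = ("baseline", "sleep_restriction", "recovery", "defeat", "post_defeat")

PRESET_NAMES = (
    "male_resilient",
    "male_susceptible",
    "female_resilient",
    "female_susceptible",
)

# Mean dwell in 10 s epochs by (state, phase). Light-phase dwell means are
# calibrated so that expected light-phase sleep matches the reported
# sleep-lost anchors (~153/20 min NREM/REM per 6 h for males, ~147/19 for
# females). Males cycle faster through NREM in the dark (more, shorter
# NREM bouts); females hold REM longer.
_MALE_DWELL = {
    (WAKE, LIGHT): 15.4, (NREM, LIGHT): 12.6, (REM, LIGHT): 6.0,
    (WAKE, DARK): 32.0, (NREM, DARK): 10.0, (REM, DARK): 5.0,
}
_FEMALE_DWELL = {
    (WAKE, LIGHT): 21.0, (NREM, LIGHT): 16.0, (REM, LIGHT): 7.0,
    (WAKE, DARK): 45.0, (NREM, DARK): 13.0, (REM, DARK): 6.0,
}

def _trans(p_rem_light: float, p_rem_dark: float) -> dict:
    return {
        (WAKE, LIGHT): {NREM: 1.0},
        (WAKE, DARK): {NREM: 1.0},
        (NREM, LIGHT): {WAKE: 1.0 - p_rem_light, REM: p_rem_light},
        (NREM, DARK): {WAKE: 1.0 - p_rem_dark, REM: p_rem_dark},
        (REM, LIGHT): {WAKE: 1.0},
        (REM, DARK): {WAKE: 1.0},
    }

# Per-preset generative knobs. delta_scale multiplies NREM delta amplitude
# (males run higher SWA); parietal_delta_ratio sets the lead asymmetry;
# post_nrem_dwell_mult lengthens NREM bouts on the post-defeat day for the
# groups that gain NREM sleep after stress; arena biases (cm per step
# toward the cage) set the expected interaction ratio.
PRESETS: dict[str, dict] = {
    "male_resilient": dict(
        sex="M", dwell=_MALE_DWELL, trans=_trans(0.28, 0.15),
        delta_scale=1.18, parietal_delta_ratio=1.30,
        post_nrem_dwell_mult=1.40, bias_pre=0.0, bias_post=0.25,
    ),
    "male_susceptible": dict(
        sex="M", dwell=_MALE_DWELL, trans=_trans(0.34, 0.15),
        delta_scale=1.18, parietal_delta_ratio=1.10,
        post_nrem_dwell_mult=1.00, bias_pre=0.0, bias_post=-0.25,
    ),
    "female_resilient": dict(
        sex="F", dwell=_FEMALE_DWELL, trans=_trans(0.30, 0.15),
        delta_scale=1.00, parietal_delta_ratio=1.10,
        post_nrem_dwell_mult=1.00, bias_pre=0.0, bias_post=0.25,
    ),
    "female_susceptible": dict(
        sex="F", dwell=_FEMALE_DWELL, trans=_trans(0.30, 0.15),
        delta_scale=1.00, parietal_delta_ratio=1.10,
        post_nrem_dwell_mult=1.50, bias_pre=0.0, bias_post=-0.25,
    ),
}

# EEG band rms amplitudes (µV) by state; NREM delta is further scaled by
# the homeostat (see _nrem_delta_amp) and the preset delta_scale.
_EEG_AMPS = {
    WAKE: {"delta": 6.0, "theta": 5.0, "broad": 14.0},
    NREM: {"delta": 45.0, "theta": 8.0, "broad": 7.0},
    REM: {"delta": 4.0, "theta": 8.0, "broad": 5.0},
    ARTIFACT: {"delta": 0.0, "theta": 0.0, "broad": 0.0},
}
_REM_SINE_RMS = 15.0     # dominant theta oscillator in REM, µV rms
_BROAD_BAND = (10.5, 30.0)

_EMG_SIGMA = {WAKE: 20.0, NREM: 7.0, REM: 2.0, ARTIFACT: 20.0}

ARTIFACT_CLIP_UV = 800.0  # amplitude of injected clipping transients


@dataclass
class SimParams:
    """Generator parameters for one subject.

    Dwell means are in epochs by (state, phase); transition weights are
    conditional next-state weights by (state, phase). Process-S rises
    toward ``s_bounds[1]`` in wake with time constant ``s_tau_rise_h`` and
    decays toward ``s_bounds[0]`` in NREM with ``s_tau_fall_h``.
    """

    epoch_s: float = EPOCH_S
    state_dwell: dict = field(default_factory=lambda: dict(_FEMALE_DWELL))
    transition_weights: dict = field(default_factory=lambda: _trans(0.30, 0.15))
    s_tau_rise_h: float = 8.0
    s_tau_fall_h: float = 2.0
    s_bounds: tuple[float, float] = (0.1, 1.0)
    rem_theta_hz: tuple[float, float] = (6.0, 10.0)
    eeg_fs: float = 100.0
    emg_sigma: dict = field(default_factory=lambda: dict(_EMG_SIGMA))
    delta_scale: float = 1.0
    parietal_delta_ratio: float = 1.10
    post_nrem_dwell_mult: float = 1.0
    recovery_nrem_dwell_mult: float = 1.2
    bias_pre: float = 0.0
    bias_post: float = 0.0
    rem_s_mode: str = "hold"   # {"hold", "decay"}
    phenotype_preset: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for key, m in self.state_dwell.items():
            if m < 1:
                raise ValueError(f"dwell mean for {key} must be >= 1 epoch, got {m}")
        for (state, phase), weights in self.transition_weights.items():
            if state not in STATES or phase not in (LIGHT, DARK):
                raise ValueError(f"invalid transition key {(state, phase)}")
            for nxt, w in weights.items():
                if nxt not in STATES:
                    raise ValueError(f"invalid next state {nxt!r}")
                if w < 0:
                    raise ValueError("transition weights must be nonnegative")
                if nxt == REM and state != NREM and w > 0:
                    raise ValueError("REM may only be entered from NREM")
        if not self.s_bounds[0] < self.s_bounds[1]:
            raise ValueError("s_bounds must be increasing")
        if self.eeg_fs < 60:
            raise ValueError("eeg_fs must be >= 60 Hz (2x the 30 Hz analysis ceiling)")

    @classmethod
    def from_preset(cls, preset: str, seed: int = 0, **overrides) -> "SimParams":
        """Build parameters from one of the four phenotype/sex presets."""
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {PRESET_NAMES}")
        p = PRESETS[preset]
        kwargs = dict(
            state_dwell=dict(p["dwell"]),
            transition_weights=p["trans"],
            delta_scale=p["delta_scale"],
            parietal_delta_ratio=p["parietal_delta_ratio"],
            post_nrem_dwell_mult=p["post_nrem_dwell_mult"],
            bias_pre=p["bias_pre"],
            bias_post=p["bias_post"],
            phenotype_preset=preset,
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @property
    def sex(self) -> str | None:
        return PRESETS[self.phenotype_preset]["sex"] if self.phenotype_preset else None


@dataclass(frozen=True)
class DayPlan:
    """One protocol day: its kind and any forced-wake / defeat windows (ZT h)."""

    day_index: int
    kind: str
    forced_wake_window: tuple[float, float] | None = None
    defeat_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in DAY_KINDS:
            raise ValueError(f"unknown day kind {self.kind!r}")
        if self.kind == "sleep_restriction" and self.forced_wake_window != (0.0, 6.0):
            raise ValueError("sleep_restriction days must force wake over [ZT0, ZT6)")
        if self.kind == "defeat":
            w = self.defeat_window
            if w is None or not (12.0 <= w[0] < w[1] <= 14.0):
                raise ValueError("defeat windows must lie within [ZT12, ZT14)")


@dataclass
class ProtocolSchedule:
    """Ordered study timeline (baseline, restriction, defeats, post-defeat)."""

    days: list[DayPlan]

    def __post_init__(self) -> None:
        idx = [d.day_index for d in self.days]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("day indices must be strictly increasing")

    @property
    def n_days(self) -> int:
        return len(self.days)

    @classmethod
    def standard(cls, n_defeat_days: int = 10) -> "ProtocolSchedule":
        """Baseline, 6 h sleep restriction (ZT0–6), recovery, ten defeat
        days (defeats in the first 2 h of the dark period), post-defeat."""
        days = [
            DayPlan(0, "baseline"),
            DayPlan(1, "sleep_restriction", forced_wake_window=(0.0, 6.0)),
            DayPlan(2, "recovery"),
        ]
        for i in range(n_defeat_days):
            days.append(DayPlan(3 + i, "defeat", defeat_window=(12.0, 12.5)))
        days.append(DayPlan(3 + n_defeat_days, "post_defeat"))
        return cls(days)

    def day_of_kind(self, kind: str, which: int = 0) -> DayPlan:
        matches = [d for d in self.days if d.kind == kind]
        if not matches:
            raise ValueError(f"schedule has no {kind!r} day")
        return matches[which]


@dataclass
class HomeostatState:
    """Process-S sleep-pressure value (dimensionless, within s_bounds)."""

    s_value: float


def update_homeostat(state: HomeostatState, epoch_state: str, params: SimParams,
                     dt_s: float | None = None) -> HomeostatState:
    """Advance Process S across one epoch of the given vigilance state.

    Wake (and artifact-obscured epochs, which are mostly wake) drive a
    saturating exponential rise toward the upper bound; NREM discharges
    toward the lower bound; REM holds by default (or decays slowly with
    4x the NREM time constant when ``rem_s_mode='decay'``).
    """
    dt = params.epoch_s if dt_s is None else dt_s
    s_lo, s_hi = params.s_bounds
    s = state.s_value
    if not s_lo <= s <= s_hi:
        raise ValueError(f"s_value {s} outside bounds {params.s_bounds}")
    if epoch_state in (WAKE, ARTIFACT):
        s = s_hi - (s_hi - s) * math.exp(-dt / (params.s_tau_rise_h * 3600.0))
    elif epoch_state == NREM:
        s = s_lo + (s - s_lo) * math.exp(-dt / (params.s_tau_fall_h * 3600.0))
    elif epoch_state == REM:
        if params.rem_s_mode == "decay":
            s = s_lo + (s - s_lo) * math.exp(-dt / (4.0 * params.s_tau_fall_h * 3600.0))
    else:
        raise ValueError(f"unknown epoch state {epoch_state!r}")
    return HomeostatState(min(max(s, s_lo), s_hi))


def homeostat_trajectory(hyp: Hypnogram, params: SimParams,
                         s0: float | None = None) -> np.ndarray:
    """Process-S value at the onset of every epoch of a hypnogram."""
    s_lo, s_hi = params.s_bounds
    state = HomeostatState(0.5 * (s_lo + s_hi) if s0 is None else s0)
    out = np.empty(hyp.n_epochs)
    for i, lab in enumerate(hyp.states):
        out[i] = state.s_value
        state = update_homeostat(state, lab, params)
    return out


def _windows_to_epochs(day: DayPlan) -> list[tuple[int, int]]:
    wins = []
    for w in (day.forced_wake_window, day.defeat_window):
        if w is not None:
            wins.append((int(w[0] * 360), int(w[1] * 360)))  # 360 epochs/h
    return sorted(wins)


def _simulate_day(rng: np.random.Generator, params: SimParams, day: DayPlan,
                  light: LightSchedule) -> np.ndarray:
    dwell = dict(params.state_dwell)
    if day.kind == "post_defeat" and params.post_nrem_dwell_mult != 1.0:
        for phase in (LIGHT, DARK):
            dwell[(NREM, phase)] = dwell[(NREM, phase)] * params.post_nrem_dwell_mult
    elif day.kind == "sleep_restriction" and params.recovery_nrem_dwell_mult != 1.0:
        # rebound sleep in the 18 h after forced wake ends: longer NREM
        # bouts (the forced-wake window itself contains no sleep anyway)
        for phase in (LIGHT, DARK):
            dwell[(NREM, phase)] = dwell[(NREM, phase)] * params.recovery_nrem_dwell_mult
    forced = _windows_to_epochs(day)

    n = EPOCHS_PER_DAY
    states = np.empty(n, dtype=object)
    t = 0
    state = WAKE
    while t < n:
        active = next((w for w in forced if w[0] <= t < w[1]), None)
        if active is not None:
            states[t:active[1]] = WAKE
            t = active[1]
            state = WAKE
            continue
        phase = light.phase_at(t * params.epoch_s)
        mean = dwell[(state, phase)]
        length = int(rng.geometric(1.0 / mean))
        end = min(t + length, n)
        upcoming = [w[0] for w in forced if w[0] > t]
        if upcoming:
            end = min(end, upcoming[0])
        states[t:end] = state
        t = end
        weights = params.transition_weights[(state, phase)]
        nxts = list(weights)
        probs = np.array([weights[s] for s in nxts], dtype=float)
        total = probs.sum()
        if total <= 0:
            raise ValueError(f"no outgoing transition from {(state, phase)}")
        state = nxts[rng.choice(len(nxts), p=probs / total)]
    return states


def simulate_hypnogram(params: SimParams, schedule: ProtocolSchedule,
                       light: LightSchedule | None = None) -> Hypnogram:
    """Simulate one concatenated hypnogram over the whole protocol.

    Each day is a full 24 h (8640 epochs of 10 s) starting at ZT0. During
    forced-wake and defeat windows every epoch is WAKE. Deterministic for
    a given (params, schedule, seed).
    """
    light = light or LightSchedule()
    rng = np.random.default_rng(params.seed)
    chunks = [_simulate_day(rng, params, day, light) for day in schedule.days]
    return Hypnogram(np.concatenate(chunks), params.epoch_s, 0.0)


def _nrem_delta_amp(params: SimParams, s: np.ndarray) -> np.ndarray:
    """NREM delta rms amplitude (µV) as a function of Process S."""
    s_lo, s_hi = params.s_bounds
    s_norm = (np.asarray(s) - s_lo) / (s_hi - s_lo)
    return _EEG_AMPS[NREM]["delta"] * params.delta_scale * (0.4 + 0.6 * s_norm)


def _band_amp_table(hyp: Hypnogram, s_traj: np.ndarray, params: SimParams,
                    channel: str) -> dict[str, np.ndarray]:
    n = hyp.n_epochs
    amps = {b: np.zeros(n) for b in ("delta", "theta", "broad")}
    for state in (WAKE, NREM, REM):
        m = hyp.mask(state)
        for b in amps:
            amps[b][m] = _EEG_AMPS[state][b]
    nrem = hyp.mask(NREM)
    amps["delta"][nrem] = _nrem_delta_amp(params, s_traj[nrem])
    if channel == "eeg_parietal":
        amps["delta"] = amps["delta"] * params.parietal_delta_ratio
    return amps


def truth_band_powers(hyp: Hypnogram, s_traj: np.ndarray, params: SimParams,
                      channel: str = "eeg_frontal") -> pd.DataFrame:
    """Analytic per-epoch band powers (µV²) the synthesizer would produce.

    Because each band component is normalised to an exact per-epoch rms,
    band power equals amplitude squared (plus the REM oscillator in
    theta); this gives a fast signal-free route for workflows that only
    need spectral aggregates.
    """
    amps = _band_amp_table(hyp, s_traj, params, channel)
    delta = amps["delta"] ** 2
    theta = amps["theta"] ** 2
    theta[hyp.mask(REM)] += _REM_SINE_RMS**2
    total = delta + theta + amps["broad"] ** 2
    art = hyp.mask(ARTIFACT)
    for arr in (delta, theta, total):
        arr[art] = np.nan
    return pd.DataFrame({"delta": delta, "theta": theta, "total": total})


def _unit_band_noise(rng: np.random.Generator, n_ep: int, n_per: int, fs: float,
                     lo: float, hi: float) -> np.ndarray:
    """Per-epoch unit-rms Gaussian noise confined to [lo, hi) Hz."""
    freqs = np.fft.rfftfreq(n_per, d=1.0 / fs)
    mask = (freqs >= lo) & (freqs < hi)
    noise = rng.standard_normal((n_ep, n_per))
    spec = np.fft.rfft(noise, axis=1)
    spec[:, ~mask] = 0.0
    x = np.fft.irfft(spec, n=n_per, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def _write_artifact_transients(sig: np.ndarray, art_idx: np.ndarray, n_per: int,
                               rng: np.random.Generator) -> None:
    """Overwrite part of each flagged epoch with a clipping square burst."""
    for i in art_idx:
        start = i * n_per + int(rng.integers(0, n_per // 2))
        length = n_per // 5
        burst = ARTIFACT_CLIP_UV * np.sign(
            np.sin(2 * np.pi * np.arange(length) / (length / 4.0) + 1e-3)
        )
        sig[start:start + length] = burst


def synthesize_signals(hyp: Hypnogram, s_traj, params: SimParams,
                       seed: int | None = None) -> Recording:
    """Render EEG (frontal + parietal) and EMG for a hypnogram.

    Per epoch the EEG is a mixture of unit-rms band noises scaled to
    state-dependent amplitudes; NREM delta amplitude scales monotonically
    with Process S, REM epochs carry a dominant theta oscillator on an
    exact 0.1 Hz bin, and ARTIFACT epochs carry clipping transients. EMG
    is zero-mean white noise with wake > NREM > REM scale.
    """
    s_traj = np.asarray(s_traj, dtype=float)
    if len(s_traj) != hyp.n_epochs:
        raise ValueError("s trajectory and hypnogram must have equal epoch count")
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    fs = params.eeg_fs
    n_ep, n_per = hyp.n_epochs, int(round(fs * params.epoch_s))
    bands = {"delta": (0.5, 4.0), "theta": (6.0, 10.0), "broad": _BROAD_BAND}

    rem_idx = np.flatnonzero(hyp.mask(REM))
    th_lo, th_hi = params.rem_theta_hz
    grid = np.arange(math.ceil((th_lo + 0.5) * 10), math.floor((th_hi - 0.5) * 10) + 1) / 10.0
    rem_f = rng.choice(grid, size=rem_idx.size)
    rem_phase = rng.uniform(0, 2 * np.pi, size=rem_idx.size)
    tvec = np.arange(n_per) / fs

    channels: dict[str, np.ndarray] = {}
    art_idx = np.flatnonzero(hyp.mask(ARTIFACT))
    for ch in ("eeg_frontal", "eeg_parietal"):
        amps = _band_amp_table(hyp, s_traj, params, ch)
        sig = np.zeros((n_ep, n_per))
        for b, (lo, hi) in bands.items():
            sig += amps[b][:, None] * _unit_band_noise(rng, n_ep, n_per, fs, lo, hi)
        if rem_idx.size:
            sig[rem_idx] += (_REM_SINE_RMS * math.sqrt(2.0)) * np.sin(
                2 * np.pi * rem_f[:, None] * tvec[None, :] + rem_phase[:, None]
            )
        sig = sig.ravel()
        _write_artifact_transients(sig, art_idx, n_per, rng)
        channels[ch] = sig

    emg_scale = np.empty(n_ep)
    for state, sigma in params.emg_sigma.items():
        emg_scale[hyp.mask(state)] = sigma
    emg = (emg_scale[:, None] * rng.standard_normal((n_ep, n_per))).ravel()
    _write_artifact_transients(emg, art_idx, n_per, rng)
    channels["emg"] = emg

    return Recording(channels, fs=fs, zt_start_s=hyp.zt_start_s)


def inject_artifacts(rec: Recording, hyp: Hypnogram, fraction: float,
                     seed: int = 0) -> tuple[Recording, Hypnogram]:
    """Relabel round(fraction * n) random epochs as ARTIFACT and write
    clipping transients into every channel at those epochs. Inputs are not
    modified; positions are reproducible from the seed."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    k = int(round(fraction * hyp.n_epochs))
    if k == 0:
        return rec, hyp
    rng = np.random.default_rng(seed)
    idx = rng.choice(hyp.n_epochs, size=k, replace=False)
    new_hyp = hyp.copy()
    new_hyp.states[idx] = ARTIFACT
    new_rec = rec.copy()
    n_per = int(round(rec.fs * hyp.epoch_s))
    for sig in new_rec.channels.values():
        _write_artifact_transients(sig, idx, n_per, rng)
    return new_rec, new_hyp


def _simulate_trial(rng: np.random.Generator, spec: ArenaSpec, bias: float,
                    trial: str, fs: float = 10.0, step_sigma: float = 0.8) -> Trajectory:
    n = int(spec.trial_s * fs)
    cx, cy = spec.cage_center
    half = spec.cage_side_cm / 2.0
    side = spec.side_cm
    x, y = side / 2.0, side / 2.0
    steps = rng.standard_normal((n, 2)) * step_sigma
    xs = np.empty(n)
    ys = np.empty(n)
    for i in range(n):
        dx, dy = steps[i]
        if bias != 0.0:
            ux, uy = cx - x, cy - y
            norm = math.hypot(ux, uy)
            if norm > 1e-9:
                dx += bias * ux / norm
                dy += bias * uy / norm
        nx, ny = x + dx, y + dy
        # reflect at walls
        if nx < 0:
            nx = -nx
        elif nx > side:
            nx = 2 * side - nx
        if ny < 0:
            ny = -ny
        elif ny > side:
            ny = 2 * side - ny
        # the cage is solid: reject steps ending inside it
        if not (abs(nx - cx) < half and abs(ny - cy) < half):
            x, y = nx, ny
        xs[i] = x
        ys[i] = y
    t = np.arange(n) / fs
    return Trajectory(t, xs, ys, trial=trial, arena=spec)


def simulate_arena(spec: ArenaSpec, attraction_bias: float,
                   seed: int = 0) -> tuple[Trajectory, Trajectory]:
    """Simulate the two consecutive 3 min interaction trials.

    Returns (empty-cage trial, target trial). The target trial adds a
    drift of ``attraction_bias`` cm/step toward the cage (negative values
    model avoidance); the empty trial is unbiased. Zero bias gives
    statistically identical trials, hence symmetric occupancy in
    expectation.
    """
    rng = np.random.default_rng(seed)
    empty = _simulate_trial(rng, spec, 0.0, "empty")
    target = _simulate_trial(rng, spec, attraction_bias, "target")
    return empty, target


@dataclass
class CohortBundle:
    """Everything one synthetic study cohort comprises."""

    design: pd.DataFrame                    # subject_id, pair, sex, phenotype, preset, seed
    schedule: ProtocolSchedule
    params: dict[str, SimParams]            # by subject_id
    hypnograms: dict[tuple[str, int], Hypnogram]      # (subject_id, day_index)
    s_trajectories: dict[str, np.ndarray]   # per subject, concatenated over days
    recordings: dict[tuple[str, int], Recording]
    trajectories: dict[tuple[str, str, str], Trajectory]  # (subject, pre|post, empty|target)
    manifest: dict

    def day_hypnogram(self, subject_id: str, day_index: int) -> Hypnogram:
        return self.hypnograms[(subject_id, day_index)]

    def day_s(self, subject_id: str, day_index: int) -> np.ndarray:
        pos = [d.day_index for d in self.schedule.days].index(day_index)
        return self.s_trajectories[subject_id][
            pos * EPOCHS_PER_DAY:(pos + 1) * EPOCHS_PER_DAY
        ]


def simulate_cohort(n_pairs: int, schedule: ProtocolSchedule | None = None,
                    seed: int = 0, presets: dict[str, str] | None = None,
                    artifact_fraction: float = 0.01,
                    signal_days: tuple[str, ...] = ("baseline", "sleep_restriction",
                                                    "recovery", "post_defeat"),
                    synthesize: bool = True,
                    out_dir: str | Path | None = None) -> CohortBundle:
    """Simulate a full male–female-pair cohort through the protocol.

    Each pair contributes one male and one female subject. Phenotypes
    alternate across pairs so groups stay balanced unless ``presets``
    (mapping subject_id -> preset name) overrides them. Per-subject child
    seeds are drawn from ``numpy.random.SeedSequence(seed).spawn``, so the
    whole bundle is a pure function of the master seed.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    schedule = schedule or ProtocolSchedule.standard()
    light = LightSchedule()

    subjects = []
    for pair in range(n_pairs):
        res_first = pair % 2 == 0
        subjects.append((f"m{pair:02d}", pair, "male_resilient" if res_first
                         else "male_susceptible"))
        subjects.append((f"f{pair:02d}", pair, "female_susceptible" if res_first
                         else "female_resilient"))
    if presets:
        unknown = set(presets) - {s[0] for s in subjects}
        if unknown:
            raise ValueError(f"presets given for unknown subjects: {sorted(unknown)}")
        subjects = [(sid, pair, presets.get(sid, ps)) for sid, pair, ps in subjects]

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(subjects))

    design_rows = []
    params_by_subject: dict[str, SimParams] = {}
    hypnograms: dict[tuple[str, int], Hypnogram] = {}
    s_trajs: dict[str, np.ndarray] = {}
    recordings: dict[tuple[str, int], Recording] = {}
    trajectories: dict[tuple[str, str, str], Trajectory] = {}
    day_indices = [d.day_index for d in schedule.days]

    for (sid, pair, preset), child in zip(subjects, children):
        sub_seeds = child.generate_state(4)  # hypnogram, signals, arena pre, arena post
        p = SimParams.from_preset(preset, seed=int(sub_seeds[0] % 2**31))
        params_by_subject[sid] = p
        full = simulate_hypnogram(p, schedule, light)
        s_full = homeostat_trajectory(full, p)
        s_trajs[sid] = s_full
        sig_rng = np.random.default_rng(int(sub_seeds[1] % 2**31))
        for pos, day in enumerate(schedule.days):
            sl = slice(pos * EPOCHS_PER_DAY, (pos + 1) * EPOCHS_PER_DAY)
            hyp = Hypnogram(full.states[sl].copy(), p.epoch_s, 0.0)
            if synthesize and day.kind in signal_days:
                rec = synthesize_signals(hyp, s_full[sl], p,
                                         seed=int(sig_rng.integers(2**31)))
                if artifact_fraction > 0:
                    rec, hyp = inject_artifacts(rec, hyp, artifact_fraction,
                                                seed=int(sig_rng.integers(2**31)))
                recordings[(sid, day.day_index)] = rec
            hypnograms[(sid, day.day_index)] = hyp
        spec = ArenaSpec()
        for when, bias, sd in (("pre", p.bias_pre, sub_seeds[2]),
                               ("post", p.bias_post, sub_seeds[3])):
            empty, target = simulate_arena(spec, bias, seed=int(sd % 2**31))
            trajectories[(sid, when, "empty")] = empty
            trajectories[(sid, when, "target")] = target
        design_rows.append(
            {"subject_id": sid, "pair": pair, "sex": PRESETS[preset]["sex"],
             "phenotype": preset.split("_")[1], "preset": preset,
             "seed": int(sub_seeds[0] % 2**31)}
        )

    design = pd.DataFrame(design_rows)
    manifest = {
        "n_pairs": n_pairs,
        "master_seed": seed,
        "artifact_fraction": artifact_fraction,
        "schedule": [
            {"day_index": d.day_index, "kind": d.kind,
             "forced_wake_window": d.forced_wake_window,
             "defeat_window": d.defeat_window}
            for d in schedule.days
        ],
        "subjects": design_rows,
        "signal_days": list(signal_days),
    }
    bundle = CohortBundle(design, schedule, params_by_subject, hypnograms,
                          s_trajs, recordings, trajectories, manifest)
    if out_dir is not None:
        _write_cohort(bundle, Path(out_dir))
    return bundle


def _write_cohort(bundle: CohortBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for (sid, day), hyp in sorted(bundle.hypnograms.items()):
        name = f"{sid}_day{day:02d}_hypnogram.csv"
        hypnogram_to_frame(hyp).to_csv(out_dir / name, index=False)
        files.append(name)
    for (sid, when, trial), traj in sorted(bundle.trajectories.items()):
        name = f"{sid}_{when}_{trial}_trajectory.csv"
        pd.DataFrame({"t_s": traj.t_s, "x_cm": traj.x_cm, "y_cm": traj.y_cm,
                      "trial": trial}).to_csv(out_dir / name, index=False)
        files.append(name)
    manifest = dict(bundle.manifest)
    manifest["files"] = files
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
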