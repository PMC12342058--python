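"""Core containers shared across the pipeline.

All signals are in microvolts (µV), time in seconds, positions in cm.
Zeitgeber time (ZT) is referenced to lights-on: ZT0 = lights on, ZT12 =
lights off under the default 12:12 light:dark schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical epoch length for sleep scoring, seconds.
EPOCH_S = 10.0

WAKE = "WAKE"
NREM = "NREM"
REM = "REM"
ARTIFACT = "ARTIFACT"

#: Vigilance states a scored epoch can take.
STATES = (WAKE, NREM, REM, ARTIFACT)
#: States that represent actual sleep ("total sleep" = NREM + REM).
SLEEP_STATES = (NREM, REM)

LIGHT = "light"
DARK = "dark"


@dataclass(frozen=True)
class LightSchedule:
    """12:12 light:dark cycle by default; ZT0 is lights-on by definition."""

    lights_on_zt: float = 0.0
    period_h: float = 24.0
    light_hours: float = 12.0

    def __post_init__(self) -> None:
        if not 0 < self.light_hours < self.period_h:
            raise ValueError(
                f"light_hours must lie in (0, {self.period_h}), got {self.light_hours}"
            )

    def phase_at(self, zt_s):
        """Return 'light'/'dark' for ZT time(s) given in seconds."""
        zt_h = (np.asarray(zt_s, dtype=float) / 3600.0) % self.period_h
        out = np.where(zt_h < self.light_hours, LIGHT, DARK)
        return out if out.ndim else out.item()


@dataclass
class Hypnogram:
    """Per-epoch vigilance-state labels aligned to Zeitgeber time.

    Parameters
    ----------
    states : array of str
        One label per epoch, each in :data:`STATES`.
    epoch_s : float
        Epoch length in seconds (10 s scoring convention).
    zt_start_s : float
        ZT of the first epoch's onset, seconds from lights-on.
    """

    states: np.ndarray
    epoch_s: float = EPOCH_S
    zt_start_s: float = 0.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=object)
        if self.states.size < 1:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = set(self.states) - set(STATES)
        if bad:
            raise ValueError(f"invalid state labels: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return int(self.states.size)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    def epoch_zt_s(self) -> np.ndarray:
        """ZT onset (s) of every epoch."""
        return self.zt_start_s + np.arange(self.n_epochs) * self.epoch_s

    @property
    def artifact_fraction(self) -> float:
        return float(np.mean(self.states == ARTIFACT))

    def mask(self, state: str) -> np.ndarray:
        return np.asarray(self.states == state)

    def copy(self) -> "Hypnogram":
        return Hypnogram(self.states.copy(), self.epoch_s, self.zt_start_s)


@dataclass
class Recording:
    """Multi-channel EEG/EMG signal block with sampling-rate metadata.

    Channels are named arrays in µV; the conventional channel set is
    ``eeg_frontal``, ``eeg_parietal`` and ``emg``. EEG is assumed low-pass
    filtered with a 30 Hz analysis ceiling, so ``fs`` must be >= 60 Hz.
    """

    channels: dict[str, np.ndarray]
    fs: float
    zt_start_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("recording needs at least one channel")
        lengths = {name: len(sig) for name, sig in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"unequal channel lengths: {lengths}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return Recording(
            {k: v.copy() for k, v in self.channels.items()}, self.fs, self.zt_start_s
        )


@dataclass(frozen=True)
class ArenaSpec:
    """Square social-interaction arena holding a small wire cage.

    Defaults follow the common configuration: 30x30 cm arena, 9x9 cm cage
    centred against one wall, 15 cm interaction zone, 3 min trials.
    """

    side_cm: float = 30.0
    cage_center: tuple[float, float] = (15.0, 4.5)
    cage_side_cm: float = 9.0
    interaction_radius_cm: float = 15.0
    trial_s: float = 180.0

    def __post_init__(self) -> None:
        cx, cy = self.cage_center
        half = self.cage_side_cm / 2.0
        if not (0 <= cx - half and cx + half <= self.side_cm
                and 0 <= cy - half and cy + half <= self.side_cm):
            raise ValueError("cage does not fit inside the arena")
        if self.interaction_radius_cm <= 0:
            raise ValueError("interaction radius must be positive")
        if self.trial_s <= 0:
            raise ValueError("trial duration must be positive")


@dataclass
class Trajectory:
    """Timestamped 2-D positions of the test animal inside the arena."""

    t_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    trial: str = "empty"  # {empty, target}
    arena: ArenaSpec = field(default_factory=ArenaSpec)

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        if not (len(self.t_s) == len(self.x_cm) == len(self.y_cm)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t_s) >= 2 and np.any(np.diff(self.t_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.t_s)

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0]) if self.n_samples > 1 else 0.0


def hypnogram_to_frame(hyp: Hypnogram):
    """Hypnogram -> DataFrame (epoch_index, zt_start_s, state)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "epoch_index": np.arange(hyp.n_epochs),
            "zt_start_s": hyp.epoch_zt_s(),
            "state": hyp.states,
        }
    )


def hypnogram_from_frame(df, epoch_s: float = EPOCH_S) -> Hypnogram:
    zt0 = float(df["zt_start_s"].iloc[0]) if "zt_start_s" in df else 0.0
    return Hypnogram(df["state"].to_numpy(dtype=object), epoch_s, zt0)
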