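"""Rule-based sleep staging of EEG/EMG recordings in 10 s epochs.

The stager operationalizes the classical visual criteria: wake is
low-voltage, high-frequency EEG with high EMG tone; NREM is high-voltage
delta-dominant EEG with low EMG; REM is low-voltage EEG with dominant
6–10 Hz theta and muscle atonia. Epochs are classified independently
(no transition smoothing by default; a 3-epoch majority filter is
available behind a flag).

Thresholds default to per-recording feature quantiles, which makes the
decisions invariant to overall amplitude scale. The decision rule per
epoch, applied in order:

1. artifact screens (absolute amplitude, total-power z-score);
2. EMG RMS above the wake threshold -> WAKE;
3. else theta/delta ratio above the REM ratio and delta below the NREM
   threshold -> REM;
4. else delta above the NREM threshold -> NREM;
5. else WAKE.

Recordings with more than 5% artifact epochs are excluded from all
analyses (strict inequality: exactly 5% is still included).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ARTIFACT, EPOCH_S, NREM, REM, WAKE, Hypnogram, Recording
from .spectral import epoch_band_powers

logger = logging.getLogger(__name__)

#: Fraction of artifact epochs above which a file is excluded.
ARTIFACT_EXCLUSION_FRACTION = 0.05

#: Default channel used for staging decisions (the parietal lead is kept
#: for lead-specific SWA analyses).
STAGING_CHANNEL = "eeg_frontal"


@dataclass
class StagerThresholds:
    """Resolved (absolute) decision thresholds for one recording."""

    emg_wake: float                 # µV RMS above which an epoch is wake
    delta_nrem: float               # µV² above which delta marks NREM
    theta_delta_rem_ratio: float = 1.5
    artifact_amplitude_uv: float = 500.0
    artifact_power_zscore: float = 6.0
    mode: str = "per-recording-quantile"


def extract_features(rec: Recording, epoch_s: float = EPOCH_S,
                     staging_channel: str = STAGING_CHANNEL) -> pd.DataFrame:
    """Per-epoch band powers and EMG RMS.

    Returns a DataFrame with columns ``delta``, ``theta``, ``total``
    (µV², staging channel), ``delta_parietal``, ``total_parietal`` when a
    parietal lead is present, ``emg_rms`` (µV) and ``peak_amp`` (µV, max
    absolute amplitude over all channels). A trailing partial epoch is
    dropped with a logged warning.
    """
    if "emg" not in rec.channels:
        raise ValueError("recording has no 'emg' channel")
    if staging_channel not in rec.channels:
        raise ValueError(f"recording has no {staging_channel!r} channel")
    if rec.fs < 60:
        raise ValueError("sampling rate too low for 30 Hz analysis")
    n_per = int(round(rec.fs * epoch_s))
    n_ep = rec.n_samples // n_per
    if rec.n_samples % n_per:
        logger.warning("dropping trailing partial epoch (%d samples)",
                       rec.n_samples % n_per)
    feats = epoch_band_powers(rec.channels[staging_channel], rec.fs, epoch_s)
    if "eeg_parietal" in rec.channels and staging_channel != "eeg_parietal":
        par = epoch_band_powers(rec.channels["eeg_parietal"], rec.fs, epoch_s)
        feats["delta_parietal"] = par["delta"]
        feats["total_parietal"] = par["total"]
    emg = rec.channels["emg"][: n_ep * n_per].reshape(n_ep, n_per)
    feats["emg_rms"] = np.sqrt(np.mean(emg**2, axis=1))
    peak = np.zeros(n_ep)
    for sig in rec.channels.values():
        seg = np.abs(sig[: n_ep * n_per]).reshape(n_ep, n_per)
        peak = np.maximum(peak, seg.max(axis=1))
    feats["peak_amp"] = peak
    return feats


def _gap_threshold(values: np.ndarray, q: float) -> float:
    """Quantile threshold moved to the midpoint of the empirical gap.

    Decision rules compare features with strict inequalities, so a
    threshold that coincides with a mass of identical feature values
    would split that mass on floating-point noise. Placing the cut
    halfway between the quantile value and the next distinct value above
    it removes the knife edge; for continuously distributed features the
    adjustment is negligible.
    """
    v = values[np.isfinite(values)]
    thr = float(np.quantile(v, q))
    above = v[v > thr * (1 + 1e-9) + 1e-12]
    if above.size:
        thr = 0.5 * (thr + float(above.min()))
    return thr


def calibrate_thresholds(features: pd.DataFrame,
                         emg_wake_quantile: float = 0.60,
                         delta_nrem_quantile: float = 0.55,
                         theta_delta_rem_ratio: float = 1.5,
                         artifact_amplitude_uv: float = 500.0,
                         artifact_power_zscore: float = 6.0,
                         mode: str = "per-recording-quantile") -> StagerThresholds:
    """Set thresholds from per-recording feature quantiles.

    Quantile calibration makes staging invariant to the amplitude scale
    of the recording. Fewer than 360 epochs (1 h) triggers a warning;
    constant features are rejected because no quantile can separate them.
    """
    if not 0 < emg_wake_quantile < 1 or not 0 < delta_nrem_quantile < 1:
        raise ValueError("quantiles must lie in (0, 1)")
    if len(features) < 360:
        logger.warning("calibrating thresholds on only %d epochs (< 360)",
                       len(features))
    for col in ("emg_rms", "delta"):
        v = features[col].to_numpy(dtype=float)
        if np.ptp(v[np.isfinite(v)]) == 0:
            raise ValueError(f"feature {col!r} is constant; cannot calibrate")
    if mode == "per-recording-quantile":
        emg_thr = _gap_threshold(features["emg_rms"].to_numpy(float), emg_wake_quantile)
        delta_thr = _gap_threshold(features["delta"].to_numpy(float), delta_nrem_quantile)
    elif mode == "absolute":
        emg_thr = emg_wake_quantile     # interpreted as absolute values
        delta_thr = delta_nrem_quantile
    else:
        raise ValueError(f"unknown calibration mode {mode!r}")
    return StagerThresholds(emg_wake=emg_thr, delta_nrem=delta_thr,
                            theta_delta_rem_ratio=theta_delta_rem_ratio,
                            artifact_amplitude_uv=artifact_amplitude_uv,
                            artifact_power_zscore=artifact_power_zscore,
                            mode=mode)


def detect_artifacts(rec: Recording | None, features: pd.DataFrame,
                     thr: StagerThresholds) -> np.ndarray:
    """Boolean artifact mask per epoch.

    An epoch is flagged if its absolute amplitude (any channel) exceeds
    ``artifact_amplitude_uv`` or its total-power z-score exceeds
    ``artifact_power_zscore``. All-zero recordings make the z-score
    undefined and raise.
    """
    total = features["total"].to_numpy(dtype=float)
    sd = float(np.std(total))
    if sd == 0:
        if np.all(total == 0):
            raise ValueError("all-zero signal: power z-score undefined")
        return np.zeros(len(features), dtype=bool)
    z = (total - np.mean(total)) / sd
    mask = z > thr.artifact_power_zscore
    if "peak_amp" in features:
        mask |= features["peak_amp"].to_numpy(dtype=float) > thr.artifact_amplitude_uv
    return mask


def classify_epochs(features: pd.DataFrame, thr: StagerThresholds,
                    artifact_mask: np.ndarray | None = None,
                    majority_filter: bool = False) -> Hypnogram:
    """Apply the ordered decision rule to every epoch.

    Pure function of (features, thresholds, artifact mask). With
    ``majority_filter`` a 3-epoch majority vote smooths isolated
    single-epoch states (off by default: scoring is epoch-wise).
    """
    n = len(features)
    emg = features["emg_rms"].to_numpy(dtype=float)
    delta = features["delta"].to_numpy(dtype=float)
    theta = features["theta"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta > 0, theta / delta, np.inf)

    states = np.full(n, WAKE, dtype=object)
    is_rem = (ratio > thr.theta_delta_rem_ratio) & (delta <= thr.delta_nrem)
    is_nrem = delta > thr.delta_nrem
    states[is_rem] = REM
    states[is_nrem & ~is_rem] = NREM
    states[emg > thr.emg_wake] = WAKE
    if artifact_mask is not None:
        states[np.asarray(artifact_mask, dtype=bool)] = ARTIFACT
    if majority_filter:
        states = _majority3(states)
    return Hypnogram(states)


def _majority3(states: np.ndarray) -> np.ndarray:
    out = states.copy()
    for i in range(1, len(states) - 1):
        if states[i - 1] == states[i + 1] != states[i] and states[i - 1] != ARTIFACT:
            out[i] = states[i - 1]
    return out


def stage_recording(rec: Recording, thresholds: StagerThresholds | None = None,
                    **calibration_kwargs) -> tuple[Hypnogram, StagerThresholds]:
    """Convenience: extract features, calibrate, screen artifacts, classify."""
    features = extract_features(rec)
    thr = thresholds or calibrate_thresholds(features, **calibration_kwargs)
    mask = detect_artifacts(rec, features, thr)
    return classify_epochs(features, thr, artifact_mask=mask), thr


@dataclass
class ExclusionResult:
    included: bool
    artifact_fraction: float


def exclusion_check(hyp: Hypnogram) -> ExclusionResult:
    """Exclude a file iff its artifact fraction exceeds 5% (strict)."""
    frac = hyp.artifact_fraction
    return ExclusionResult(included=frac <= ARTIFACT_EXCLUSION_FRACTION,
                           artifact_fraction=frac)


def agreement(h1: Hypnogram, h2: Hypnogram,
              ignore_mask: np.ndarray | None = None) -> float:
    """Epoch-wise percent agreement between two hypnograms.

    ARTIFACT counts as a class. ``ignore_mask`` drops epochs (e.g. known
    injected artifacts) from both numerator and denominator.
    """
    if h1.n_epochs != h2.n_epochs or h1.epoch_s != h2.epoch_s:
        raise ValueError("hypnograms must have equal length and epoch size")
    match = h1.states == h2.states
    if ignore_mask is not None:
        keep = ~np.asarray(ignore_mask, dtype=bool)
        if not keep.any():
            raise ValueError("ignore mask removes every epoch")
        match = match[keep]
    return 100.0 * float(np.mean(match))


def read_recording_edf(path, zt_start_s: float = 0.0) -> Recording:
    """Read an EDF file into a :class:`Recording` (requires ``mne``).

    Channel names are lower-cased; channels named like ``EEG1``/``frontal``
    map to ``eeg_frontal``, ``EEG2``/``parietal`` to ``eeg_parietal`` and
    anything containing ``emg`` to ``emg``.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> µV
    channels = {}
    for name, row in zip(raw.ch_names, data):
        low = name.lower()
        if "emg" in low:
            key = "emg"
        elif "front" in low or low.endswith("1"):
            key = "eeg_frontal"
        elif "pariet" in low or low.endswith("2"):
            key = "eeg_parietal"
        else:
            key = low
        channels[key] = row
    return Recording(channels, fs=float(raw.info["sfreq"]), zt_start_s=zt_start_s)
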