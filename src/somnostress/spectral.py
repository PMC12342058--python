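"""Per-epoch power spectra and slow-wave metrics.

Spectra are computed by a plain FFT of each 10 s epoch. A 10 s window at
any sampling rate has a native frequency resolution of 0.1 Hz, so no
zero-padding is needed. Power is returned as a one-sided density (µV²/Hz)
satisfying Parseval's theorem: sum(power) * 0.1 Hz equals the mean squared
signal.

Band conventions (µV², obtained by integrating the density over the band):

* delta — 0.5–4 Hz, the slow-wave band; its power during NREM sleep is the
  slow-wave activity (SWA).
* theta — 6–10 Hz, dominant during REM sleep.
* total — 0.5–30 Hz, the full analysed range (EEG is low-passed at 30 Hz).

Bands are half-open ``[lo, hi)`` so that delta + (4–30 Hz) partitions the
total band without double-counting the 4 Hz bin; pass ``closed=True`` to
``band_power`` for closed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EPOCH_S

DELTA_BAND = (0.5, 4.0)
THETA_BAND = (6.0, 10.0)
TOTAL_BAND = (0.5, 30.0)

#: Native analysis resolution for 10 s epochs, Hz.
FREQ_RESOLUTION = 0.1


@dataclass
class Spectrum:
    """One-sided power spectral density of a single epoch."""

    freqs: np.ndarray        # Hz, uniform 0.1 Hz grid from 0
    power: np.ndarray        # µV²/Hz
    epoch_index: int | None = None

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def epoch_spectrum(segment, fs: float, window: str = "rect",
                   epoch_index: int | None = None) -> Spectrum:
    """Power spectral density of one 10 s epoch.

    Parameters
    ----------
    segment : array
        Exactly 10 s of signal (``len == fs * 10``), µV.
    fs : float
        Sampling rate, Hz; must be >= 60 Hz for a 30 Hz analysis ceiling.
    window : {"rect", "hann"}
        Taper applied before the FFT. The default is the raw (rectangular)
        FFT; the Hann estimate is power-corrected so Parseval still holds
        in expectation.
    """
    x = np.asarray(segment, dtype=float)
    if fs < 60:
        raise ValueError(f"fs={fs} Hz too low for 30 Hz analysis (need >= 60)")
    n_expect = int(round(fs * EPOCH_S))
    if len(x) != n_expect:
        raise ValueError(f"segment must be {EPOCH_S:.0f} s = {n_expect} samples, got {len(x)}")
    power = _psd_matrix(x[None, :], fs, window)[0]
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    return Spectrum(freqs=freqs, power=power, epoch_index=epoch_index)


def _psd_matrix(segments: np.ndarray, fs: float, window: str = "rect") -> np.ndarray:
    """Vectorised one-sided PSD for an (n_epochs, n_samples) array."""
    n = segments.shape[1]
    if window == "hann":
        w = np.hanning(n)
        scale = np.sum(w**2)          # window power correction
        segments = segments * w
    elif window == "rect":
        scale = float(n)
    else:
        raise ValueError(f"unknown window {window!r}")
    spec = np.fft.rfft(segments, axis=1)
    psd = (np.abs(spec) ** 2) / (fs * scale)
    psd[:, 1:] *= 2.0
    if n % 2 == 0:                     # Nyquist bin is not duplicated
        psd[:, -1] /= 2.0
    return psd


def band_power(spec: Spectrum, lo: float, hi: float, closed: bool = False) -> float:
    """Integrated power in [lo, hi) (µV²); ``closed=True`` for [lo, hi]."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    if lo < spec.freqs[0] - 1e-9 or hi > spec.freqs[-1] + spec.df + 1e-9:
        raise ValueError(f"band [{lo}, {hi}] outside spectrum range")
    f = spec.freqs
    if closed:
        sel = (f >= lo - 1e-9) & (f <= hi + 1e-9)
    else:
        sel = (f >= lo - 1e-9) & (f < hi - 1e-9)
    return float(np.sum(spec.power[sel]) * spec.df)


def band_power_matrix(psd: np.ndarray, freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Vectorised ``band_power`` over epoch rows of a PSD matrix."""
    df = freqs[1] - freqs[0]
    sel = (freqs >= lo - 1e-9) & (freqs < hi - 1e-9)
    return np.sum(psd[:, sel], axis=1) * df


def normalized_swa(delta_series, baseline_delta_series) -> np.ndarray:
    """Express per-epoch delta power as % of the baseline-day NREM mean.

    The divisor is the mean NREM delta power of the first, undisturbed
    recording day, so the baseline day self-normalises to a mean of 100%.

    Parameters
    ----------
    delta_series : array
        Delta power (µV²) of the epochs to normalise (typically NREM only).
    baseline_delta_series : array
        Delta power of the baseline day's NREM epochs.
    """
    base = np.asarray(baseline_delta_series, dtype=float)
    if base.size == 0:
        raise ValueError("baseline NREM delta series is empty")
    mean = float(np.mean(base))
    if mean <= 0:
        raise ValueError("baseline mean delta power must be positive")
    return 100.0 * np.asarray(delta_series, dtype=float) / mean


def relative_swa(delta, total):
    """Delta power as a percentage of total 0.5–30 Hz power (0–100%)."""
    delta = np.asarray(delta, dtype=float)
    total = np.asarray(total, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total power must be positive")
    if np.any(delta > total * (1 + 1e-12)):
        raise ValueError("delta power cannot exceed total power")
    out = 100.0 * delta / total
    return out if out.ndim else float(out)


def slow_wave_energy(delta_series, nrem_mask, t_s: float = EPOCH_S) -> np.ndarray:
    """Cumulative slow-wave energy, Σ power_i × t_i over NREM epochs (µV²·s).

    Non-NREM epochs contribute zero and carry the running total forward,
    so the returned series is non-decreasing and has one value per epoch.
    """
    delta = np.asarray(delta_series, dtype=float)
    mask = np.asarray(nrem_mask, dtype=bool)
    if delta.shape != mask.shape:
        raise ValueError("delta series and NREM mask must have equal length")
    contrib = np.where(mask, delta * t_s, 0.0)
    return np.cumsum(contrib)


def swa_timecourse(values, zt_s, bin_h: float = 1.0, period_h: float = 24.0) -> pd.DataFrame:
    """Bin a per-epoch series into ZT bins with mean and SEM.

    Bins with no contributing epochs are reported with NaN mean (missing),
    never zero.

    Returns a DataFrame with columns ``zt_bin_start_h``, ``mean``, ``sem``,
    ``n`` covering one full period.
    """
    if period_h % bin_h != 0:
        raise ValueError(f"bin={bin_h} h must divide {period_h} h")
    values = np.asarray(values, dtype=float)
    zt_h = (np.asarray(zt_s, dtype=float) / 3600.0) % period_h
    edges = np.arange(0, period_h + bin_h, bin_h)
    idx = np.digitize(zt_h, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        v = values[idx == b]
        rows.append(
            {
                "zt_bin_start_h": edges[b],
                "mean": float(np.mean(v)) if v.size else np.nan,
                "sem": float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan,
                "n": int(v.size),
            }
        )
    return pd.DataFrame(rows)


def epoch_band_powers(signal, fs: float, epoch_s: float = EPOCH_S,
                      window: str = "rect") -> pd.DataFrame:
    """Delta/theta/total band power per 10 s epoch of a continuous signal.

    Trailing samples short of a full epoch are dropped.
    """
    x = np.asarray(signal, dtype=float)
    n_per = int(round(fs * epoch_s))
    n_ep = len(x) // n_per
    segs = x[: n_ep * n_per].reshape(n_ep, n_per)
    psd = _psd_matrix(segs, fs, window)
    freqs = np.fft.rfftfreq(n_per, d=1.0 / fs)
    return pd.DataFrame(
        {
            "delta": band_power_matrix(psd, freqs, *DELTA_BAND),
            "theta": band_power_matrix(psd, freqs, *THETA_BAND),
            "total": band_power_matrix(psd, freqs, *TOTAL_BAND),
        }
    )
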