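"""LFP channel selection, band power and speed-restricted averaging.

Band power (theta 6-12 Hz, slow gamma 20-50 Hz, fast gamma 50-110 Hz) is
estimated with a multitaper spectrogram (0.5 s windows, time-bandwidth 3,
5 DPSS tapers -> a 2 Hz power trace); session power spectral densities use
Welch's method.  To control for running-speed differences, band-power
traces are spline-upsampled to the 50 Hz behaviour framerate and averaged
over frames at intermediate speeds (20 <= speed <= 40 cm/s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, signal

__all__ = [
    "BANDS",
    "BandPower",
    "select_channel",
    "multitaper_spectrogram",
    "band_power",
    "welch_psd",
    "speed_restricted_power",
]

#: frequency bands (Hz)
BANDS = {"theta": (6.0, 12.0), "slow_gamma": (20.0, 50.0), "fast_gamma": (50.0, 110.0)}


@dataclass
class BandPower:
    band: str
    times: np.ndarray  # centre of each spectrogram window (s)
    power: np.ndarray  # band-integrated power per window
    speed_restricted_mean: float = float("nan")


def select_channel(
    theta_power: np.ndarray,
    tip_distance_um: np.ndarray,
    has_good_cell: np.ndarray,
    n_closest: int = 200,
) -> int:
    """Channel with the highest theta power among the ``n_closest`` channels
    nearest the probe tip that carry at least one good cell."""
    theta_power = np.asarray(theta_power, dtype=float)
    tip = np.asarray(tip_distance_um, dtype=float)
    good = np.asarray(has_good_cell, dtype=bool)
    closest = np.argsort(tip, kind="stable")[:n_closest]
    eligible = closest[good[closest]]
    if eligible.size == 0:
        raise ValueError("no eligible channel (tip-proximal with a good cell)")
    return int(eligible[np.argmax(theta_power[eligible])])


def multitaper_spectrogram(
    trace: np.ndarray,
    fs: float,
    window_s: float = 0.5,
    nw: float = 3.0,
    n_tapers: int = 5,
):
    """DPSS multitaper spectrogram with non-overlapping windows.

    Returns (times, freqs, psd) with psd shaped (n_windows, n_freqs) in
    power per Hz; the window length sets the trace rate (0.5 s -> 2 Hz).
    """
    x = np.asarray(trace, dtype=float)
    n_per_win = int(round(window_s * fs))
    if x.shape[0] < n_per_win:
        raise ValueError("trace shorter than one spectrogram window")
    n_win = x.shape[0] // n_per_win
    tapers = signal.windows.dpss(n_per_win, nw, Kmax=n_tapers)
    freqs = np.fft.rfftfreq(n_per_win, d=1.0 / fs)
    segs = x[: n_win * n_per_win].reshape(n_win, n_per_win)
    # (n_win, n_tapers, n_per_win) -> average periodograms across tapers
    tapered = segs[:, None, :] * tapers[None, :, :]
    spec = np.abs(np.fft.rfft(tapered, axis=-1)) ** 2
    psd = spec.mean(axis=1) / fs
    psd[:, 1:-1] *= 2.0  # one-sided
    times = (np.arange(n_win) + 0.5) * window_s
    return times, freqs, psd


def band_power(
    trace: np.ndarray,
    fs: float,
    band: str | tuple[float, float],
    window_s: float = 0.5,
    nw: float = 3.0,
    n_tapers: int = 5,
) -> BandPower:
    """Time-resolved band-integrated power from the multitaper spectrogram."""
    lo, hi = BANDS[band] if isinstance(band, str) else band
    if fs < 2.0 * hi:
        raise ValueError(f"sampling rate {fs} Hz under-samples the band top {hi} Hz")
    times, freqs, psd = multitaper_spectrogram(trace, fs, window_s, nw, n_tapers)
    sel = (freqs >= lo) & (freqs <= hi)
    power = np.trapezoid(psd[:, sel], freqs[sel], axis=1)
    return BandPower(
        band=band if isinstance(band, str) else f"{lo}-{hi}", times=times, power=power
    )


def welch_psd(trace: np.ndarray, fs: float, nperseg: int | None = None):
    """Session power spectral density (Welch's method)."""
    x = np.asarray(trace, dtype=float)
    if nperseg is None:
        nperseg = min(x.shape[0], int(4 * fs))
    return signal.welch(x, fs=fs, nperseg=nperseg)


def speed_restricted_power(
    bp: BandPower,
    frames: pd.DataFrame,
    speed_range: tuple[float, float] = (20.0, 40.0),
    spline_order: int = 2,
) -> float:
    """Mean band power over frames at intermediate running speeds.

    The 2 Hz power trace is up-sampled to the behaviour framerate with a
    second-order spline and averaged where ``speed_range[0] <= speed <=
    speed_range[1]`` (both boundaries included).
    """
    t_frames = frames["t"].to_numpy(dtype=float)
    speed = frames["speed"].to_numpy(dtype=float)
    if bp.times.shape[0] > spline_order:
        spl = interpolate.make_interp_spline(bp.times, bp.power, k=spline_order)
        upsampled = np.asarray(
            spl(np.clip(t_frames, bp.times[0], bp.times[-1]))
        )
    else:
        upsampled = np.interp(t_frames, bp.times, bp.power)
    lo, hi = speed_range
    sel = (speed >= lo) & (speed <= hi)
    if not sel.any():
        return float("nan")
    return float(np.mean(upsampled[sel]))
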