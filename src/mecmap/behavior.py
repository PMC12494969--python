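"""Behaviour preprocessing and task-performance measures.

Raw VR frames arrive at an uneven rate; everything downstream assumes a
uniform 50 Hz stream, a trial index that increments at teleports, a cleaned
running-speed trace, and a stationary-bin mask.  This module also computes
the behavioural readouts used to quantify task engagement: fraction of
rewards requested, reward-triggered licking/slowing profiles, and the
contrast-sensitivity psychometric fit.

Binning convention (package-wide): half-open ``[left, right)`` bins,
0-based indices, last bin closed at the track end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "Psychometric",
    "resample_frames",
    "segment_trials",
    "compute_speed",
    "filter_stationary",
    "task_performance",
    "reward_triggered_profiles",
    "fit_contrast_sensitivity",
    "unwrap_position",
]

#: Trial boundaries are position drops steeper than this (cm per frame).
TELEPORT_THRESHOLD = -100.0


def unwrap_position(position: np.ndarray, track_length: float = 400.0) -> np.ndarray:
    """Cumulative distance: undo teleports so interpolation never crosses one.

    Positions below 0 or above the track length are thereby mapped into the
    previous / subsequent lap's coordinates.
    """
    position = np.asarray(position, dtype=float)
    d = np.diff(position)
    wraps = np.cumsum(np.concatenate([[0.0], (d < TELEPORT_THRESHOLD).astype(float)]))
    return position + wraps * track_length


def resample_frames(
    raw: pd.DataFrame,
    frame_rate: float = 50.0,
    track_length: float = 400.0,
) -> pd.DataFrame:
    """Resample a raw frame table onto a uniform grid (default 50 Hz).

    Position is linearly interpolated after unwrapping across teleports and
    folded back into ``[0, track_length)``; the trial index is recomputed
    from the folded trace.  Event-count columns (``lick``, ``reward``) are
    rebinned so totals are preserved; remaining numeric columns are
    linearly interpolated and categorical columns carried by most recent
    value.
    """
    if len(raw) < 2:
        raise ValueError("need at least 2 raw frames to resample")
    t_raw = raw["t"].to_numpy(dtype=float)
    if np.any(np.diff(t_raw) < 0):
        raise ValueError("raw timestamps must be non-decreasing")
    dt = 1.0 / frame_rate
    t_new = np.arange(t_raw[0], t_raw[-1] + 0.5 * dt, dt)

    cum = unwrap_position(raw["position"].to_numpy(), track_length)
    cum_new = np.interp(t_new, t_raw, cum)
    # fold: lap index may start at -1 if the session begins below 0 cm
    lap = np.floor(cum_new / track_length).astype(int)
    out = pd.DataFrame({"t": t_new, "position": cum_new - lap * track_length})
    out["trial"] = lap - lap.min()

    edges = np.concatenate([t_new - 0.5 * dt, [t_new[-1] + 0.5 * dt]])
    for col in raw.columns:
        if col in ("t", "position", "trial"):
            continue
        vals = raw[col]
        if col in ("lick", "reward"):
            out[col], _ = np.histogram(t_raw, bins=edges, weights=vals.to_numpy(dtype=float))
        elif pd.api.types.is_numeric_dtype(vals):
            out[col] = np.interp(t_new, t_raw, vals.to_numpy(dtype=float))
        else:
            idx = np.clip(np.searchsorted(t_raw, t_new, side="right") - 1, 0, len(t_raw) - 1)
            out[col] = vals.to_numpy()[idx]
    return out


def segment_trials(frames: pd.DataFrame, track_length: float = 400.0) -> pd.DataFrame:
    """(Re)compute the trial index: increments where Δposition < −100 cm."""
    pos = frames["position"].to_numpy(dtype=float)
    d = np.diff(pos)
    trial = np.cumsum(np.concatenate([[0], (d < TELEPORT_THRESHOLD).astype(int)]))
    out = frames.copy()
    out["trial"] = trial
    return out


def compute_speed(
    frames: pd.DataFrame,
    frame_rate: float = 50.0,
    track_length: float = 400.0,
    low_cut: float = 5.0,
    high_cut: float = 150.0,
    smooth_sd_bins: float = 0.2,
) -> pd.DataFrame:
    """Frame-to-frame running speed, cleaned and lightly smoothed.

    Speed is the unwrapped position difference times the frame rate.
    Samples at or below ``low_cut`` or above ``high_cut`` cm/s are treated
    as artifacts, removed and linearly interpolated from their neighbours;
    the result is smoothed with a Gaussian filter of SD ``smooth_sd_bins``
    samples.
    """
    cum = unwrap_position(frames["position"].to_numpy(), track_length)
    d = np.diff(cum)
    speed = np.concatenate([[d[0] if d.size else 0.0], d]) * frame_rate
    bad = (speed <= low_cut) | (speed > high_cut)
    if bad.any() and not bad.all():
        idx = np.arange(speed.shape[0])
        speed = speed.copy()
        speed[bad] = np.interp(idx[bad], idx[~bad], speed[~bad])
    speed = gaussian_filter1d(speed, smooth_sd_bins, mode="nearest")
    out = frames.copy()
    out["speed"] = np.clip(speed, 0.0, None)
    return out


def filter_stationary(frames: pd.DataFrame, threshold: float = 2.0) -> np.ndarray:
    """Analysis mask: False exactly where speed < ``threshold`` cm/s."""
    return frames["speed"].to_numpy(dtype=float) >= threshold


def task_performance(frames: pd.DataFrame, trials=None) -> float:
    """Fraction of eligible reward zones where the reward was requested.

    A zone counts as requested when a lick occurred inside the zone before
    its centre (i.e. before automatic delivery).  ``trials`` restricts the
    computation to a task phase; returns NaN when no zone is eligible.
    """
    sel = frames
    if trials is not None:
        sel = frames[frames["trial"].isin(np.asarray(trials))]
    eligible = 0
    requested = 0
    for _, tf in sel.groupby("trial"):
        z0 = tf["reward_start"].to_numpy(dtype=float)
        if np.all(np.isnan(z0)):
            continue
        z1 = tf["reward_end"].to_numpy(dtype=float)
        center = (z0 + z1) / 2.0
        pos = tf["position"].to_numpy(dtype=float)
        lick = tf["lick"].to_numpy(dtype=float)
        eligible += 1
        in_zone_pre = (pos >= z0) & (pos < center)
        if np.any(lick[in_zone_pre] > 0):
            requested += 1
    if eligible == 0:
        return float("nan")
    return requested / eligible


@dataclass
class RewardProfiles:
    """Reward-zone-aligned mean traces and their peak prominences."""

    lick_trace: np.ndarray
    slowing_trace: np.ndarray  # inverted mean speed
    bin_centers: np.ndarray  # cm relative to zone start
    licking_magnitude: float
    slowing_magnitude: float


def _peak_magnitude(trace: np.ndarray) -> float:
    """Prominence of the absolute maximum of a trace (0 for flat traces)."""
    if np.allclose(trace, trace[0]):
        return 0.0
    peak = int(np.nanargmax(trace))
    prom = signal.peak_prominences(trace, [peak])[0][0]
    if prom == 0.0:  # maximum at an edge: fall back to range above baseline
        prom = float(np.nanmax(trace) - np.nanmin(trace))
    return float(prom)


def reward_triggered_profiles(
    frames: pd.DataFrame,
    bin_size: float = 2.5,
    pre_cm: float = 25.0,
) -> RewardProfiles:
    """Mean licking and slowing around the reward zone across rewarded trials.

    Licks and speed are position-binned (2.5 cm) from 25 cm before the zone
    start to the zone end (75 cm / 30 bins for a 50 cm zone); the slowing
    trace is the inverted mean speed.  Magnitudes are the prominence of
    each trace's absolute maximum.
    """
    rewarded = frames.groupby("trial")["reward"].sum()
    rewarded = rewarded[rewarded > 0].index
    if len(rewarded) == 0:
        raise ValueError("no rewarded trials")
    sel = frames[frames["trial"].isin(rewarded)]
    zone_len = float(np.nanmean(sel["reward_end"] - sel["reward_start"]))
    n_bins = int(round((pre_cm + zone_len) / bin_size))
    edges = np.arange(n_bins + 1) * bin_size - pre_cm
    lick_sum = np.zeros(n_bins)
    speed_sum = np.zeros(n_bins)
    occ = np.zeros(n_bins)
    for _, tf in sel.groupby("trial"):
        z0 = np.nanmean(tf["reward_start"].to_numpy(dtype=float))
        rel = tf["position"].to_numpy(dtype=float) - z0
        which = np.digitize(rel, edges) - 1
        ok = (which >= 0) & (which < n_bins)
        np.add.at(lick_sum, which[ok], tf["lick"].to_numpy(dtype=float)[ok])
        np.add.at(speed_sum, which[ok], tf["speed"].to_numpy(dtype=float)[ok])
        np.add.at(occ, which[ok], 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        lick_trace = lick_sum / len(rewarded)
        speed_trace = np.where(occ > 0, speed_sum / np.maximum(occ, 1), np.nan)
    slowing = -speed_trace
    return RewardProfiles(
        lick_trace=lick_trace,
        slowing_trace=slowing,
        bin_centers=(edges[:-1] + edges[1:]) / 2.0,
        licking_magnitude=_peak_magnitude(lick_trace),
        slowing_magnitude=_peak_magnitude(slowing),
    )


@dataclass
class Psychometric:
    """Sigmoid psychometric fit of fraction-requested vs reward-zone opacity."""

    center: float
    scale: float
    converged: bool
    message: str = ""

    #: default optimiser initialisation (opacity units)
    INIT_CENTER = 0.1
    INIT_SCALE = 0.002

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _sigmoid(np.asarray(x, dtype=float), self.center, self.scale)


def _sigmoid(x, center, scale):
    return 1.0 / (1.0 + np.exp(-(x - center) / scale))


def fit_contrast_sensitivity(
    opacity: np.ndarray,
    fraction_requested: np.ndarray,
    init_center: float = Psychometric.INIT_CENTER,
    init_scale: float = Psychometric.INIT_SCALE,
) -> Psychometric:
    """Least-squares sigmoid fit of the contrast-sensitivity curve.

    The fitted ``center`` is the animal's estimated contrast-sensitivity
    threshold.  Degenerate inputs (constant response, optimiser failure)
    return a flagged, non-converged fit rather than raising.
    """
    x = np.asarray(opacity, dtype=float)
    y = np.asarray(fraction_requested, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.shape[0] < 3:
        raise ValueError("need at least 3 opacity bins with defined fractions")
    if np.allclose(y, y[0]):
        return Psychometric(np.nan, np.nan, False, "constant response; fit is degenerate")

    def _try(p0):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                popt, _ = optimize.curve_fit(_sigmoid, x, y, p0=p0, maxfev=10000)
            except RuntimeError:
                return None, np.inf
        sse = float(np.sum((y - _sigmoid(x, *popt)) ** 2))
        return popt, sse

    popt, sse = _try([init_center, init_scale])
    # a near-step initial scale can leave the optimiser on a flat gradient;
    # restart from a data-driven guess and keep the better fit
    x_mid = x[np.argmin(np.abs(y - 0.5 * (y.min() + y.max())))]
    popt2, sse2 = _try([x_mid, 0.1 * (x.max() - x.min())])
    if sse2 < sse:
        popt, sse = popt2, sse2
    if popt is None:
        return Psychometric(np.nan, np.nan, False, "no convergence")
    return Psychometric(float(popt[0]), float(popt[1]), True)
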