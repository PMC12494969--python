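"""Speed tuning: score, regression slope, and stability variants.

The speed score is the Pearson correlation between running speed and the
instantaneous firing rate (smoothed spike counts / frame duration).  The
smoothing kernel inherits a distance-unit SD (40 cm); it is applied in time
with SD = 40 cm divided by the session's mean running speed, exposed as
``speed_kernel_sd_cm``.  Stability variants are spike-weighted averages of
speed scores computed per 80 cm track section (speed stability) or per
trial (trial stability); values below the overall speed score indicate
tuning instability across position or trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "SpeedScores",
    "instantaneous_rate",
    "speed_score",
    "spike_weighted_average",
    "speed_stability_score",
    "trial_speed_stability",
    "compute_speed_scores",
]

#: default smoothing SD for instantaneous rate, in track-distance units
SPEED_KERNEL_SD_CM = 40.0


@dataclass
class SpeedScores:
    speed_score: float
    slope: float
    intercept: float
    speed_stability: float = float("nan")
    trial_stability: float = float("nan")
    flagged: bool = False


def instantaneous_rate(
    spike_times: np.ndarray,
    frames: pd.DataFrame,
    speed_kernel_sd_cm: float = SPEED_KERNEL_SD_CM,
    frame_rate: float = 50.0,
) -> np.ndarray:
    """Smoothed per-frame firing rate (Hz).

    Per-frame spike counts are smoothed with a Gaussian kernel whose SD in
    samples is ``speed_kernel_sd_cm`` / mean running speed * frame rate,
    then divided by the frame duration.  The kernel is normalised, so the
    series integrates to the total spike count.
    """
    t = frames["t"].to_numpy(dtype=float)
    dt = 1.0 / frame_rate
    idx = np.searchsorted(t, np.asarray(spike_times, dtype=float), side="right") - 1
    idx = idx[(idx >= 0) & (idx < t.shape[0])]
    counts = np.bincount(idx, minlength=t.shape[0]).astype(float)
    mean_speed = float(np.nanmean(frames["speed"].to_numpy(dtype=float)))
    sd_samples = speed_kernel_sd_cm / max(mean_speed, 1e-9) * frame_rate
    return gaussian_filter1d(counts, sd_samples, mode="reflect") / dt


def speed_score(
    rate: np.ndarray, speed: np.ndarray, mask: np.ndarray | None = None
) -> SpeedScores:
    """Pearson correlation of rate with speed plus least-squares slope/intercept.

    Stationary bins should already be excluded via ``mask``.  Zero-variance
    rate or speed yields a flagged score of 0.
    """
    r = np.asarray(rate, dtype=float)
    v = np.asarray(speed, dtype=float)
    if mask is not None:
        r, v = r[mask], v[mask]
    ok = np.isfinite(r) & np.isfinite(v)
    r, v = r[ok], v[ok]
    if r.shape[0] < 3 or np.std(r) == 0 or np.std(v) == 0:
        return SpeedScores(0.0, float("nan"), float("nan"), flagged=True)
    fit = stats.linregress(v, r)
    return SpeedScores(
        speed_score=float(fit.rvalue), slope=float(fit.slope), intercept=float(fit.intercept)
    )


def spike_weighted_average(scores: np.ndarray, spike_counts: np.ndarray) -> float:
    """sum(n_i * p_i) / n over strata; strata with undefined scores or zero
    spikes drop out.  Undefined when no spikes remain."""
    p = np.asarray(scores, dtype=float)
    n = np.asarray(spike_counts, dtype=float)
    ok = np.isfinite(p) & (n > 0)
    if n[ok].sum() == 0:
        return float("nan")
    return float(np.sum(n[ok] * p[ok]) / n[ok].sum())


def _spike_frame_index(spike_times, frames):
    t = frames["t"].to_numpy(dtype=float)
    idx = np.searchsorted(t, np.asarray(spike_times, dtype=float), side="right") - 1
    return idx[(idx >= 0) & (idx < t.shape[0])]


def speed_stability_score(
    spike_times: np.ndarray,
    frames: pd.DataFrame,
    rate: np.ndarray,
    mask: np.ndarray | None = None,
    n_sections: int = 5,
    track_length: float = 400.0,
) -> float:
    """Spike-weighted average of speed scores across track sections (5 x 80 cm)."""
    pos = frames["position"].to_numpy(dtype=float)
    section = np.minimum((pos / (track_length / n_sections)).astype(int), n_sections - 1)
    sp_idx = _spike_frame_index(spike_times, frames)
    speed = frames["speed"].to_numpy(dtype=float)
    scores = np.full(n_sections, np.nan)
    counts = np.zeros(n_sections)
    for s in range(n_sections):
        in_s = section == s
        m = in_s if mask is None else (in_s & mask)
        scores[s] = speed_score(rate[m], speed[m]).speed_score
        counts[s] = np.count_nonzero(section[sp_idx] == s)
    return spike_weighted_average(scores, counts)


def trial_speed_stability(
    spike_times: np.ndarray,
    frames: pd.DataFrame,
    rate: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Spike-weighted average of per-trial speed scores."""
    trial = frames["trial"].to_numpy(dtype=int)
    sp_idx = _spike_frame_index(spike_times, frames)
    speed = frames["speed"].to_numpy(dtype=float)
    trial_ids = np.unique(trial)
    scores = np.full(trial_ids.shape[0], np.nan)
    counts = np.zeros(trial_ids.shape[0])
    for i, tr in enumerate(trial_ids):
        in_t = trial == tr
        m = in_t if mask is None else (in_t & mask)
        scores[i] = speed_score(rate[m], speed[m]).speed_score
        counts[i] = np.count_nonzero(trial[sp_idx] == tr)
    return spike_weighted_average(scores, counts)


def compute_speed_scores(
    spike_times: np.ndarray,
    frames: pd.DataFrame,
    mask: np.ndarray | None = None,
    speed_kernel_sd_cm: float = SPEED_KERNEL_SD_CM,
    track_length: float = 400.0,
) -> SpeedScores:
    """All speed-tuning scores of one unit in a single pass."""
    rate = instantaneous_rate(spike_times, frames, speed_kernel_sd_cm)
    speed = frames["speed"].to_numpy(dtype=float)
    base = speed_score(rate, speed, mask)
    base.speed_stability = speed_stability_score(
        spike_times, frames, rate, mask, track_length=track_length
    )
    base.trial_stability = trial_speed_stability(spike_times, frames, rate, mask)
    return base
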