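"""Unit quality control and shuffle-null functional cell typing.

Units surviving QC are split into putative fast-spiking interneurons (IN)
vs excitatory cells by waveform duration / mean rate, then typed against
spike-time-shuffle nulls: speed cells (|speed score| and |speed stability|
both beyond their shuffle 99th percentiles), spatial cells (coherence and
sparsity both beyond theirs; Block A trials only in the split-maze task),
grid cells (excitatory, distance-tuned in the dark, with rate and
noise-ratio exclusions) and non-grid spatial (NGS) cells (spatial but not
grid).  Conjunctive subtypes (+/- speed-only, +IN speed, +grid speed) are
set algebra on those flags.

Exceedance conventions follow the classification rules literally: ties at
the 99th percentile count for distance tuning ("greater than or equal to")
but not for speed/spatial typing ("exceeded").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "QC_RULES",
    "qc_filter_units",
    "split_in_excitatory",
    "classify_speed_cells",
    "classify_spatial_cells",
    "classify_grid_cells",
    "derive_subtypes",
    "check_label_invariants",
]

#: unit exclusion rules (any match excludes)
QC_RULES = {
    "min_snr": 1.0,  # signal:noise ratio < 1.0
    "min_rate_hz": 0.10,  # firing rate < 0.10 Hz
    "min_repolarization_slope": 0.0,  # repolarization slope < 0
    "max_depth_um": 3200.0,  # depth > 3200 um from probe tip
    "max_halfwidth_ms": 0.30,  # halfwidth > 0.30 ms
    "min_spikes": 350,  # kept only if > 350 spikes
    "min_cells_per_session": 10,
}

#: interneuron thresholds: duration < 0.35 ms OR mean rate > 40 Hz
IN_MAX_DURATION_MS = 0.35
IN_MIN_RATE_HZ = 40.0

#: grid-cell rate exclusions and trial-averaged-rate noise threshold
GRID_MIN_DARK_RATE_HZ = 0.05  # excluded if dark rate <= this
GRID_MIN_OVERALL_RATE_HZ = 0.3  # excluded if overall rate < this
GRID_MAX_NOISE_RATIO = 0.45  # excluded if SEM/mean > this in either context


def qc_filter_units(units: pd.DataFrame, rules: dict = QC_RULES):
    """Apply unit QC; returns (retained units, session_excluded flag).

    Units failing any rule (low SNR, low rate, negative repolarization
    slope, too deep along the probe, wide halfwidth, <= 350 spikes, or a
    manual not-good label when present) are removed; a session retaining
    fewer than 10 units is flagged excluded.
    """
    u = units
    bad = (
        (u["snr"] < rules["min_snr"])
        | (u["mean_rate_hz"] < rules["min_rate_hz"])
        | (u["repolarization_slope"] < rules["min_repolarization_slope"])
        | (u["depth_um"] > rules["max_depth_um"])
        | (u["halfwidth_ms"] > rules["max_halfwidth_ms"])
        | (u["n_spikes"] <= rules["min_spikes"])
    )
    if "is_good" in u.columns:
        bad |= ~u["is_good"].astype(bool)
    retained = u[~bad].reset_index(drop=True)
    session_excluded = len(retained) < rules["min_cells_per_session"]
    return retained, session_excluded


def split_in_excitatory(units: pd.DataFrame) -> pd.DataFrame:
    """Flag putative INs (duration < 0.35 ms or mean rate > 40 Hz)."""
    labels = pd.DataFrame({"unit_id": units["unit_id"].to_numpy()})
    labels["is_IN"] = (
        (units["duration_ms"].to_numpy() < IN_MAX_DURATION_MS)
        | (units["mean_rate_hz"].to_numpy() > IN_MIN_RATE_HZ)
    )
    labels["is_excitatory"] = ~labels["is_IN"]
    return labels


def classify_speed_cells(
    labels: pd.DataFrame,
    speed_scores: np.ndarray,
    stability_scores: np.ndarray,
    speed_null_q99: np.ndarray,
    stability_null_q99: np.ndarray,
) -> pd.DataFrame:
    """Speed-tuned iff |score| and |stability| each strictly exceed the 99th
    percentile of their absolute shuffle scores; the score sign splits +/-.

    Only excitatory-or-IN distinction is respected downstream via subtype
    derivation; the speed flags themselves are set for every unit.
    """
    out = labels.copy()
    score = np.asarray(speed_scores, dtype=float)
    stab = np.asarray(stability_scores, dtype=float)
    tuned = (np.abs(score) > np.asarray(speed_null_q99, dtype=float)) & (
        np.abs(stab) > np.asarray(stability_null_q99, dtype=float)
    )
    tuned &= np.isfinite(score) & np.isfinite(stab)
    out["is_speed_tuned"] = tuned
    out["is_speed_pos"] = tuned & (score > 0)
    out["is_speed_neg"] = tuned & (score < 0)
    return out


def classify_spatial_cells(
    labels: pd.DataFrame,
    coherence: np.ndarray,
    sparsity: np.ndarray,
    coherence_null_q99: np.ndarray,
    sparsity_null_q99: np.ndarray,
) -> pd.DataFrame:
    """Spatial iff coherence and sparsity both strictly exceed their shuffle
    99th percentiles.  In the SM task the caller must supply metrics
    computed on Block A trials only."""
    out = labels.copy()
    coh = np.asarray(coherence, dtype=float)
    spa = np.asarray(sparsity, dtype=float)
    spatial = (coh > np.asarray(coherence_null_q99, dtype=float)) & (
        spa > np.asarray(sparsity_null_q99, dtype=float)
    )
    spatial &= np.isfinite(coh) & np.isfinite(spa)
    out["is_spatial"] = spatial
    return out


def classify_grid_cells(
    labels: pd.DataFrame,
    distance_tuned: np.ndarray,
    dark_rate_hz: np.ndarray,
    overall_rate_hz: np.ndarray,
    noise_ratio_a: np.ndarray | None = None,
    noise_ratio_b: np.ndarray | None = None,
) -> pd.DataFrame:
    """Grid = excitatory, distance-tuned, dark rate > 0.05 Hz, overall rate
    >= 0.3 Hz, and trial-averaged-rate noise (SEM/mean) <= 0.45 in both
    contexts (exclusion fires if either context exceeds it).  NGS = spatial
    and not grid (excitatory by construction of the spatial nulls)."""
    out = labels.copy()
    grid = (
        out["is_excitatory"].to_numpy()
        & np.asarray(distance_tuned, dtype=bool)
        & (np.asarray(dark_rate_hz, dtype=float) > GRID_MIN_DARK_RATE_HZ)
        & (np.asarray(overall_rate_hz, dtype=float) >= GRID_MIN_OVERALL_RATE_HZ)
    )
    for ratio in (noise_ratio_a, noise_ratio_b):
        if ratio is not None:
            r = np.asarray(ratio, dtype=float)
            grid &= ~(r > GRID_MAX_NOISE_RATIO)
    out["is_grid"] = grid
    out["is_NGS"] = out["is_spatial"].to_numpy() & ~grid & out["is_excitatory"].to_numpy()
    return out


def derive_subtypes(labels: pd.DataFrame) -> pd.DataFrame:
    """Conjunctive subtypes from the base flags."""
    out = labels.copy()
    non_spatial = ~out["is_spatial"].to_numpy()
    out["is_speed_only_pos"] = out["is_speed_pos"].to_numpy() & non_spatial
    out["is_speed_only_neg"] = out["is_speed_neg"].to_numpy() & non_spatial
    out["is_IN_speed"] = out["is_IN"].to_numpy() & out["is_speed_pos"].to_numpy()
    out["is_grid_speed"] = out["is_grid"].to_numpy() & out["is_speed_pos"].to_numpy()
    return out


def check_label_invariants(labels: pd.DataFrame) -> None:
    """Raise AssertionError if the label-consistency invariants fail."""
    assert not (labels["is_grid"] & labels["is_NGS"]).any(), "grid and NGS overlap"
    assert (labels["is_grid"] <= labels["is_excitatory"]).all(), "grid must be excitatory"
    assert (labels["is_NGS"] <= labels["is_spatial"]).all(), "NGS must be spatial"
    assert not (labels["is_IN"] & labels["is_excitatory"]).any(), "IN/excitatory overlap"
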