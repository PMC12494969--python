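"""Session-level orchestration: per-cell metrics, typing, maps and decoding.

Glue over the analysis modules for whole-session runs: compute the
stationary mask, per-cell tuning and speed metrics with their shuffle
nulls, classify functional cell types, assemble population tensors
(back-track bins for split-maze population analyses), and run the map
clustering and alignment pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify, maps, similarity, speedcode, tuning
from .behavior import filter_stationary
from .similarity import RateTensor, _phase_of_trials
from .synthio import SessionBundle

__all__ = [
    "session_trial_info",
    "cell_metrics",
    "classify_cells",
    "build_tensor",
    "MapResult",
    "run_maps",
]


def session_trial_info(frames: pd.DataFrame, config=None) -> pd.DataFrame:
    """Per-trial context / trial-type / phase table, chronological.

    With a session config the task phases come from the configured trial
    counts; otherwise they are inferred from the context sequence (the
    first context switch after the B block ends it, so alternation trials
    that happen to open with context B are indistinguishable from a block
    tail).
    """
    info = (
        frames.groupby("trial")[["context", "trial_type"]].first().reset_index()
    )
    if config is not None:
        bounds = np.cumsum(
            [config.n_dark, config.n_blockA, config.n_blockB,
             config.n_alternation, config.n_gain]
        )
        names = ["dark", "blockA", "blockB", "alt", "gain"]
        idx = np.searchsorted(bounds, info["trial"].to_numpy(), side="right")
        info["phase"] = [names[i] for i in idx]
    else:
        info["phase"] = _phase_of_trials(info)
    return info


def _per_trial_rate(spike_times, frames, trials, mask):
    """Mean firing rate (Hz) per listed trial."""
    t = frames["t"].to_numpy(dtype=float)
    dt = t[1] - t[0] if t.shape[0] > 1 else 0.02
    trial = frames["trial"].to_numpy(dtype=int)
    idx = np.searchsorted(t, np.asarray(spike_times, dtype=float), side="right") - 1
    idx = idx[(idx >= 0) & (idx < t.shape[0])]
    idx = idx[mask[idx]]
    rates = []
    for tr in trials:
        sel = (trial == tr) & mask
        dur = sel.sum() * dt
        rates.append(np.count_nonzero(trial[idx] == tr) / dur if dur > 0 else np.nan)
    return np.asarray(rates)


def cell_metrics(
    bundle: SessionBundle,
    n_shuffles: int = 100,
    seed: int = 0,
    unit_ids=None,
    speed_kernel_sd_cm: float = speedcode.SPEED_KERNEL_SD_CM,
) -> pd.DataFrame:
    """Per-cell tuning/speed metrics with shuffle-null 99th percentiles.

    Spatial metrics (coherence, sparsity, information) use Block A trials
    in the SM task (all VR trials in RF); dark-trial autocorrelation
    drives distance tuning and grid-scale estimation.  Shuffle nulls use
    the circular spike-time shift with ``n_shuffles`` draws per statistic.
    """
    frames = bundle.frames
    cfg = bundle.config
    track_length = cfg.track_length
    mask = filter_stationary(frames)
    info = session_trial_info(frames, cfg)
    block_a = info.loc[info["phase"] == "blockA", "trial"].to_numpy()
    block_b = info.loc[info["phase"] == "blockB", "trial"].to_numpy()
    dark = info.loc[info["phase"] == "dark", "trial"].to_numpy()
    spatial_trials = block_a if (cfg.task == "SM" and block_a.size) else info.loc[
        info["trial_type"] == "vr", "trial"
    ].to_numpy()

    t = frames["t"].to_numpy(dtype=float)
    dt = t[1] - t[0] if t.shape[0] > 1 else 0.02
    duration = t[-1] + dt - t[0]
    dark_frames = frames["trial"].isin(dark).to_numpy()
    dark_time = (dark_frames & mask).sum() * dt

    if unit_ids is None:
        unit_ids = bundle.units["unit_id"].to_numpy()
    rng = np.random.default_rng(seed)
    speed = frames["speed"].to_numpy(dtype=float)

    in_spatial = frames["trial"].isin(spatial_trials).to_numpy()
    frames_sp = frames[in_spatial].reset_index(drop=True)
    mask_sp = mask[in_spatial]
    in_dark = frames["trial"].isin(dark).to_numpy()
    frames_dk = frames[in_dark].reset_index(drop=True)
    mask_dk = mask[in_dark]

    def spatial_stats(st):
        m = tuning.trial_rate_matrix(
            st, frames_sp, None, mask_sp, track_length=track_length,
            trials=spatial_trials,
        )
        rate, p_occ = tuning.trial_average(m)
        return (
            tuning.spatial_coherence(rate),
            tuning.spatial_sparsity(rate, p_occ),
            tuning.spatial_information(rate, p_occ),
        )

    def speed_stats(st):
        rate = speedcode.instantaneous_rate(st, frames, speed_kernel_sd_cm)
        sc = speedcode.speed_score(rate, speed, mask).speed_score
        stab = speedcode.speed_stability_score(
            st, frames, rate, mask, track_length=track_length
        )
        return sc, stab

    rows = []
    for uid in unit_ids:
        st = bundle.spikes.loc[bundle.spikes["unit_id"] == uid, "t"].to_numpy(dtype=float)
        row = {"unit_id": uid}
        coh, spars, info_rate = spatial_stats(st)
        row.update(coherence=coh, sparsity=spars, information=info_rate)
        sc_scores = speedcode.compute_speed_scores(
            st, frames, mask, speed_kernel_sd_cm, track_length
        )
        row.update(
            speed_score=sc_scores.speed_score,
            speed_slope=sc_scores.slope,
            speed_intercept=sc_scores.intercept,
            speed_stability=sc_scores.speed_stability,
            trial_stability=sc_scores.trial_stability,
        )

        # shuffle nulls (shared offsets per statistic family)
        sseed = int(rng.integers(2**31 - 1))
        null_spatial = tuning.shuffle_null(
            st, frames, lambda s: spatial_stats(s)[:2], n_shuffles=n_shuffles, seed=sseed
        ) if st.size else None
        null_speed = tuning.shuffle_null(
            st, frames, speed_stats, n_shuffles=n_shuffles,
            seed=int(rng.integers(2**31 - 1)),
        ) if st.size else None
        if null_spatial is not None:
            vals = np.asarray(null_spatial.values.tolist(), dtype=float)
            row["coherence_q99"] = float(np.nanpercentile(vals[:, 0], 99))
            row["sparsity_q99"] = float(np.nanpercentile(vals[:, 1], 99))
            svals = np.asarray(null_speed.values.tolist(), dtype=float)
            row["speed_score_q99"] = float(np.nanpercentile(np.abs(svals[:, 0]), 99))
            row["speed_stability_q99"] = float(np.nanpercentile(np.abs(svals[:, 1]), 99))
        else:
            row.update(
                coherence_q99=np.nan, sparsity_q99=np.nan,
                speed_score_q99=np.nan, speed_stability_q99=np.nan,
            )

        # dark-running distance tuning
        row.update(distance_tuned=False, grid_scale_cm=np.nan, dark_rate_hz=np.nan)
        if dark.size and st.size:
            dark_m = tuning.trial_rate_matrix(
                st, frames_dk, 4.0, mask_dk, track_length=track_length, trials=dark
            )
            row["dark_rate_hz"] = (
                np.count_nonzero(dark_frames[
                    np.clip(np.searchsorted(t, st, side="right") - 1, 0, t.shape[0] - 1)
                ]) / dark_time if dark_time > 0 else np.nan
            )
            try:
                ac = tuning.dark_autocorrelation(dark_m)
            except ValueError:
                ac = None
            if ac is not None and len(ac.qualifying_peaks(tuning.STRICT_PEAK_CRITERIA)):

                def shuffle_prominence(s):
                    m = tuning.trial_rate_matrix(
                        s, frames_dk, 4.0, mask_dk, track_length=track_length,
                        trials=dark,
                    )
                    try:
                        return tuning.max_peak_prominence(
                            tuning.dark_autocorrelation(m)
                        )
                    except ValueError:
                        return np.nan

                null_prom = tuning.shuffle_null(
                    st, frames, shuffle_prominence, n_shuffles=n_shuffles,
                    seed=int(rng.integers(2**31 - 1)),
                )
                row["distance_tuned"] = tuning.detect_distance_tuning(ac, null_prom)
            if ac is not None:
                row["grid_scale_cm"] = tuning.estimate_grid_scale(ac).scale_cm

        row["overall_rate_hz"] = st.size / duration if duration > 0 else np.nan
        for name, trials_ in (("noise_ratio_a", block_a), ("noise_ratio_b", block_b)):
            if trials_.size >= 2:
                r = _per_trial_rate(st, frames, trials_, mask)
                r = r[np.isfinite(r)]
                mu = r.mean() if r.size else np.nan
                row[name] = (
                    (r.std(ddof=1) / np.sqrt(r.size)) / mu if r.size > 1 and mu else np.nan
                )
            else:
                row[name] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def classify_cells(bundle: SessionBundle, metrics: pd.DataFrame) -> pd.DataFrame:
    """Full functional typing from a metrics table (QC is applied first)."""
    units = bundle.units.set_index("unit_id").loc[metrics["unit_id"]].reset_index()
    labels = classify.split_in_excitatory(units)
    labels = classify.classify_speed_cells(
        labels,
        metrics["speed_score"].to_numpy(),
        metrics["speed_stability"].to_numpy(),
        metrics["speed_score_q99"].to_numpy(),
        metrics["speed_stability_q99"].to_numpy(),
    )
    labels = classify.classify_spatial_cells(
        labels,
        metrics["coherence"].to_numpy(),
        metrics["sparsity"].to_numpy(),
        metrics["coherence_q99"].to_numpy(),
        metrics["sparsity_q99"].to_numpy(),
    )
    # spatial typing is defined among excitatory cells
    labels["is_spatial"] &= labels["is_excitatory"]
    labels = classify.classify_grid_cells(
        labels,
        metrics["distance_tuned"].to_numpy(),
        metrics["dark_rate_hz"].to_numpy(),
        metrics["overall_rate_hz"].to_numpy(),
        metrics["noise_ratio_a"].to_numpy(),
        metrics["noise_ratio_b"].to_numpy(),
    )
    labels = classify.derive_subtypes(labels)
    classify.check_label_invariants(labels)
    return labels


def build_tensor(
    bundle: SessionBundle,
    unit_ids,
    half: str | None = None,
    sort_alternation: bool | None = None,
    smoothing_sd: float = 5.0,
) -> RateTensor:
    """Normalised population tensor for the given cells.

    Defaults follow the task: split-maze population analyses use
    back-track bins and context-sorted alternation trials; random
    foraging uses the full track in chronological order.
    """
    is_sm = bundle.config.task == "SM"
    if half is None:
        half = "back" if is_sm else "full"
    if sort_alternation is None:
        sort_alternation = is_sm
    frames = bundle.frames
    mask = filter_stationary(frames)
    info = session_trial_info(frames, bundle.config)
    matrices = [
        tuning.trial_rate_matrix(
            bundle.spikes.loc[bundle.spikes["unit_id"] == uid, "t"].to_numpy(dtype=float),
            frames,
            smoothing_sd,
            mask,
            track_length=bundle.config.track_length,
        )
        for uid in unit_ids
    ]
    return similarity.normalize_tensor(
        matrices, info, sort_alternation=sort_alternation, half=half
    )


@dataclass
class MapResult:
    """Output of the map-clustering pipeline for one session."""

    k: int
    model: maps.FactorizedKMeans
    labeling: maps.MapLabeling
    diagnostics: maps.MapDiagnostics
    aligned: np.ndarray = field(default_factory=lambda: np.array([]))
    aligned_fraction: float = float("nan")


def run_maps(
    tensor: RateTensor,
    task: str = "SM",
    k_max: int = 4,
    reps: int = 10,
    restarts: int = 100,
    seed: int = 0,
    mean_speeds: np.ndarray | None = None,
) -> MapResult:
    """Select k, fit, canonically relabel, assign identities and score
    context alignment (one-map detection included)."""
    rng = np.random.default_rng(seed)
    k, diag = maps.select_k(tensor, k_max=k_max, reps=reps, restarts=restarts,
                            seed=int(rng.integers(2**31 - 1)))
    cv_seed = int(rng.integers(2**31 - 1))
    masks = maps._speckle_masks(
        tensor.unfold().shape, 0.10, reps, np.random.default_rng(cv_seed)
    )
    diag.cv_real = maps.speckled_cv(tensor, k, masks=masks, seed=cv_seed)
    shuffled = maps.rotation_shuffle(tensor, seed=int(rng.integers(2**31 - 1)))
    diag.cv_shuffled = maps.speckled_cv(shuffled, k, masks=masks, seed=cv_seed)
    diag.one_map, diag.one_map_p = maps.detect_one_map(diag.cv_real, diag.cv_shuffled)
    diag.tsvd_r2 = float(np.mean(maps.tsvd_comparison(tensor, k, masks=masks)))
    if diag.one_map:
        k = 1
    diag.k_selected = k
    model = maps.FactorizedKMeans(
        n_maps=k, n_restarts=restarts, random_state=int(rng.integers(2**31 - 1))
    ).fit(tensor)
    labeling = maps.relabel_maps(model, task, tensor.trial_meta, mean_speeds)
    result = MapResult(k=k, model=model, labeling=labeling, diagnostics=diag)
    if task == "SM" and k >= 2:
        net = similarity.network_similarity_matrix(tensor)
        labeling = maps.assign_context_identity(labeling, net, tensor.trial_meta)
        identities = np.array(
            [labeling.context_of_map[m] for m in labeling.labels], dtype=object
        )
        contexts = tensor.trial_meta["context"].to_numpy(dtype=object)
        result.aligned, result.aligned_fraction = maps.context_alignment(
            identities, contexts
        )
    return result
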