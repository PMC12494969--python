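"""Seeded synthetic VR sessions: behaviour, spike trains and ground truth.

Emulates the recording conditions the downstream analyses assume: a 400 cm
circular VR track sampled at 50 Hz, a leading block of dark (no visual cue)
trials, two visual contexts (A / B) presented in blocks and then in
pseudorandom alternation, and an optional trailing set of reduced-gain
trials.  Spike trains are drawn from inhomogeneous Poisson processes whose
rate functions implement the tuned archetypes of the study system:

``grid``
    distance-periodic firing (von-Mises bumps with a configurable scale)
    that remains periodic during dark running and remaps (circular field
    shift) between contexts;
``ngs``
    non-grid spatial cells with a single place-field-like bump, spatially
    tuned in VR but not distance-periodic in the dark;
``speed_pos`` / ``speed_neg``
    rate linear in running speed with positive / negative slope;
``fs_in``
    putative fast-spiking interneurons (high rate, narrow waveform);
``untuned``
    homogeneous Poisson background cells.

Global remapping is modelled as a network-wide per-trial map label: at each
context switch the active map follows the new context with probability
``remap_probability_per_context_switch``; every tuned cell expresses a
circularly shifted copy of its context-A tuning whenever the active map is
B.  Ground truth (archetypes, tuning parameters, per-trial map labels) is
stored alongside the generated tables so recovery tests have an oracle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SessionBundle",
    "SchemaError",
    "generate_behavior",
    "generate_spikes",
    "generate_session",
    "write_session",
    "read_session",
    "synthesize_lfp",
    "FRAME_COLUMNS",
    "SPIKE_COLUMNS",
    "UNIT_COLUMNS",
]

#: Required columns of each table in a session bundle (the bundle schema).
FRAME_COLUMNS = [
    "t",
    "position",
    "trial",
    "context",
    "trial_type",
    "speed",
    "lick",
    "reward",
    "reward_start",
    "reward_end",
]
SPIKE_COLUMNS = ["unit_id", "t"]
UNIT_COLUMNS = [
    "unit_id",
    "archetype",
    "duration_ms",
    "halfwidth_ms",
    "mean_rate_hz",
    "n_spikes",
    "snr",
    "repolarization_slope",
    "depth_um",
    "peak_trough_ratio",
    "is_good",
]

#: Hidden reward-zone centres per context (cm); zones are 50 cm long.
REWARD_CENTERS = {"A": 270.0, "B": 370.0}
REWARD_ZONE_LENGTH = 50.0


class SchemaError(ValueError):
    """A session bundle is missing a required file or column."""


@dataclass
class SynthConfig:
    """Parameters of a synthetic VR session.

    Trial counts mirror the split-maze (SM) task structure: ``n_dark``
    leading dark trials, sequential context blocks of ``n_blockA`` and
    ``n_blockB`` trials, ``n_alternation`` pseudorandomly alternated
    trials, and ``n_gain`` trailing trials at reduced VR gain.  For the
    random-foraging (RF) task set ``task="RF"``; all non-dark, non-gain
    trials then share a single context ("A").
    """

    seed: int = 0
    track_length: float = 400.0
    frame_rate: float = 50.0
    task: str = "SM"
    n_dark: int = 20
    n_blockA: int = 60
    n_blockB: int = 60
    n_alternation: int = 80
    n_gain: int = 20
    gain: float = 0.7
    speed_mean: float = 40.0
    speed_sd: float = 10.0
    cell_counts: dict = field(
        default_factory=lambda: {
            "grid": 16,
            "ngs": 8,
            "speed_pos": 6,
            "speed_neg": 4,
            "fs_in": 4,
            "untuned": 8,
        }
    )
    grid_scales: tuple = (40.0, 60.0, 80.0, 100.0)
    remap_probability_per_context_switch: float = 1.0
    drift_sd: float = 0.0
    rate_noise: float = 0.1
    baseline_rate: float = 0.3
    grid_peak_rate: float = 8.0
    ngs_peak_rate: float = 10.0
    untuned_rate: float = 3.0
    lick_probability: float = 0.85

    def __post_init__(self) -> None:
        for name in ("n_dark", "n_blockA", "n_blockB", "n_alternation", "n_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.track_length <= 0:
            raise ValueError("track_length must be > 0")
        if any(s <= 0 for s in self.grid_scales):
            raise ValueError("grid scales must be > 0")
        if not 0.0 <= self.remap_probability_per_context_switch <= 1.0:
            raise ValueError("remap probability must be in [0, 1]")
        if self.baseline_rate < 0 or self.grid_peak_rate < 0 or self.ngs_peak_rate < 0:
            raise ValueError("rate parameters must be >= 0")
        if self.untuned_rate < 0:
            raise ValueError("rate parameters must be >= 0")

    @property
    def n_trials(self) -> int:
        return self.n_dark + self.n_blockA + self.n_blockB + self.n_alternation + self.n_gain

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_scales"] = list(self.grid_scales)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "grid_scales" in d:
            d["grid_scales"] = tuple(d["grid_scales"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Generative parameters: per-unit tuning and per-trial map labels."""

    units: pd.DataFrame
    trials: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "units": self.units.to_dict(orient="list"),
            "trials": self.trials.to_dict(orient="list"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(units=pd.DataFrame(d["units"]), trials=pd.DataFrame(d["trials"]))


@dataclass
class SessionBundle:
    """All tables of one session plus ground truth and config."""

    frames: pd.DataFrame
    spikes: pd.DataFrame
    units: pd.DataFrame
    truth: GroundTruth
    config: SynthConfig


# ---------------------------------------------------------------------------
# trial structure


def _trial_structure(config: SynthConfig, rng: np.random.Generator):
    """Return (contexts, trial_types) lists, one entry per trial."""
    contexts: list[str] = []
    types: list[str] = []
    contexts += ["dark"] * config.n_dark
    types += ["dark"] * config.n_dark
    if config.task == "SM":
        contexts += ["A"] * config.n_blockA + ["B"] * config.n_blockB
        # pseudorandom alternation: an independent uniform draw per trial,
        # mirroring the task engine's per-teleport random number
        alt = rng.integers(0, 2, size=config.n_alternation + config.n_gain)
        contexts += ["A" if a == 0 else "B" for a in alt]
    else:
        n_vr = config.n_blockA + config.n_blockB + config.n_alternation + config.n_gain
        contexts += ["A"] * n_vr
    types += ["vr"] * (config.n_blockA + config.n_blockB + config.n_alternation)
    types += ["gain"] * config.n_gain
    return contexts, types


def _map_labels(contexts, types, config: SynthConfig, rng: np.random.Generator):
    """Network-wide per-trial map label under switch-triggered remapping."""
    labels = []
    active = "A"
    prev_context = None
    for ctx, tt in zip(contexts, types):
        if tt == "dark":
            labels.append(active)
            continue
        if prev_context is not None and ctx != prev_context:
            if rng.random() < config.remap_probability_per_context_switch:
                active = ctx
        elif prev_context is None:
            active = ctx
        prev_context = ctx
        labels.append(active)
    return labels


# ---------------------------------------------------------------------------
# behaviour


def generate_behavior(config: SynthConfig) -> pd.DataFrame:
    """Generate a 50 Hz behaviour frame table for one session.

    Running speed is a smoothed positive autoregressive process clipped to
    (2, 150) cm/s; position integrates speed (scaled by the VR gain on gain
    trials) and wraps at the track end, incrementing the trial index.
    Licks and rewards follow the hidden-reward-zone rules of the SM task:
    a lick inside the zone before its centre triggers delivery, otherwise
    the reward is delivered automatically at the zone centre.
    """
    if config.n_trials == 0:
        raise ValueError("configuration yields zero trials (empty session)")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    contexts, types = _trial_structure(config, rng)
    dt = 1.0 / config.frame_rate

    # AR(1) speed stream, smoothed then clipped; generated in one draw for
    # determinism, extended if the session needs more frames
    mean_frames = int(
        config.n_trials * config.track_length / max(config.speed_mean, 5.0) / dt * 1.6 / config.gain
    )
    theta, sigma = 0.02, config.speed_sd * 0.2

    def _speed_stream(n):
        eps = rng.normal(0.0, sigma, size=n)
        v = np.empty(n)
        v[0] = config.speed_mean
        for i in range(1, n):
            v[i] = v[i - 1] + theta * (config.speed_mean - v[i - 1]) + eps[i]
        v = gaussian_filter1d(v, 10.0, mode="nearest")
        return np.clip(v, 2.0, 150.0)

    speed = _speed_stream(max(mean_frames, 64))

    # per-frame integration with position-locked slowing at reward zones and
    # occasional pauses, so lap durations vary the way real running does and
    # the stationary (<2 cm/s) filter has genuine work to do
    L = config.track_length
    pos_all: list[float] = []
    spd_all: list[float] = []
    trial_all: list[int] = []
    pause_plan = []
    for tt in types:
        if rng.random() < 0.3:  # a pause somewhere on ~30% of trials
            pause_plan.append(
                (rng.uniform(0.1 * L, 0.9 * L), int(rng.uniform(0.3, 1.2) / dt))
            )
        else:
            pause_plan.append(None)
    pos = 0.0
    ptr = 0
    trial_idx = 0
    pause_left = 0
    while trial_idx < len(types):
        if ptr >= speed.shape[0]:
            speed = np.concatenate([speed, _speed_stream(max(speed.shape[0], 64))])
        tt = types[trial_idx]
        ctx = contexts[trial_idx]
        g = config.gain if tt == "gain" else 1.0
        v = speed[ptr]
        if ctx in REWARD_CENTERS:  # anticipatory slowing around the zone
            d = pos - REWARD_CENTERS[ctx]
            v *= 1.0 - 0.7 * np.exp(-0.5 * (d / 15.0) ** 2)
        plan = pause_plan[trial_idx]
        if pause_left > 0:
            v *= 0.02
            pause_left -= 1
        elif plan is not None and pos >= plan[0]:
            pause_left = plan[1]
            pause_plan[trial_idx] = None
        pos_all.append(pos)
        spd_all.append(v)
        trial_all.append(trial_idx)
        pos += v * dt * g
        ptr += 1
        if pos >= L:
            pos -= L
            trial_idx += 1
    pos_list = [np.asarray(pos_all)]
    spd_list = [np.asarray(spd_all)]
    trial_list = [np.asarray(trial_all, dtype=int)]

    n = sum(p.shape[0] for p in pos_list)
    frames = pd.DataFrame(
        {
            "t": np.arange(n) * dt,
            "position": np.concatenate(pos_list) if n else np.array([]),
            "trial": np.concatenate(trial_list).astype(int) if n else np.array([], int),
        }
    )
    frames["context"] = np.asarray(contexts, dtype=object)[frames["trial"].to_numpy()]
    frames["trial_type"] = np.asarray(types, dtype=object)[frames["trial"].to_numpy()]
    frames["speed"] = np.concatenate(spd_list) if n else np.array([])

    lick = np.zeros(n, dtype=int)
    reward = np.zeros(n, dtype=int)
    rz_start = np.full(n, np.nan)
    rz_end = np.full(n, np.nan)
    trial_arr = frames["trial"].to_numpy()
    pos_arr = frames["position"].to_numpy()
    for trial_idx, (ctx, tt) in enumerate(zip(contexts, types)):
        if ctx not in REWARD_CENTERS:
            continue
        center = REWARD_CENTERS[ctx]
        z0, z1 = center - REWARD_ZONE_LENGTH / 2, center + REWARD_ZONE_LENGTH / 2
        sel = np.flatnonzero(trial_arr == trial_idx)
        if sel.size == 0:
            continue
        rz_start[sel] = z0
        rz_end[sel] = z1
        in_zone = sel[(pos_arr[sel] >= z0) & (pos_arr[sel] <= z1)]
        pre_center = in_zone[pos_arr[in_zone] < center]
        if pre_center.size and rng.random() < config.lick_probability:
            k = pre_center[rng.integers(0, pre_center.size)]
            lick[k] += 1
            reward[k] = 1
            # a few consummatory licks after delivery
            post = in_zone[in_zone > k][:3]
            lick[post] += 1
        else:
            at_center = in_zone[pos_arr[in_zone] >= center]
            if at_center.size:
                reward[at_center[0]] = 1
    frames["lick"] = lick
    frames["reward"] = reward
    frames["reward_start"] = rz_start
    frames["reward_end"] = rz_end
    return frames


# ---------------------------------------------------------------------------
# spikes


def _vonmises_bump(x: np.ndarray, period: float, phase: float, kappa: float = 4.0) -> np.ndarray:
    """Periodic bump train in [0, 1], peak 1 at x = phase (mod period)."""
    return np.exp(kappa * (np.cos(2.0 * np.pi * (x - phase) / period) - 1.0))


def _unit_rate(
    row: pd.Series,
    frames: pd.DataFrame,
    map_by_trial: np.ndarray,
    drift: np.ndarray,
    config: SynthConfig,
) -> np.ndarray:
    """Ground-truth firing rate (Hz) of one unit at every frame."""
    pos = frames["position"].to_numpy()
    trial = frames["trial"].to_numpy()
    speed = frames["speed"].to_numpy()
    is_dark = frames["trial_type"].to_numpy() == "dark"
    L = config.track_length
    arch = row["archetype"]
    shift = np.where(map_by_trial[trial] == "B", row["remap_offset_cm"], 0.0)
    phase = row["phase_cm"] + shift + drift[trial]

    if arch == "grid":
        lam = np.full(pos.shape, config.baseline_rate)
        dist = trial * L + pos  # cumulative distance, track laps are exact
        amp = config.grid_peak_rate - config.baseline_rate
        lam = lam + amp * np.where(
            is_dark,
            _vonmises_bump(dist, row["grid_scale_cm"], row["phase_cm"]),
            _vonmises_bump(pos, row["grid_scale_cm"], phase),
        )
    elif arch == "ngs":
        amp = config.ngs_peak_rate - config.baseline_rate
        centered = np.mod(pos - phase + L / 2, L) - L / 2
        bump = np.exp(-0.5 * (centered / row["field_width_cm"]) ** 2)
        lam = config.baseline_rate + amp * np.where(is_dark, 0.0, bump)
    elif arch == "speed_pos":
        lam = row["speed_intercept_hz"] + row["speed_slope"] * speed
    elif arch == "speed_neg":
        lam = row["speed_intercept_hz"] + row["speed_slope"] * speed
    elif arch == "fs_in":
        lam = row["speed_intercept_hz"] + row["speed_slope"] * speed
    elif arch == "untuned":
        lam = np.full(pos.shape, config.untuned_rate)
    else:  # pragma: no cover
        raise ValueError(f"unknown archetype {arch!r}")
    return np.clip(lam, 0.0, None)


def _draw_unit_params(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    uid = 0
    scales = list(config.grid_scales)
    for arch, count in config.cell_counts.items():
        for i in range(int(count)):
            r = {
                "unit_id": uid,
                "archetype": arch,
                "grid_scale_cm": np.nan,
                "phase_cm": np.nan,
                "field_width_cm": np.nan,
                "speed_slope": 0.0,
                "speed_intercept_hz": np.nan,
                "remap_offset_cm": 0.0,
            }
            if arch == "grid":
                r["grid_scale_cm"] = scales[i % len(scales)]
                r["phase_cm"] = rng.uniform(0.0, r["grid_scale_cm"])
                r["remap_offset_cm"] = rng.uniform(0.3, 0.7) * r["grid_scale_cm"]
            elif arch == "ngs":
                r["phase_cm"] = rng.uniform(10.0, config.track_length - 10.0)
                r["field_width_cm"] = rng.uniform(15.0, 25.0)
                r["remap_offset_cm"] = rng.uniform(0.25, 0.75) * config.track_length
            elif arch == "speed_pos":
                r["speed_slope"] = rng.uniform(0.1, 0.2)
                r["speed_intercept_hz"] = rng.uniform(0.5, 1.5)
            elif arch == "speed_neg":
                r["speed_slope"] = -rng.uniform(0.05, 0.12)
                r["speed_intercept_hz"] = rng.uniform(8.0, 12.0)
            elif arch == "fs_in":
                r["speed_slope"] = rng.uniform(0.05, 0.3)
                r["speed_intercept_hz"] = rng.uniform(42.0, 55.0)
            rows.append(r)
            uid += 1
    return pd.DataFrame(rows)


def _unit_meta(params: pd.DataFrame, spikes: pd.DataFrame, duration_s: float, rng) -> pd.DataFrame:
    """Waveform/QC metadata consistent with each archetype."""
    n = len(params)
    counts = spikes.groupby("unit_id").size().reindex(params["unit_id"], fill_value=0).to_numpy()
    is_in = (params["archetype"] == "fs_in").to_numpy()
    units = pd.DataFrame(
        {
            "unit_id": params["unit_id"].to_numpy(),
            "archetype": params["archetype"].to_numpy(),
            "duration_ms": np.where(is_in, rng.uniform(0.15, 0.3, n), rng.uniform(0.4, 0.8, n)),
            "halfwidth_ms": np.where(is_in, rng.uniform(0.08, 0.15, n), rng.uniform(0.15, 0.28, n)),
            "mean_rate_hz": counts / duration_s if duration_s > 0 else np.zeros(n),
            "n_spikes": counts,
            "snr": rng.uniform(1.5, 6.0, n),
            "repolarization_slope": rng.uniform(0.1, 1.0, n),
            "depth_um": rng.uniform(400.0, 3000.0, n),
            "peak_trough_ratio": rng.uniform(0.3, 1.2, n),
            "is_good": np.ones(n, dtype=bool),
        }
    )
    return units


def generate_spikes(
    config: SynthConfig, frames: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw spike trains for every configured unit over the given frames.

    Spikes follow an inhomogeneous Poisson process discretised at the frame
    rate: counts per 20 ms frame are Poisson with mean lambda(t) * dt and
    spike times are placed uniformly within their frame.  Per-trial
    multiplicative rate jitter (lognormal, sd = ``rate_noise``) and
    per-trial phase drift (``drift_sd`` cm) model slow instability.
    """
    if len(frames) == 0:
        raise ValueError("frames table is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    params = _draw_unit_params(config, rng)
    n_trials = int(frames["trial"].max()) + 1
    ctx_by_trial = frames.groupby("trial")["context"].first().reindex(range(n_trials)).to_numpy()
    type_by_trial = (
        frames.groupby("trial")["trial_type"].first().reindex(range(n_trials)).to_numpy()
    )
    map_by_trial = np.asarray(
        _map_labels(list(ctx_by_trial), list(type_by_trial), config, rng), dtype=object
    )

    dt = 1.0 / config.frame_rate
    t = frames["t"].to_numpy()
    trial = frames["trial"].to_numpy()
    all_uid, all_t = [], []
    for _, row in params.iterrows():
        urng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 2, int(row["unit_id"])])
        )
        drift = np.cumsum(urng.normal(0.0, config.drift_sd, size=n_trials))
        lam = _unit_rate(row, frames, map_by_trial, drift, config)
        if config.rate_noise > 0:
            g = np.exp(
                urng.normal(-0.5 * config.rate_noise**2, config.rate_noise, size=n_trials)
            )
            lam = lam * g[trial]
        counts = urng.poisson(lam * dt)
        idx = np.repeat(np.arange(counts.shape[0]), counts)
        times = t[idx] + urng.uniform(0.0, dt, size=idx.shape[0])
        all_uid.append(np.full(idx.shape[0], int(row["unit_id"])))
        all_t.append(times)
    spikes = pd.DataFrame(
        {
            "unit_id": np.concatenate(all_uid) if all_uid else np.array([], int),
            "t": np.concatenate(all_t) if all_t else np.array([]),
        }
    ).sort_values(["unit_id", "t"], kind="stable", ignore_index=True)

    duration = t[-1] + dt - t[0]
    units = _unit_meta(params, spikes, duration, rng)
    truth_trials = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "context": ctx_by_trial,
            "trial_type": type_by_trial,
            "map_label": map_by_trial,
        }
    )
    truth = GroundTruth(units=params, trials=truth_trials)
    return spikes, units, truth


def generate_session(config: SynthConfig) -> SessionBundle:
    """Generate a full session bundle (behaviour + spikes + truth)."""
    frames = generate_behavior(config)
    spikes, units, truth = generate_spikes(config, frames)
    return SessionBundle(frames=frames, spikes=spikes, units=units, truth=truth, config=config)


# ---------------------------------------------------------------------------
# bundle I/O


def write_session(bundle: SessionBundle, path: str | Path) -> Path:
    """Write a session bundle to a directory of plain-text files.

    Layout: ``frames.csv``, ``spikes.csv``, ``units.csv``, ``truth.json``,
    ``config.yaml`` (column schemas in ``FRAME_COLUMNS`` etc.).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    bundle.frames.to_csv(path / "frames.csv", index=False)
    bundle.spikes.to_csv(path / "spikes.csv", index=False)
    bundle.units.to_csv(path / "units.csv", index=False)
    (path / "truth.json").write_text(json.dumps(bundle.truth.to_dict()))
    (path / "config.yaml").write_text(yaml.safe_dump(bundle.config.to_dict()))
    return path


def _require_columns(df: pd.DataFrame, columns, table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"table {table!r} is missing column(s): {', '.join(missing)}")


def read_session(path: str | Path) -> SessionBundle:
    """Read a session bundle, validating files and column schemas."""
    path = Path(path)
    for name in ("frames", "spikes", "units"):
        if not (path / f"{name}.csv").exists():
            raise SchemaError(f"bundle at {path} is missing table {name!r} ({name}.csv)")
    frames = pd.read_csv(path / "frames.csv")
    spikes = pd.read_csv(path / "spikes.csv")
    units = pd.read_csv(path / "units.csv")
    _require_columns(frames, FRAME_COLUMNS, "frames")
    _require_columns(spikes, SPIKE_COLUMNS, "spikes")
    _require_columns(units, [c for c in UNIT_COLUMNS if c != "archetype"], "units")
    truth_path = path / "truth.json"
    truth = (
        GroundTruth.from_dict(json.loads(truth_path.read_text()))
        if truth_path.exists()
        else GroundTruth(units=pd.DataFrame(), trials=pd.DataFrame())
    )
    cfg_path = path / "config.yaml"
    config = (
        SynthConfig.from_dict(yaml.safe_load(cfg_path.read_text()))
        if cfg_path.exists()
        else SynthConfig()
    )
    return SessionBundle(frames=frames, spikes=spikes, units=units, truth=truth, config=config)


# ---------------------------------------------------------------------------
# LFP helper (for lfp module tests only; see Non-goals)


def synthesize_lfp(
    duration_s: float,
    fs: float,
    components: list[tuple[float, float]],
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Sum-of-sinusoids + white noise trace: components = [(freq Hz, amp)]."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * fs))) / fs
    x = rng.normal(0.0, noise_sd, size=t.shape[0])
    for f, a in components:
        x = x + a * np.sin(2.0 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return x
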