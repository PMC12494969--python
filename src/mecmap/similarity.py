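"""Normalised rate tensors, cross-trial correlation and similarity statistics.

Population analyses operate on a trials x bins x cells tensor of smoothed
(SD 5 cm) spatial firing rates, min-max scaled per cell to [0, 1] so
high-rate cells do not dominate.  Per-cell cross-trial correlation matrices
(lag-0 normalised cross-correlation = Pearson correlation of mean-centred
spatial vectors) summarise trial-to-trial similarity; group means of their
entries yield spatial stability, context-similarity ratios, gain-change
responses and remapping-coordination measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tuning import TrialRateMatrix

__all__ = [
    "RateTensor",
    "normalize_tensor",
    "cross_trial_matrix",
    "trial_stability",
    "within_map_stability",
    "similarity_ratio_block",
    "similarity_ratio_alt",
    "rate_remapping_pct",
    "spatial_dissimilarity",
    "network_similarity_matrix",
    "remapping_coordination",
    "gain_response_magnitude",
]


@dataclass
class RateTensor:
    """Trials x bins x cells tensor, each cell min-max scaled to [0, 1].

    ``trial_meta`` keeps, per tensor row, the original trial id, context
    and task phase; ``groups`` maps group names (``"A"``, ``"B"`` for block
    trials; ``"A'"``, ``"B'"`` for alternation trials) to row indices.
    Silent (constant-rate) cells are kept as all-zero.
    """

    X: np.ndarray  # (I, J, K)
    trial_meta: pd.DataFrame  # columns: trial, context, phase
    half: str = "full"
    context_sorted: bool = False

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def groups(self) -> dict[str, np.ndarray]:
        meta = self.trial_meta
        out = {}
        for name, (ctx, phase) in {
            "A": ("A", "blockA"),
            "B": ("B", "blockB"),
            "A'": ("A", "alt"),
            "B'": ("B", "alt"),
        }.items():
            out[name] = np.flatnonzero(
                (meta["context"] == ctx) & (meta["phase"] == phase)
            )
        return out

    def unfold(self) -> np.ndarray:
        """Trials x (bins * cells) matrix of flattened trial vectors."""
        return self.X.reshape(self.n_trials, -1)


def _phase_of_trials(trial_info: pd.DataFrame) -> np.ndarray:
    """Task phase per trial: dark / blockA / blockB / alt / gain."""
    ctx = trial_info["context"].to_numpy(dtype=object)
    tt = trial_info["trial_type"].to_numpy(dtype=object)
    phase = np.empty(len(trial_info), dtype=object)
    seen_b = False
    prev_ctx = None
    for i, (c, t) in enumerate(zip(ctx, tt)):
        if t == "dark":
            phase[i] = "dark"
        elif t == "gain":
            phase[i] = "gain"
        else:
            # blocks end at the first context switch after B appeared
            if c == "B" and not seen_b:
                seen_b = True
                phase[i] = "blockB"
            elif not seen_b:
                phase[i] = "blockA"
            elif c == "B" and prev_ctx in ("B", None) and phase[i - 1] == "blockB":
                phase[i] = "blockB"
            else:
                phase[i] = "alt"
        prev_ctx = c
    return phase


def normalize_tensor(
    matrices: list[TrialRateMatrix],
    trial_info: pd.DataFrame,
    sort_alternation: bool = False,
    half: str = "full",
    include_gain: bool = False,
) -> RateTensor:
    """Stack per-cell rate matrices into a min-max-scaled tensor.

    ``trial_info`` needs columns ``trial``, ``context``, ``trial_type``
    covering the rows of every matrix.  Dark trials are always omitted;
    gain trials are omitted by default.  With ``sort_alternation`` the
    alternation trials are stably sorted by context (chronological order
    preserved within context).  ``half`` restricts bins to the front
    ([0, L/2)) or back ([L/2, L)) half of the track.
    """
    if not matrices:
        raise ValueError("need at least one cell")
    info = trial_info.set_index("trial")
    phase_all = pd.Series(
        _phase_of_trials(trial_info), index=trial_info["trial"].to_numpy()
    )
    trials = matrices[0].trials
    keep_types = {"vr"} | ({"gain"} if include_gain else set())
    keep = np.array([info.loc[tr, "trial_type"] in keep_types for tr in trials])
    kept_trials = trials[keep]
    meta = pd.DataFrame(
        {
            "trial": kept_trials,
            "context": [info.loc[tr, "context"] for tr in kept_trials],
            "phase": [phase_all.loc[tr] for tr in kept_trials],
        }
    )
    if sort_alternation:
        is_alt = (meta["phase"] != "blockA") & (meta["phase"] != "blockB")
        order = np.concatenate(
            [
                np.flatnonzero(~is_alt),
                np.flatnonzero(is_alt & (meta["context"] == "A")),
                np.flatnonzero(is_alt & (meta["context"] != "A")),
            ]
        )
        meta = meta.iloc[order].reset_index(drop=True)
    else:
        order = np.arange(len(meta))

    n_bins = matrices[0].n_bins
    if half == "front":
        bin_slice = slice(0, n_bins // 2)
    elif half == "back":
        bin_slice = slice(n_bins // 2, n_bins)
    elif half == "full":
        bin_slice = slice(0, n_bins)
    else:
        raise ValueError("half must be 'full', 'front' or 'back'")

    layers = []
    row_sel = np.flatnonzero(keep)[order]
    for m in matrices:
        V = m.values[row_sel][:, bin_slice].astype(float)
        lo, hi = np.nanmin(V), np.nanmax(V)
        if hi > lo:
            V = (V - lo) / (hi - lo)
        else:  # silent / constant cell kept as zero
            V = np.zeros_like(V)
        layers.append(V)
    X = np.stack(layers, axis=-1)
    return RateTensor(X=X, trial_meta=meta, half=half, context_sorted=sort_alternation)


# ---------------------------------------------------------------------------
# cross-trial correlation


def cross_trial_matrix(trial_vectors: np.ndarray) -> np.ndarray:
    """Trial-pair correlation matrix of one cell's (I, J) rate matrix.

    Each trial's mean rate is subtracted and the lag-0 normalised
    cross-correlation (= Pearson correlation) computed for every pair;
    zero-variance trials yield missing (NaN) rows/columns.
    """
    V = np.asarray(trial_vectors, dtype=float)
    C = V - np.nanmean(V, axis=1, keepdims=True)
    sd = np.sqrt(np.nansum(C**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (C @ C.T) / np.outer(sd, sd)
    R[(sd == 0) | ~np.isfinite(sd), :] = np.nan
    R[:, (sd == 0) | ~np.isfinite(sd)] = np.nan
    np.fill_diagonal(R, np.where(np.isfinite(np.diag(R)), 1.0, np.nan))
    return R


def _neighbor_sets(n: int, n_neighbors: int):
    """Up to ``n_neighbors`` nearest other trials by index distance,
    tie-break toward the earlier trial; truncated at the edges."""
    for i in range(n):
        others = sorted(range(n), key=lambda j: (abs(j - i), j))
        yield i, [j for j in others if j != i][:n_neighbors]


def trial_stability(matrix: np.ndarray, rows: np.ndarray | None = None,
                    n_neighbors: int = 5) -> float:
    """Mean correlation of each trial with its 5 nearest neighbours.

    ``rows`` restricts (and orders) the trials considered; windows truncate
    at the edges of the set.  Undefined (NaN) for fewer than 2 trials.
    """
    M = np.asarray(matrix, dtype=float)
    if rows is not None:
        M = M[np.ix_(rows, rows)]
    n = M.shape[0]
    if n < 2:
        return float("nan")
    per_trial = []
    for i, neigh in _neighbor_sets(n, n_neighbors):
        vals = M[i, neigh]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            per_trial.append(vals.mean())
    return float(np.mean(per_trial)) if per_trial else float("nan")


def within_map_stability(matrix: np.ndarray, map_labels: np.ndarray,
                         n_neighbors: int = 5) -> float:
    """Trial stability computed within each map, averaged across maps with
    at least two trials."""
    labels = np.asarray(map_labels)
    vals = []
    for lab in pd.unique(labels):
        rows = np.flatnonzero(labels == lab)
        if rows.shape[0] >= 2:
            s = trial_stability(matrix, rows, n_neighbors)
            if np.isfinite(s):
                vals.append(s)
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# group similarity statistics


def _pair_mean(matrix: np.ndarray, rows_a: np.ndarray, rows_b: np.ndarray) -> float:
    """Mean pairwise similarity between two trial groups (NaN pairs and the
    diagonal excluded; within-group uses unordered pairs)."""
    A = np.asarray(rows_a)
    B = np.asarray(rows_b)
    if A.size == 0 or B.size == 0:
        return float("nan")
    sub = np.asarray(matrix, dtype=float)[np.ix_(A, B)]
    if np.array_equal(A, B):
        iu = np.triu_indices(A.size, k=1)
        vals = sub[iu]
    else:
        vals = sub[A[:, None] != B[None, :]]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def similarity_ratio_block(matrix: np.ndarray, groups: dict[str, np.ndarray]) -> float:
    """Block-phase context-specificity: mean(AxA, BxB) / mean(AxB).

    1 means context-matched trials are no more mutually similar than
    mismatched ones; > 1 implies context-specific spatial firing.
    Undefined (NaN) when the mismatched mean is <= 0.
    """
    axa = _pair_mean(matrix, groups["A"], groups["A"])
    bxb = _pair_mean(matrix, groups["B"], groups["B"])
    axb = _pair_mean(matrix, groups["A"], groups["B"])
    matched = np.nanmean([axa, bxb])
    if not np.isfinite(axb) or axb <= 0:
        return float("nan")
    return float(matched / axb)


def similarity_ratio_alt(matrix: np.ndarray, groups: dict[str, np.ndarray]) -> float:
    """Alternation-phase context-specificity:
    mean(AxA', BxB') / mean(AxB', BxA')."""
    matched = np.nanmean(
        [
            _pair_mean(matrix, groups["A"], groups["A'"]),
            _pair_mean(matrix, groups["B"], groups["B'"]),
        ]
    )
    mismatched = np.nanmean(
        [
            _pair_mean(matrix, groups["A"], groups["B'"]),
            _pair_mean(matrix, groups["B"], groups["A'"]),
        ]
    )
    if not np.isfinite(mismatched) or mismatched <= 0:
        return float("nan")
    return float(matched / mismatched)


def rate_remapping_pct(cell_tensor: np.ndarray, rows_a: np.ndarray,
                       rows_b: np.ndarray) -> float:
    """Percent change in peak rate of the trial-averaged normalised spatial
    vector from Block A to Block B: 100 * (peak_B - peak_A) / peak_A."""
    V = np.asarray(cell_tensor, dtype=float)
    peak_a = float(np.nanmax(np.nanmean(V[rows_a], axis=0)))
    peak_b = float(np.nanmax(np.nanmean(V[rows_b], axis=0)))
    if peak_a == 0:
        return float("nan")
    return 100.0 * (peak_b - peak_a) / peak_a


def spatial_dissimilarity(cell_tensor: np.ndarray, rows_a: np.ndarray,
                          rows_b: np.ndarray) -> float:
    """1 - cosine similarity of the Block A and Block B mean spatial
    vectors: 0 = identical pattern, 1 = orthogonal."""
    V = np.asarray(cell_tensor, dtype=float)
    a = np.nanmean(V[rows_a], axis=0)
    b = np.nanmean(V[rows_b], axis=0)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(1.0 - np.dot(a, b) / (na * nb))


def network_similarity_matrix(tensor: RateTensor, min_cells: int | None = None) -> np.ndarray:
    """Trial-pair correlation of flattened bins x cells population vectors.

    ``min_cells`` enforces the population-eligibility gate (>10 spatial
    cells for RF, >=10 grid cells for SM sessions)."""
    K = tensor.X.shape[2]
    if min_cells is not None and K < min_cells:
        raise ValueError(f"session ineligible: {K} cells < required {min_cells}")
    return cross_trial_matrix(tensor.unfold())


def remapping_coordination(unit_matrix: np.ndarray, network_matrix: np.ndarray) -> float:
    """Correlation between a unit's cross-trial matrix and the network-wide
    matrix built from the remaining co-recorded units (upper triangle,
    diagonal excluded)."""
    U = np.asarray(unit_matrix, dtype=float)
    N = np.asarray(network_matrix, dtype=float)
    iu = np.triu_indices(U.shape[0], k=1)
    u, v = U[iu], N[iu]
    ok = np.isfinite(u) & np.isfinite(v)
    if ok.sum() < 3 or np.std(u[ok]) == 0 or np.std(v[ok]) == 0:
        return float("nan")
    return float(np.corrcoef(u[ok], v[ok])[0, 1])


def gain_response_magnitude(matrix: np.ndarray, pre_rows: np.ndarray,
                            post_rows: np.ndarray) -> float:
    """Gain-change response: mean pairwise similarity within the baseline
    trials minus the mean similarity of baseline vs post-gain trials.

    The baseline is restricted to the last ``len(post_rows)`` pre-gain
    trials so pre and post sets are matched in size; larger values mean a
    stronger response to the gain manipulation.
    """
    post = np.asarray(post_rows)
    if post.size == 0:
        return float("nan")
    pre = np.asarray(pre_rows)[-post.size:]
    within = _pair_mean(matrix, pre, pre)
    across = _pair_mean(matrix, pre, post)
    return float(within - across)
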