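"""Factorized k-means spatial-map clustering and context-alignment scoring.

The population tensor X (trials x bins x cells) is modelled as
``X_hat[i, j, k] = sum_r U[i, r] * V[r, j, k]`` with one-hot rows ``U`` —
ordinary k-means on flattened trial vectors, where each centroid slice
``V[r]`` is a spatial map (one tuning curve per cell).  The model rank
(number of maps, k) is selected by silhouette-score maximisation over
repeated fits; sessions whose speckled-holdout cross-validated performance
does not beat a rotation-shuffled control are flagged as one-map sessions.
Fitted maps are relabelled deterministically (map 1 = most Block A trials
in the split-maze task; slowest-running map first in random foraging),
assigned context identities, and scored for remap frequency and
context alignment.

``FactorizedKMeans`` follows the scikit-learn estimator protocol
(``fit`` / ``predict`` / ``get_params``), with masked (speckled-holdout)
fitting supported via ``fit(X, mask=...)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.metrics import silhouette_score

from .similarity import RateTensor

__all__ = [
    "FactorizedKMeans",
    "MapDiagnostics",
    "MapLabeling",
    "fit_factorized_kmeans",
    "select_k",
    "speckled_cv",
    "rotation_shuffle",
    "detect_one_map",
    "tsvd_comparison",
    "relabel_maps",
    "assign_context_identity",
    "detect_remaps",
    "remap_frequency",
    "context_alignment",
    "uncentered_r2",
]


def _as_matrix(X) -> np.ndarray:
    """Accept a RateTensor, a 3-d tensor, or an already-unfolded matrix."""
    if isinstance(X, RateTensor):
        return X.unfold()
    X = np.asarray(X, dtype=float)
    if X.ndim == 3:
        return X.reshape(X.shape[0], -1)
    return X


class FactorizedKMeans(BaseEstimator):
    """K-means on flattened trial vectors, with masked-entry support.

    Parameters
    ----------
    n_maps : int
        Model rank R (number of spatial maps / clusters).
    n_restarts : int
        Independent k-means++-seeded Lloyd runs; the restart with the
        lowest reconstruction error on observed entries is kept.
    max_iter : int
        Lloyd iteration cap per restart (converges when assignments stop
        changing).
    random_state : int or None
        Seed for restart initialisation.

    Attributes
    ----------
    labels_ : (I,) map label per trial.
    centroids_ : (R, J*K) flattened centroid per map.
    inertia_ : summed squared reconstruction error over observed entries.
    n_iter_ : Lloyd iterations used by the winning restart.
    """

    def __init__(self, n_maps: int = 2, n_restarts: int = 100, max_iter: int = 100,
                 random_state: int | None = 0):
        self.n_maps = n_maps
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    @staticmethod
    def _masked_distances(M, obs, centroids):
        """Mean squared distance over observed entries, trials x R."""
        d = np.empty((M.shape[0], centroids.shape[0]))
        counts = obs.sum(axis=1).astype(float)
        counts[counts == 0] = 1.0
        for r in range(centroids.shape[0]):
            diff = np.where(obs, M - centroids[r], 0.0)
            d[:, r] = (diff**2).sum(axis=1) / counts
        return d

    def _plusplus_init(self, M, obs, rng):
        """k-means++ seeding on the mean-imputed matrix."""
        filled = M.copy()
        col_mean = np.where(obs, M, 0.0).sum(0) / np.maximum(obs.sum(0), 1)
        filled[~obs] = np.broadcast_to(col_mean, M.shape)[~obs]
        n = M.shape[0]
        centers = [filled[rng.integers(n)]]
        for _ in range(1, self.n_maps):
            d2 = np.min(
                [((filled - c) ** 2).sum(axis=1) for c in centers], axis=0
            )
            total = d2.sum()
            probs = d2 / total if total > 0 else np.full(n, 1.0 / n)
            centers.append(filled[rng.choice(n, p=probs)])
        return np.array(centers)

    def _lloyd(self, M, obs, rng):
        centroids = self._plusplus_init(M, obs, rng)
        labels = np.full(M.shape[0], -1)
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            d = self._masked_distances(M, obs, centroids)
            new_labels = d.argmin(axis=1)
            for r in range(self.n_maps):  # re-seed empty clusters at the worst fit
                if not np.any(new_labels == r):
                    new_labels[d.min(axis=1).argmax()] = r
                    d[d.min(axis=1).argmax(), :] = 0
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for r in range(self.n_maps):
                rows = labels == r
                w = obs[rows]
                s = np.where(w, M[rows], 0.0).sum(axis=0)
                c = w.sum(axis=0)
                col_mean = np.where(obs, M, 0.0).sum(0) / np.maximum(obs.sum(0), 1)
                centroids[r] = np.where(c > 0, s / np.maximum(c, 1), col_mean)
        inertia = float(
            (np.where(obs, M - centroids[labels], 0.0) ** 2).sum()
        )
        return labels, centroids, inertia, n_iter

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None, mask: np.ndarray | None = None) -> "FactorizedKMeans":
        """Fit on a tensor / unfolded matrix; ``mask`` marks observed entries."""
        M = _as_matrix(X)
        if self.n_maps < 1:
            raise ValueError("n_maps must be >= 1")
        if self.n_maps > M.shape[0]:
            raise ValueError(f"n_maps={self.n_maps} exceeds {M.shape[0]} trials")
        obs = (
            np.ones(M.shape, dtype=bool)
            if mask is None
            else _as_matrix(mask).astype(bool)
        )
        self._shape3 = np.asarray(X.X if isinstance(X, RateTensor) else X).shape
        if self.n_maps == 1:  # grand-centroid model, no restarts needed
            col_mean = np.where(obs, M, 0.0).sum(0) / np.maximum(obs.sum(0), 1)
            self.labels_ = np.zeros(M.shape[0], dtype=int)
            self.centroids_ = col_mean[None, :]
            self.inertia_ = float((np.where(obs, M - col_mean, 0.0) ** 2).sum())
            self.n_iter_ = 1
            return self
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_restarts):
            labels, centroids, inertia, n_iter = self._lloyd(M, obs, rng)
            if best is None or inertia < best[2]:
                best = (labels, centroids, inertia, n_iter)
        self.labels_, self.centroids_, self.inertia_, self.n_iter_ = best
        return self

    def predict(self, X) -> np.ndarray:
        M = _as_matrix(X)
        obs = np.ones(M.shape, dtype=bool)
        return self._masked_distances(M, obs, self.centroids_).argmin(axis=1)

    def reconstruct(self) -> np.ndarray:
        """X_hat: each trial replaced by its assigned centroid (3-d)."""
        flat = self.centroids_[self.labels_]
        if len(self._shape3) == 3:
            return flat.reshape(self._shape3)
        return flat

    @property
    def centroid_maps_(self) -> np.ndarray:
        """Centroids as (R, J, K) spatial maps when fitted on a tensor."""
        if len(self._shape3) == 3:
            return self.centroids_.reshape(self.n_maps, *self._shape3[1:])
        return self.centroids_


def fit_factorized_kmeans(
    tensor, k: int, restarts: int = 100, seed: int | None = 0,
    mask: np.ndarray | None = None,
) -> FactorizedKMeans:
    """Functional wrapper over :class:`FactorizedKMeans`."""
    return FactorizedKMeans(
        n_maps=k, n_restarts=restarts, random_state=seed
    ).fit(tensor, mask=mask)


# ---------------------------------------------------------------------------
# model selection


@dataclass
class MapDiagnostics:
    """Model-selection diagnostics for one session."""

    silhouette: pd.DataFrame = field(default_factory=pd.DataFrame)  # k, rep, score
    k_selected: int = 0
    cv_real: np.ndarray = field(default_factory=lambda: np.array([]))
    cv_shuffled: np.ndarray = field(default_factory=lambda: np.array([]))
    one_map: bool = False
    one_map_p: float = float("nan")
    tsvd_r2: float = float("nan")


def select_k(
    tensor, k_max: int = 4, reps: int = 10, restarts: int = 100, seed: int = 0
) -> tuple[int, MapDiagnostics]:
    """Silhouette-maximising model rank over k in {2..k_max}.

    Each repetition refits the model with fresh random restarts and scores
    the mean silhouette (Euclidean, on flattened trial vectors); the k with
    the highest repetition-mean silhouette wins.  Rank 1 is not scored
    here — one-map sessions are detected separately via
    :func:`detect_one_map`.
    """
    M = _as_matrix(tensor)
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(2, k_max + 1):
        for rep in range(reps):
            model = FactorizedKMeans(
                n_maps=k, n_restarts=restarts,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(M)
            score = (
                silhouette_score(M, model.labels_)
                if len(np.unique(model.labels_)) > 1
                else float("nan")
            )
            rows.append({"k": k, "rep": rep, "silhouette": score})
    sil = pd.DataFrame(rows)
    means = sil.groupby("k")["silhouette"].mean()
    k_star = int(means.idxmax())
    diag = MapDiagnostics(silhouette=sil, k_selected=k_star)
    return k_star, diag


def uncentered_r2(actual: np.ndarray, predicted: np.ndarray) -> float:
    """1 - SS_err / SS_total with no mean-centering of the data."""
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    denom = float(np.dot(a, a))
    if denom == 0:
        return float("nan")
    return float(1.0 - np.sum((a - p) ** 2) / denom)


def _speckle_masks(shape, holdout, replicates, rng):
    masks = []
    n = int(np.prod(shape))
    n_hold = int(round(holdout * n))
    for _ in range(replicates):
        flat = np.ones(n, dtype=bool)
        flat[rng.choice(n, size=n_hold, replace=False)] = False
        masks.append(flat.reshape(shape))
    return masks


def speckled_cv(
    tensor, rank: int, holdout: float = 0.10, replicates: int = 10,
    restarts: int = 10, seed: int = 0, masks: list | None = None,
) -> np.ndarray:
    """Cross-validated model performance under a speckled-holdout pattern.

    In each replicate 10% of tensor entries are censored at random, the
    model is fit on the rest (masked centroid updates and distances), and
    the uncentered R^2 of the reconstruction on the censored entries is
    returned (one value per replicate).
    """
    M = _as_matrix(tensor)
    rng = np.random.default_rng(seed)
    if masks is None:
        masks = _speckle_masks(M.shape, holdout, replicates, rng)
    scores = []
    for mask in masks:
        mask = _as_matrix(mask).astype(bool)
        model = FactorizedKMeans(
            n_maps=rank, n_restarts=restarts,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(M, mask=mask)
        recon = model.centroids_[model.labels_]
        scores.append(uncentered_r2(M[~mask], recon[~mask]))
    return np.asarray(scores)


def rotation_shuffle(tensor, seed: int = 0):
    """Shuffle a tensor by a random rotation across trials.

    Left-multiplies the trial-mode unfolding by a random orthogonal matrix:
    the data norm and the bin x cell correlation structure are preserved,
    but the one-hot (discrete cluster) structure on trials is destroyed.
    """
    M = _as_matrix(tensor)
    rng = np.random.default_rng(seed)
    Q = stats.ortho_group.rvs(M.shape[0], random_state=rng)
    Y = Q @ M
    if isinstance(tensor, RateTensor):
        return RateTensor(
            X=Y.reshape(tensor.X.shape),
            trial_meta=tensor.trial_meta,
            half=tensor.half,
            context_sorted=tensor.context_sorted,
        )
    X = np.asarray(tensor, dtype=float)
    return Y.reshape(X.shape)


def detect_one_map(
    cv_real: np.ndarray, cv_shuffled: np.ndarray, alpha: float = 0.05
) -> tuple[bool, float]:
    """One-map session iff real cross-validated performance does not beat
    the rotation-shuffled control (one-sided Wilcoxon signed-rank test).

    Returns (one_map flag, p value).  Identical paired scores are a
    degenerate case with nothing to reject: one_map = True, p = 1.
    """
    real = np.asarray(cv_real, dtype=float)
    shuf = np.asarray(cv_shuffled, dtype=float)
    if real.shape[0] < 5:
        import warnings

        warnings.warn("fewer than 5 replicates: one-map test is underpowered")
    if np.allclose(real, shuf):
        return True, 1.0
    stat = stats.wilcoxon(real, shuf, alternative="greater")
    return bool(stat.pvalue >= alpha), float(stat.pvalue)


def _svd_lowrank(M: np.ndarray, rank: int) -> np.ndarray:
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    return (U[:, :rank] * s[:rank]) @ Vt[:rank]


def tsvd_comparison(
    tensor, rank: int, masks: list | None = None, holdout: float = 0.10,
    replicates: int = 10, seed: int = 0, n_em_iter: int = 50,
) -> np.ndarray:
    """Cross-validated test R^2 of a rank-matched truncated SVD.

    Uses the same speckled-holdout masks as :func:`speckled_cv` (pass them
    in for a paired comparison).  Missing entries are handled by EM-style
    imputation: fill with the current low-rank reconstruction, re-factor,
    repeat.  tSVD relaxes the one-hot constraint of the k-means model, so
    on noise-free data its test performance bounds the k-means score.
    """
    M = _as_matrix(tensor)
    rng = np.random.default_rng(seed)
    if masks is None:
        masks = _speckle_masks(M.shape, holdout, replicates, rng)
    scores = []
    for mask in masks:
        mask = _as_matrix(mask).astype(bool)
        filled = M.copy()
        filled[~mask] = M[mask].mean()
        for _ in range(n_em_iter):
            recon = _svd_lowrank(filled, rank)
            prev = filled[~mask]
            filled[~mask] = recon[~mask]
            if np.max(np.abs(filled[~mask] - prev)) < 1e-10:
                break
        scores.append(uncentered_r2(M[~mask], recon[~mask]))
    return np.asarray(scores)


# ---------------------------------------------------------------------------
# map labeling and alignment


@dataclass
class MapLabeling:
    """Canonical map labels and context identities for one session."""

    labels: np.ndarray  # relabeled map id per trial (1-based), tensor order
    mapping: dict  # raw cluster id -> canonical map id
    context_of_map: dict = field(default_factory=dict)  # map id -> "A" | "B"
    tie_warning: bool = False


def relabel_maps(
    model: FactorizedKMeans,
    task: str,
    trial_meta: pd.DataFrame | None = None,
    mean_speeds: np.ndarray | None = None,
) -> MapLabeling:
    """Deterministic canonical relabeling of arbitrary cluster ids.

    SM: map 1 = most Block A trials; for k = 3-4, map 2 = remaining map
    with most Block B trials; for k = 4, map 3 = remaining map with more
    trials before the midpoint of the context-sorted alternation phase.
    Ties break toward the lowest raw cluster id.  RF: maps ordered by mean
    running speed, slowest first (``mean_speeds`` indexed per trial).
    """
    raw = model.labels_
    k = model.n_maps
    ids = list(range(k))
    order: list[int] = []
    if task == "RF":
        if mean_speeds is None:
            raise ValueError("RF relabeling needs per-trial mean running speeds")
        speed_of = {
            r: (np.mean(mean_speeds[raw == r]) if np.any(raw == r) else np.inf)
            for r in ids
        }
        order = sorted(ids, key=lambda r: (speed_of[r], r))
    else:
        if trial_meta is None:
            raise ValueError("SM relabeling needs trial metadata")
        phase = trial_meta["phase"].to_numpy(dtype=object)
        in_a = phase == "blockA"
        in_b = phase == "blockB"
        remaining = set(ids)
        map1 = max(sorted(remaining), key=lambda r: (np.sum(raw[in_a] == r), -r))
        order.append(map1)
        remaining.discard(map1)
        if remaining:
            map2 = max(sorted(remaining), key=lambda r: (np.sum(raw[in_b] == r), -r))
            order.append(map2)
            remaining.discard(map2)
        if len(remaining) == 2:
            alt_rows = np.flatnonzero(phase == "alt")
            mid = alt_rows[alt_rows.shape[0] // 2] if alt_rows.size else 0
            early = np.zeros(raw.shape[0], dtype=bool)
            early[alt_rows[alt_rows < mid]] = True
            map3 = max(sorted(remaining), key=lambda r: (np.sum(raw[early] == r), -r))
            order.append(map3)
            remaining.discard(map3)
        order += sorted(remaining)
    mapping = {r: i + 1 for i, r in enumerate(order)}
    labels = np.array([mapping[r] for r in raw])
    return MapLabeling(labels=labels, mapping=mapping)


def assign_context_identity(
    labeling: MapLabeling, network_matrix: np.ndarray,
    trial_meta: pd.DataFrame,
) -> MapLabeling:
    """Assign a VR context identity (A or B) to every canonical map.

    Map 1 represents context A and map 2 context B by construction; maps 3
    and 4 go to whichever context's block trials they are more similar to
    on average (ties go to A, flagged).  Several maps may share a context.
    """
    labeling.context_of_map = {}
    phase = trial_meta["phase"].to_numpy(dtype=object)
    rows_a = np.flatnonzero(phase == "blockA")
    rows_b = np.flatnonzero(phase == "blockB")
    for map_id in sorted(set(labeling.labels)):
        if map_id == 1:
            labeling.context_of_map[map_id] = "A"
            continue
        if map_id == 2:
            labeling.context_of_map[map_id] = "B"
            continue
        rows_m = np.flatnonzero(labeling.labels == map_id)
        sim_a = np.nanmean(network_matrix[np.ix_(rows_m, rows_a)])
        sim_b = np.nanmean(network_matrix[np.ix_(rows_m, rows_b)])
        if np.isclose(sim_a, sim_b):
            labeling.tie_warning = True
            labeling.context_of_map[map_id] = "A"
        else:
            labeling.context_of_map[map_id] = "A" if sim_a > sim_b else "B"
    return labeling


def detect_remaps(labels: np.ndarray) -> np.ndarray:
    """Remap flag per consecutive trial pair (chronological label order)."""
    lab = np.asarray(labels)
    return lab[1:] != lab[:-1]


def remap_frequency(labels: np.ndarray) -> float:
    """Remaps per trial within a phase: remap count / trial count."""
    lab = np.asarray(labels)
    if lab.shape[0] == 0:
        return float("nan")
    return float(detect_remaps(lab).sum() / lab.shape[0])


def context_alignment(
    map_identities: np.ndarray, contexts: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-trial aligned flags (map context identity == VR context) and the
    aligned fraction over trials with a defined context."""
    ident = np.asarray(map_identities, dtype=object)
    ctx = np.asarray(contexts, dtype=object)
    defined = np.isin(ctx, ("A", "B"))
    aligned = defined & (ident == ctx)
    frac = float(aligned[defined].mean()) if defined.any() else float("nan")
    return aligned, frac
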