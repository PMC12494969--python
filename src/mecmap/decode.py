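"""Circular-linear position decoding from population spike counts.

Track position is mapped to an angle y_t in [0, 2pi) (position / track
length * 2pi, the track being effectively circular).  The decoder learns
two coefficients per neuron and predicts

    y_hat_t = atan2( sum_n beta1_n * s_nt , sum_n beta2_n * s_nt )

where ``s_nt`` are binned spike counts.  Fitting initialises the
coefficients by ridge least squares of (sin y, cos y) on the counts and
then iteratively maximises the mean-cosine objective
mean cos(y_t - y_hat_t) (L-BFGS with a small ridge penalty); the pure
least-squares fit is available as ``method="lsq"``.  The decoder score is
the mean of cos(y_t - y_hat_t) over test bins: 1 for perfect prediction,
0 for random guesses on the circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .tuning import shift_spike_times

__all__ = [
    "CircularPositionDecoder",
    "DecodeEval",
    "fit_circular_decoder",
    "predict_position",
    "decoder_score",
    "position_to_angle",
    "bin_population_activity",
    "evaluate_decoding",
]


def position_to_angle(position: np.ndarray, track_length: float = 400.0) -> np.ndarray:
    """Map track position (cm) to an angle in [0, 2pi)."""
    return np.mod(np.asarray(position, dtype=float) / track_length * 2.0 * np.pi,
                  2.0 * np.pi)


class CircularPositionDecoder:
    """Circular-linear population decoder (sklearn-style estimator).

    Parameters
    ----------
    alpha : float
        Ridge penalty on the coefficients (numerical stabiliser).
    max_iter, tol : int, float
        Iteration cap and convergence tolerance of the cosine-objective
        maximisation.
    method : {"em", "lsq"}
        "em" runs the iterative cosine-objective maximisation from the
        least-squares initialisation; "lsq" stops at the initialisation.

    Attributes
    ----------
    beta1_, beta2_ : (N,) per-neuron coefficient pairs.
    n_iter_ : iterations used; converged_ : optimiser convergence flag.
    """

    def __init__(self, alpha: float = 1e-6, max_iter: int = 500, tol: float = 1e-6,
                 method: str = "em"):
        self.alpha = alpha
        self.max_iter = max_iter
        self.tol = tol
        self.method = method

    def get_params(self, deep: bool = True) -> dict:
        return {"alpha": self.alpha, "max_iter": self.max_iter, "tol": self.tol,
                "method": self.method}

    def set_params(self, **params) -> "CircularPositionDecoder":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, S: np.ndarray, y: np.ndarray) -> "CircularPositionDecoder":
        """Fit coefficients on counts S (T x N) and angles y (T,)."""
        S = np.asarray(S, dtype=float)
        y = np.asarray(y, dtype=float)
        if S.ndim != 2 or S.shape[0] != y.shape[0]:
            raise ValueError("S must be (T, N) with one angle per row")
        if not np.any(S):
            raise ValueError("all-zero spike count matrix")
        T, N = S.shape
        # ridge least-squares init: regress (sin y, cos y) on counts
        G = S.T @ S + self.alpha * np.eye(N)
        B = np.linalg.solve(G, S.T @ np.column_stack([np.sin(y), np.cos(y)]))
        beta = B.ravel(order="F")  # [beta1..., beta2...]

        sin_y, cos_y = np.sin(y), np.cos(y)

        def neg_objective(b):
            b1, b2 = b[:N], b[N:]
            a = S @ b1
            c = S @ b2
            r = np.sqrt(a**2 + c**2)
            r = np.maximum(r, 1e-12)
            # mean cos(y - y_hat) = mean (a sin y + c cos y) / r
            proj = (a * sin_y + c * cos_y) / r
            f = -proj.mean() + self.alpha * (b @ b)
            ga = (c * (c * sin_y - a * cos_y)) / r**3
            gc = (a * (a * cos_y - c * sin_y)) / r**3
            grad = -np.concatenate([S.T @ ga, S.T @ gc]) / T + 2 * self.alpha * b
            return f, grad

        if self.method == "lsq":
            self.n_iter_ = 0
            self.converged_ = True
        else:
            res = optimize.minimize(
                neg_objective, beta, jac=True, method="L-BFGS-B",
                options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-8},
            )
            beta = res.x
            self.n_iter_ = int(res.nit)
            self.converged_ = bool(res.success)
        self.beta1_ = beta[:N]
        self.beta2_ = beta[N:]
        return self

    def predict(self, S: np.ndarray) -> np.ndarray:
        """Predicted angles in [0, 2pi); NaN where a count row is all zero."""
        S = np.asarray(S, dtype=float)
        a = S @ self.beta1_
        c = S @ self.beta2_
        y_hat = np.mod(np.arctan2(a, c), 2.0 * np.pi)
        y_hat[~S.any(axis=1)] = np.nan
        return y_hat

    def score(self, S: np.ndarray, y: np.ndarray) -> float:
        return decoder_score(y, self.predict(S))


def fit_circular_decoder(S: np.ndarray, y: np.ndarray, seed: int | None = None,
                         **kwargs) -> CircularPositionDecoder:
    """Fit a decoder (deterministic given the data; ``seed`` is accepted for
    interface symmetry with the shuffled controls)."""
    return CircularPositionDecoder(**kwargs).fit(S, y)


def predict_position(model: CircularPositionDecoder, S: np.ndarray) -> np.ndarray:
    return model.predict(S)


def decoder_score(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean of cos(y_t - y_hat_t); undefined bins (NaN) are excluded."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    ok = np.isfinite(y) & np.isfinite(y_hat)
    if not ok.any():
        return float("nan")
    return float(np.mean(np.cos(y[ok] - y_hat[ok])))


# ---------------------------------------------------------------------------
# session-level evaluation


@dataclass
class DecodeEval:
    """Cross-validated decoder scores with their shuffle control."""

    scores: np.ndarray
    shuffle_scores: np.ndarray
    mean_score: float = field(init=False)
    mean_shuffle_score: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_score = float(np.nanmean(self.scores)) if self.scores.size else float("nan")
        self.mean_shuffle_score = (
            float(np.nanmean(self.shuffle_scores)) if self.shuffle_scores.size else float("nan")
        )


def bin_population_activity(
    spikes: pd.DataFrame,
    frames: pd.DataFrame,
    unit_ids: np.ndarray,
    bin_size_s: float = 0.2,
    track_length: float = 400.0,
    speed_threshold: float = 2.0,
):
    """Bin spikes into (T, N) counts with matched angles and speeds.

    Time bins whose mean running speed is below ``speed_threshold``
    (stationary) are dropped.  Returns (S, y, speeds).
    """
    t = frames["t"].to_numpy(dtype=float)
    edges = np.arange(t[0], t[-1] + bin_size_s, bin_size_s)
    centers = (edges[:-1] + edges[1:]) / 2.0
    unit_ids = np.asarray(unit_ids)
    S = np.zeros((centers.shape[0], unit_ids.shape[0]))
    for j, uid in enumerate(unit_ids):
        st = spikes.loc[spikes["unit_id"] == uid, "t"].to_numpy(dtype=float)
        S[:, j], _ = np.histogram(st, bins=edges)
    pos = np.interp(centers, t, frames["position"].to_numpy(dtype=float))
    # binned mean speed via interpolation at centers (bins are short)
    speed = np.interp(centers, t, frames["speed"].to_numpy(dtype=float))
    keep = speed >= speed_threshold
    return S[keep], position_to_angle(pos[keep], track_length), speed[keep]


def match_observations(
    index_sets: list[np.ndarray], y: np.ndarray, speed: np.ndarray,
    n_pos_bins: int = 8, seed: int = 0,
) -> list[np.ndarray]:
    """Down-sample training sets to matched (position x speed-quartile)
    histograms and equal size (greedy per-stratum minimum)."""
    rng = np.random.default_rng(seed)
    pos_bin = np.minimum((y / (2 * np.pi) * n_pos_bins).astype(int), n_pos_bins - 1)
    q = np.quantile(speed, [0.25, 0.5, 0.75])
    speed_bin = np.searchsorted(q, speed)
    stratum = pos_bin * 4 + speed_bin
    matched = []
    strata = np.unique(stratum)
    quota = {
        s: min(int(np.sum(stratum[idx] == s)) for idx in index_sets) for s in strata
    }
    for idx in index_sets:
        take = []
        for s in strata:
            cand = idx[stratum[idx] == s]
            if quota[s] and cand.size:
                take.append(rng.choice(cand, size=quota[s], replace=False))
        matched.append(np.sort(np.concatenate(take)) if take else np.array([], int))
    return matched


def evaluate_decoding(
    spikes: pd.DataFrame,
    frames: pd.DataFrame,
    unit_ids: np.ndarray,
    reps: int = 10,
    holdout: float = 0.10,
    seed: int = 0,
    bin_size_s: float = 0.2,
    track_length: float = 400.0,
    min_cells: int | None = None,
) -> DecodeEval:
    """Repeated 90/10 fit/test decoder evaluation with a spike-time-shuffle
    control.

    Each repetition draws a random 90% of time bins for training and
    scores the rest; the control repeats the protocol on circularly
    time-shifted spike trains (which preserves rates but destroys spatial
    tuning), approximating chance performance.
    """
    unit_ids = np.asarray(unit_ids)
    if min_cells is not None and unit_ids.shape[0] < min_cells:
        raise ValueError(f"session ineligible: {unit_ids.shape[0]} cells < {min_cells}")
    rng = np.random.default_rng(seed)
    S, y, _ = bin_population_activity(
        spikes, frames, unit_ids, bin_size_s, track_length
    )

    t = frames["t"].to_numpy(dtype=float)
    dt = t[1] - t[0] if t.shape[0] > 1 else 0.0
    duration = t[-1] + dt - t[0]
    shuf_spikes = spikes.copy()
    offsets = rng.uniform(20.0, duration, size=unit_ids.shape[0])
    for uid, off in zip(unit_ids, offsets):
        m = shuf_spikes["unit_id"] == uid
        shuf_spikes.loc[m, "t"] = shift_spike_times(
            shuf_spikes.loc[m, "t"].to_numpy(dtype=float), t[0], duration, off
        )
    S_shuf, y_shuf, _ = bin_population_activity(
        shuf_spikes, frames, unit_ids, bin_size_s, track_length
    )

    def _rep_scores(Sm, ym):
        out = []
        T = Sm.shape[0]
        n_test = max(1, int(round(holdout * T)))
        for _ in range(reps):
            test = np.zeros(T, dtype=bool)
            test[rng.choice(T, size=n_test, replace=False)] = True
            model = CircularPositionDecoder().fit(Sm[~test], ym[~test])
            out.append(decoder_score(ym[test], model.predict(Sm[test])))
        return np.asarray(out)

    return DecodeEval(scores=_rep_scores(S, y), shuffle_scores=_rep_scores(S_shuf, y_shuf))
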