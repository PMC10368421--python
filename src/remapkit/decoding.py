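"""Memoryless Bayesian position decoding and the decoding accuracy index.

Position is decoded frame by frame from the population's active-frame vector
using per-cell emission models built from a training session's rate maps
(independent Bernoulli on active frames by default, Poisson counts as an
option), with a uniform prior over bins.  Decoding error is referenced to a
cell-identity shuffle; the Wilcoxon signed-rank p-value of the per-frame
error differences and the sign of the accuracy gain G combine into the
decoding accuracy index DAI = −log10(p)·sign(G) − 2, which is zero at
p = 0.01 with above-chance decoding and is unbiased by track position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .behavior import N_BINS, BeelineTrial, PositionTrace, bin_centers, bin_index

__all__ = [
    "DecodingResult",
    "bayes_decode_frame",
    "decode_frames",
    "decode_session_pair",
    "shuffle_decoding_error",
    "accuracy_index",
    "dai",
]

_EPS = 1e-6


@dataclass
class DecodingResult:
    """Per-bin decoding summary for a session pair (averaged over running
    directions and decode directions)."""

    de_cm: np.ndarray  # (n_bins,) median decoding error per bin
    g_cm: np.ndarray  # (n_bins,) accuracy gain vs shuffle
    wilcoxon_p: np.ndarray  # (n_bins,)
    dai: np.ndarray  # (n_bins,)
    n_cells_per_direction: int = 0


def _log_emission(
    rate_maps: np.ndarray, frame_rate: float, emission: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell per-bin log-probabilities for active/inactive frames."""
    p = np.clip(np.nan_to_num(rate_maps) / frame_rate, _EPS, 1.0 - _EPS)
    if emission == "bernoulli":
        return np.log(p), np.log1p(-p)
    if emission == "poisson":
        # P(active) = P(N >= 1) = 1 - exp(-mu) with mu = rate/frame_rate
        q = np.clip(1.0 - np.exp(-p), _EPS, 1.0 - _EPS)
        return np.log(q), np.log1p(-q)
    raise ValueError("emission must be 'bernoulli' or 'poisson'")


def decode_frames(
    activity: np.ndarray,
    rate_maps: np.ndarray,
    frame_rate: float,
    prior: np.ndarray | None = None,
    emission: str = "bernoulli",
    return_posterior: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Decode many frames at once.

    Parameters
    ----------
    activity : (n_frames, n_cells) boolean active-frame matrix.
    rate_maps : (n_cells, n_bins) Af/s training-session tuning curves.
    prior : optional (n_bins,) prior over position; uniform by default.

    Returns the 1-based maximum-a-posteriori bin per frame (ties -> lowest
    bin), and optionally the normalized posterior (n_frames × n_bins).
    """
    A = np.atleast_2d(np.asarray(activity)).astype(float)
    log_on, log_off = _log_emission(rate_maps, frame_rate, emission)
    ll = A @ log_on + (1.0 - A) @ log_off
    if prior is not None:
        prior = np.asarray(prior, float)
        if prior.shape[0] != rate_maps.shape[1] or np.any(prior < 0) or prior.sum() <= 0:
            raise ValueError("prior must be a non-negative vector over bins")
        with np.errstate(divide="ignore"):
            ll = ll + np.log(prior / prior.sum())
    pred = np.argmax(ll, axis=1) + 1
    if not return_posterior:
        return pred
    post = np.exp(ll - ll.max(axis=1, keepdims=True))
    post /= post.sum(axis=1, keepdims=True)
    return pred, post


def bayes_decode_frame(
    activity_vector: np.ndarray,
    rate_maps: np.ndarray,
    frame_rate: float,
    prior: np.ndarray | None = None,
    emission: str = "bernoulli",
) -> int:
    """Maximum-a-posteriori position bin (1-based) for one frame."""
    return int(
        decode_frames(
            np.asarray(activity_vector)[None, :], rate_maps, frame_rate, prior, emission
        )[0]
    )


def dai(p: float, g: float) -> float:
    """Decoding accuracy index: −log10(p) × sign(g) − 2 (NaN-propagating)."""
    if np.isnan(p):
        return float("nan")
    return float(-np.log10(p) * np.sign(g) - 2.0)


def accuracy_index(
    de: np.ndarray, de_shuffle: np.ndarray
) -> tuple[float, float, float]:
    """Shuffle-referenced accuracy for one bin's visits.

    Parameters
    ----------
    de : (n_frames,) decoding error per visit frame, cm.
    de_shuffle : (n_frames, n_shuffles) or (n_frames,) shuffled errors.

    Returns ``(G, wilcoxon_p, DAI)``: G is the median over frames of
    (per-frame median shuffled error − error); the Wilcoxon signed-rank test
    is applied to those per-frame differences; DAI applies the −log10(p) ×
    sign(G) − 2 transform.  With all-zero differences the test is undefined
    and p and DAI are NaN.
    """
    de = np.asarray(de, float)
    if de.size == 0:
        raise ValueError("need at least one visit to the bin")
    shuf = np.asarray(de_shuffle, float)
    shuf_med = np.median(shuf, axis=1) if shuf.ndim == 2 else shuf
    diffs = shuf_med - de
    g = float(np.median(diffs))
    if np.all(diffs == 0):
        return g, float("nan"), float("nan")
    p = float(stats.wilcoxon(diffs).pvalue)
    return g, p, dai(p, g)


def shuffle_decoding_error(
    activity: np.ndarray,
    rate_maps: np.ndarray,
    frame_rate: float,
    actual_cm: np.ndarray,
    n_shuffles: int = 2000,
    seed: int | np.random.Generator = 0,
    emission: str = "bernoulli",
    track_length: float = 250.0,
) -> np.ndarray:
    """Per-frame decoding-error distribution under cell-identity shuffles.

    Each shuffle draws one uniform permutation of cell identities against the
    rate maps (the identity permutation is not excluded) and decodes every
    frame.  Returns (n_frames, n_shuffles) absolute errors in cm.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = np.atleast_2d(np.asarray(activity)).astype(float)
    n_cells, n_bins = rate_maps.shape
    centers = bin_centers(n_bins, track_length)
    log_on, log_off = _log_emission(rate_maps, frame_rate, emission)
    out = np.empty((A.shape[0], n_shuffles))
    for s in range(n_shuffles):
        perm = rng.permutation(n_cells)
        ll = A[:, perm] @ log_on + (1.0 - A[:, perm]) @ log_off
        pred = np.argmax(ll, axis=1)
        out[:, s] = np.abs(actual_cm - centers[pred])
    return out


def _direction_frames(
    trace: PositionTrace, trials: list[BeelineTrial], direction: str
) -> np.ndarray:
    trs = [tr for tr in trials if tr.direction == direction]
    if not trs:
        return np.empty(0, dtype=int)
    return np.concatenate([tr.frames for tr in trs])


def decode_session_pair(
    curves_a: dict[str, np.ndarray],
    curves_b: dict[str, np.ndarray],
    rasters: tuple[np.ndarray, np.ndarray],
    traces: tuple[PositionTrace, PositionTrace],
    trials: tuple[list[BeelineTrial], list[BeelineTrial]],
    n_subsample: int = 100,
    n_shuffles: int = 2000,
    seed: int = 0,
    emission: str = "bernoulli",
    n_bins: int = N_BINS,
    cell_indices: dict[str, np.ndarray] | None = None,
) -> DecodingResult:
    """Cross-decode a session pair and summarize per-bin accuracy.

    Parameters
    ----------
    curves_a, curves_b : mapping direction -> (n_cells, n_bins) rate maps of
        the *recurring place cells* (same row identity in both sessions).
    rasters : the two sessions' boolean active matrices (cells × frames).
        ``cell_indices`` maps each direction to the raster row indices of
        that direction's curve rows; by default curve row i is raster row i.
    traces, trials : the two sessions' position traces and beeline trials.

    For each running direction and each decode direction (a→b and b→a), cell
    counts are equalized across directions by random subsampling to
    min(n_LR, n_RL) cells (``n_subsample`` iterations); the per-frame
    decoding error is the absolute difference between actual and predicted
    bin centers, and the per-bin error is the median over all visits.  The
    per-bin shuffle reference uses ``n_shuffles`` cell-identity permutations.
    Per-bin results are averaged over running and decode directions.
    """
    rng = np.random.default_rng(seed)
    n_lr = curves_a["LR"].shape[0]
    n_rl = curves_a["RL"].shape[0]
    if min(n_lr, n_rl) == 0:
        raise ValueError("no recurring place cells in one of the directions")
    n_eq = min(n_lr, n_rl)

    track_length = traces[0].track_length
    centers = bin_centers(n_bins, track_length)
    de_acc = np.full((4, n_bins), np.nan)
    g_acc = np.full((4, n_bins), np.nan)
    p_acc = np.full((4, n_bins), np.nan)
    dai_acc = np.full((4, n_bins), np.nan)
    row = 0
    for direction in ("LR", "RL"):
        for train_idx, test_idx in ((0, 1), (1, 0)):
            train_curves = (curves_a if train_idx == 0 else curves_b)[direction]
            test_active = rasters[test_idx]
            trace = traces[test_idx]
            frames = _direction_frames(trace, trials[test_idx], direction)
            if frames.size == 0:
                row += 1
                continue
            x_act = trace.x[frames]
            act_bins = np.asarray(
                bin_index(x_act, n_bins=n_bins, track_length=track_length)
            ) - 1
            n_dir = train_curves.shape[0]
            rows = (
                np.asarray(cell_indices[direction])
                if cell_indices is not None
                else np.arange(n_dir)
            )
            # average decoding error over cell-count-equalizing subsamples
            err = np.zeros(frames.size)
            for _ in range(n_subsample):
                sub = rng.choice(n_dir, size=n_eq, replace=False)
                pred = decode_frames(
                    test_active[np.ix_(rows[sub], frames)].T,
                    train_curves[sub],
                    trace.frame_rate,
                    emission=emission,
                )
                err += np.abs(x_act - centers[pred - 1])
            err /= n_subsample
            sub = rng.choice(n_dir, size=n_eq, replace=False)
            shuf = shuffle_decoding_error(
                test_active[np.ix_(rows[sub], frames)].T,
                train_curves[sub],
                trace.frame_rate,
                x_act,
                n_shuffles=n_shuffles,
                seed=rng,
                emission=emission,
                track_length=track_length,
            )
            for b in range(n_bins):
                sel = act_bins == b
                if not np.any(sel):
                    continue
                g, p, d = accuracy_index(err[sel], shuf[sel])
                de_acc[row, b] = np.median(err[sel])
                g_acc[row, b] = g
                p_acc[row, b] = p
                dai_acc[row, b] = d
            row += 1

    # each (running direction × decode direction) is one observation per bin
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins stay NaN
        de = np.nanmean(de_acc, axis=0)
        g = np.nanmean(g_acc, axis=0)
        p = np.nanmean(p_acc, axis=0)
        dai_vals = np.nanmean(dai_acc, axis=0)
    return DecodingResult(
        de_cm=de, g_cm=g, wilcoxon_p=p, dai=dai_vals, n_cells_per_direction=n_eq
    )
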