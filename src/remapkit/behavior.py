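"""Beeline-trial extraction, spatial binning, and behavioral subsampling.

All analyses operate on *beeline trials*: continuous end-to-end traversals of
the linearized short path during which 1-D position changes monotonically in
one direction (up to tracking jitter).  The routines here extract those trials
from a position trace, assign spatial bins, evaluate the behavioral criteria
(reward rate, 48 h retention ratio), and implement the speed-matched trial
subsampling procedures used to equate behavior across sessions and conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PositionTrace",
    "BeelineTrial",
    "RetentionScore",
    "detect_beeline_trials",
    "bin_index",
    "bin_centers",
    "short_path_criterion",
    "retention_ratio",
    "omit_fastest_fraction",
    "omit_last_fraction",
    "equalize_by_speed",
    "percent_ratio",
    "round_half_away",
    "temporal_downsample",
    "N_BINS",
    "BIN_WIDTH_CM",
]

N_BINS = 23
#: nominal bin width on the 250 cm short path (23 bins)
BIN_WIDTH_CM = 10.8


@dataclass
class PositionTrace:
    """Timestamped 1-D position along the linearized track.

    Parameters
    ----------
    t : array of float
        Frame timestamps in seconds, strictly increasing.
    x : array of float
        Linearized position in cm, within ``[0, track_length]``.
    frame_rate : float
        Nominal imaging frame rate in Hz.
    track_length : float
        Length of the instrumented path in cm.
    """

    t: np.ndarray
    x: np.ndarray
    frame_rate: float
    track_length: float = 250.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t.shape != self.x.shape:
            raise ValueError("t and x must have equal length")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class BeelineTrial:
    """One monotone end-to-end traversal of the short path."""

    start_frame: int
    end_frame: int  # inclusive
    direction: str  # "LR" or "RL"
    mean_speed: float  # cm/s, span traversed / duration

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")
        if self.direction not in ("LR", "RL"):
            raise ValueError("direction must be 'LR' or 'RL'")

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.start_frame, self.end_frame + 1)


@dataclass(frozen=True)
class RetentionScore:
    """48 h retention of short-path avoidance, A = n_post / n_pre.

    Lower A means better retention (fewer short-path rewards after training).
    The classification cutoffs are condition-specific: a drug-free rat *failed*
    retention if A > 0.6, while a scopolamine rat *retained* if A < 0.31.
    """

    n_post: float
    n_pre: float
    A: float
    condition: str
    label: str


def detect_beeline_trials(
    trace: PositionTrace,
    end_zones: tuple[float, float] = (15.0, 235.0),
    jitter_tol: float = 1.0,
) -> list[BeelineTrial]:
    """Extract beeline trials from a position trace.

    A trial runs from the last frame inside one end zone to the first frame
    inside the other, with every intermediate frame strictly between the
    zones and per-frame displacement never opposing the trial direction by
    more than ``jitter_tol`` cm.  Direction is ``LR`` iff x increases.

    Parameters
    ----------
    end_zones : (float, float)
        Inner boundaries (cm) of the left and right end zones; positions
        ``x <= end_zones[0]`` are "left", ``x >= end_zones[1]`` are "right".
    jitter_tol : float
        Tracking-jitter tolerance in cm; "monotone" means no single-frame
        displacement against the travel direction larger than this.
    """
    lo, hi = end_zones
    if not (0.0 <= lo < hi <= trace.track_length):
        raise ValueError("end_zones must lie within the track and be ordered")
    x = trace.x
    if x.size == 0:
        return []

    zone = np.zeros(x.size, dtype=np.int8)
    zone[x <= lo] = -1
    zone[x >= hi] = 1

    trials: list[BeelineTrial] = []
    i = 0
    n = x.size
    while i < n:
        if zone[i] == 0:
            i += 1
            continue
        side = zone[i]
        # last frame of this dwell in the end zone
        j = i
        while j + 1 < n and zone[j + 1] == side:
            j += 1
        # scan forward through mid-track frames to the next zone frame
        k = j + 1
        while k < n and zone[k] == 0:
            k += 1
        if k < n and zone[k] == -side:
            dx = np.diff(x[j : k + 1])
            direction = "LR" if side == -1 else "RL"
            ok = np.all(dx >= -jitter_tol) if direction == "LR" else np.all(dx <= jitter_tol)
            if ok:
                span = abs(x[k] - x[j])
                dur = trace.t[k] - trace.t[j]
                trials.append(BeelineTrial(int(j), int(k), direction, float(span / dur)))
        i = k
    return trials


def bin_index(
    x: float | np.ndarray,
    n_bins: int = N_BINS,
    track_length: float = 250.0,
) -> int | np.ndarray:
    """Map position(s) in cm to a 1-based spatial bin in ``1..n_bins``.

    Bins partition ``[0, track_length]`` into ``n_bins`` equal intervals
    (nominally 10.8 cm on the 250 cm path), half-open ``[lo, hi)`` with the
    final bin closed, indexed from the LR start of the track.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(arr > track_length):
        raise ValueError("position out of track range")
    width = track_length / n_bins
    idx = np.minimum(np.floor(arr / width).astype(int), n_bins - 1) + 1
    if np.isscalar(x) or arr.ndim == 0:
        return int(idx)
    return idx


def bin_centers(n_bins: int = N_BINS, track_length: float = 250.0) -> np.ndarray:
    """Centers (cm) of the spatial bins, index 0 = bin 1."""
    width = track_length / n_bins
    return (np.arange(n_bins) + 0.5) * width


def short_path_criterion(short_rewards_per_min: float, n_short: int, n_long: int) -> bool:
    """Criterion for short-path preference: ≥2 rewards/min on the short path
    and at least twice as many short- as long-path rewards."""
    if n_short < 0 or n_long < 0:
        raise ValueError("reward counts must be non-negative")
    return short_rewards_per_min >= 2.0 and n_short >= 2 * n_long


def retention_ratio(n_post: float, n_pre: float, condition: str = "drug_free") -> RetentionScore:
    """48 h retention ratio A = n_post/n_pre with condition-specific label.

    Drug-free rats are labeled ``"failed retention"`` when A > 0.6 (else
    ``"retained"``); scopolamine rats are labeled ``"retained"`` when A < 0.31
    (else ``"failed retention"``).
    """
    if n_pre <= 0:
        raise ZeroDivisionError("n_pre must be positive; retention ratio undefined")
    if condition not in ("drug_free", "scopolamine"):
        raise ValueError("condition must be 'drug_free' or 'scopolamine'")
    A = n_post / n_pre
    if condition == "drug_free":
        label = "failed retention" if A > 0.6 else "retained"
    else:
        label = "retained" if A < 0.31 else "failed retention"
    return RetentionScore(n_post=n_post, n_pre=n_pre, A=A, condition=condition, label=label)


def round_half_away(v: float) -> int:
    """Round to nearest integer, halves away from zero (so 3.5 → 4, -3.5 → -4)."""
    return int(math.floor(v + 0.5)) if v >= 0 else -int(math.floor(-v + 0.5))


def percent_ratio(numer: float, denom: float) -> int:
    """Ratio of two counts expressed as a whole percentage.

    Used for the trial-count bookkeeping of the subsampling procedures
    (e.g. mean training-trial counts across conditions).
    """
    if denom == 0:
        raise ZeroDivisionError("denominator must be nonzero")
    return round_half_away(100.0 * numer / denom)


def _split_by_direction(trials: list[BeelineTrial]) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {"LR": [], "RL": []}
    for i, tr in enumerate(trials):
        out[tr.direction].append(i)
    return out


def omit_fastest_fraction(trials: list[BeelineTrial], fraction: float) -> list[BeelineTrial]:
    """Remove the fastest ``round(fraction * n)`` trials per running direction.

    Speed ranking uses mean trial speed; ties are broken by removing the trial
    with the lower original index first.  Survivors keep their original order.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    drop: set[int] = set()
    for _, idxs in _split_by_direction(trials).items():
        n_remove = round_half_away(fraction * len(idxs))
        # fastest first; ties -> lower original index first
        ranked = sorted(idxs, key=lambda i: (-trials[i].mean_speed, i))
        drop.update(ranked[:n_remove])
    return [tr for i, tr in enumerate(trials) if i not in drop]


def omit_last_fraction(trials: list[BeelineTrial], fraction: float) -> list[BeelineTrial]:
    """Remove the chronologically last ``round(fraction * n)`` trials per direction."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    drop: set[int] = set()
    for _, idxs in _split_by_direction(trials).items():
        n_remove = round_half_away(fraction * len(idxs))
        if n_remove:
            drop.update(idxs[-n_remove:])
    return [tr for i, tr in enumerate(trials) if i not in drop]


def equalize_by_speed(
    trials_a: list[BeelineTrial], trials_b: list[BeelineTrial]
) -> tuple[list[BeelineTrial], list[BeelineTrial]]:
    """Equalize per-direction trial counts between two sessions.

    In each direction the larger set loses its ``|nA - nB|`` fastest trials,
    which both matches the counts and shrinks the mean-speed difference
    (fast trials are preferentially dropped from the better-sampled session).
    """
    by_a, by_b = _split_by_direction(trials_a), _split_by_direction(trials_b)
    drop_a: set[int] = set()
    drop_b: set[int] = set()
    for d in ("LR", "RL"):
        na, nb = len(by_a[d]), len(by_b[d])
        if na > nb:
            ranked = sorted(by_a[d], key=lambda i: (-trials_a[i].mean_speed, i))
            drop_a.update(ranked[: na - nb])
        elif nb > na:
            ranked = sorted(by_b[d], key=lambda i: (-trials_b[i].mean_speed, i))
            drop_b.update(ranked[: nb - na])
    return (
        [tr for i, tr in enumerate(trials_a) if i not in drop_a],
        [tr for i, tr in enumerate(trials_b) if i not in drop_b],
    )


def temporal_downsample(trace: PositionTrace, factor: int = 2) -> PositionTrace:
    """Keep every ``factor``-th frame, dividing the effective frame rate.

    Mirrors the acquisition-side temporal downsampling (e.g. 22 Hz video kept
    at every other frame gives an effective ~11 Hz sample rate).
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    return PositionTrace(
        t=trace.t[::factor],
        x=trace.x[::factor],
        frame_rate=trace.frame_rate / factor,
        track_length=trace.track_length,
    )
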