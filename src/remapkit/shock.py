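"""Shock-zone entries and Poisson-based shock-response classification.

A cell is shock-responsive when its count of active frames in a 2 s window
after entry into the electrified shock zone exceeds the p < 0.01 confidence
limit of a Poisson fit to its baseline window counts from earlier,
non-electrified visits in the same running direction.  Only the first two
electrified entries are considered, so detection power does not depend on
how many shocks an animal happened to receive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .behavior import PositionTrace
from .tuning import TuningCurve

__all__ = [
    "ZoneEntry",
    "ShockResponseLabel",
    "detect_zone_entries",
    "classify_shock_response",
    "poisson_threshold",
    "approach_departure_side",
    "reflect_curve",
    "population_shock_average",
]


@dataclass(frozen=True)
class ZoneEntry:
    """One entry into the shock zone."""

    entry_frame: int
    direction: str  # LR | RL
    electrified: bool
    window: tuple[int, int]  # [start, stop) frame span, ceil(2 s * fps) frames

    @property
    def n_frames(self) -> int:
        return self.window[1] - self.window[0]


@dataclass(frozen=True)
class ShockResponseLabel:
    responsive: bool
    first_significant_entry: int | None  # 1 or 2, None if not responsive
    baseline_lambda: float  # expected active frames per full window
    threshold_k: int  # smallest count significant at p < alpha
    trigger_counts: tuple[int, ...]  # active-frame counts on tested entries


def detect_zone_entries(
    trace: PositionTrace,
    zone_bounds: tuple[float, float],
    shock_on_time: float | None,
    window_s: float = 2.0,
) -> list[ZoneEntry]:
    """Find shock-zone entries and tag each with direction and shock state.

    An entry is the first frame inside the zone after at least one frame
    outside; it is electrified iff its timestamp is at or after
    ``shock_on_time``.  Direction comes from the sign of the displacement at
    the entry frame.  Each entry's analysis window spans ``ceil(window_s *
    frame_rate)`` frames from the entry frame, truncated at session end.
    """
    lo, hi = zone_bounds
    if not (0.0 <= lo < hi <= trace.track_length):
        raise ValueError("zone_bounds must lie within the track")
    x = trace.x
    if x.size < 2:
        return []
    inside = (x >= lo) & (x <= hi)
    entry_frames = np.flatnonzero(inside[1:] & ~inside[:-1]) + 1
    win = int(math.ceil(window_s * trace.frame_rate))
    entries = []
    for f in entry_frames:
        direction = "LR" if x[f] - x[f - 1] > 0 else "RL"
        electrified = shock_on_time is not None and trace.t[f] >= shock_on_time
        stop = min(f + win, trace.n_frames)
        entries.append(ZoneEntry(int(f), direction, bool(electrified), (int(f), int(stop))))
    return entries


def poisson_threshold(lam: float, alpha: float = 0.01) -> int:
    """Smallest integer k with P(X >= k | Poisson(lam)) < alpha."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    # want the smallest k with P(X >= k) = sf(k - 1) < alpha; start from the
    # scipy inverse-survival estimate and correct in both directions
    k = max(int(stats.poisson.isf(alpha, lam)), 0)
    while stats.poisson.sf(k - 1, lam) >= alpha:
        k += 1
    while k > 0 and stats.poisson.sf(k - 2, lam) < alpha:
        k -= 1
    return k


def classify_shock_response(
    cell_active: np.ndarray,
    entries: list[ZoneEntry],
    alpha: float = 0.01,
    max_entries: int = 2,
) -> ShockResponseLabel:
    """Poisson test of a cell's activity after electrified shock-zone entries.

    ``cell_active`` is the cell's boolean active-frame vector.  For each of
    the first ``max_entries`` electrified entries, the baseline is the mean
    active-frame count over windows of same-direction, non-electrified
    entries (λ, floored at one active frame per total baseline frames to
    avoid a degenerate always-significant test at λ = 0); the entry is
    significant when its window count reaches the smallest k with
    P(X ≥ k | Poisson(λ)) < alpha.  Windows truncated at session end use λ
    scaled to their observed length.
    """
    cell_active = np.asarray(cell_active).astype(bool)
    electrified = [e for e in entries if e.electrified]
    if not electrified:
        raise ValueError("no shock entries")
    tested = electrified[:max_entries]

    full_win = max(e.n_frames for e in entries)
    lam_by_dir: dict[str, float] = {}
    for d in ("LR", "RL"):
        base = [e for e in entries if not e.electrified and e.direction == d]
        if not base:
            continue
        counts = sum(int(cell_active[e.window[0] : e.window[1]].sum()) for e in base)
        total = sum(e.n_frames for e in base)
        # per-frame baseline rate, floored at 1 active frame per total
        # baseline frames so a zero-rate baseline is not always-significant
        lam_by_dir[d] = max(counts, 1) / total * full_win

    first_sig: int | None = None
    trigger_counts: list[int] = []
    lam_used = np.nan
    k_used = 0
    for i, e in enumerate(tested, start=1):
        if e.direction not in lam_by_dir:
            raise ValueError(f"no baseline entries in direction {e.direction}")
        lam_full = lam_by_dir[e.direction]
        lam = lam_full * e.n_frames / full_win  # scale for truncated windows
        count = int(cell_active[e.window[0] : e.window[1]].sum())
        k = poisson_threshold(lam, alpha)
        trigger_counts.append(count)
        if np.isnan(lam_used):
            lam_used, k_used = lam_full, k
        if count >= k and first_sig is None:
            first_sig = i
    return ShockResponseLabel(
        responsive=first_sig is not None,
        first_significant_entry=first_sig,
        baseline_lambda=float(lam_used),
        threshold_k=int(k_used),
        trigger_counts=tuple(trigger_counts),
    )


def reflect_curve(rates: np.ndarray) -> np.ndarray:
    """Reflect a 23-bin curve across the middle bin (bin b -> 24 - b)."""
    return np.asarray(rates)[::-1].copy()


def approach_departure_side(curve: TuningCurve | np.ndarray, direction: str) -> str:
    """Classify a field peak as approach- or departure-side of the shock zone.

    RL curves are reflected across the middle bin so that for both running
    directions bins 1–12 lie on the approach side of the center.  A peak in
    bins 1–12 is "approach", in 14–23 "departure"; a center peak (bin 13) is
    resolved by comparing the area under bins 1–12 versus 14–23.
    """
    rates = curve.rates if isinstance(curve, TuningCurve) else np.asarray(curve, float)
    if direction == "RL":
        rates = reflect_curve(rates)
    elif direction != "LR":
        raise ValueError("direction must be 'LR' or 'RL'")
    filled = np.where(np.isnan(rates), -np.inf, rates)
    peak = int(np.argmax(filled)) + 1  # 1-based
    if peak < 13:
        return "approach"
    if peak > 13:
        return "departure"
    area = np.nansum(rates[:12]), np.nansum(rates[13:])
    return "approach" if area[0] > area[1] else "departure"


def population_shock_average(
    active: np.ndarray,
    entries: list[ZoneEntry],
    labels: list[ShockResponseLabel],
    frame_rate: float,
    pre_s: float = 2.0,
    post_s: float = 2.0,
) -> np.ndarray:
    """Entry-locked population-average activity trace (Af/s per time point).

    Each cell contributes exactly one window: responders contribute their
    first significant electrified entry, non-responders their first
    electrified entry.  The returned trace spans ``pre_s`` seconds before to
    ``post_s`` seconds after zone entry; out-of-session samples are NaN-
    excluded from the mean.
    """
    active = np.asarray(active).astype(bool)
    if active.shape[0] != len(labels) or active.shape[0] == 0:
        raise ValueError("need one label per cell and at least one cell")
    electrified = [e for e in entries if e.electrified]
    if not electrified:
        raise ValueError("no shock entries")
    n_pre = int(math.ceil(pre_s * frame_rate))
    n_post = int(math.ceil(post_s * frame_rate))
    n_frames = active.shape[1]
    traces = np.full((active.shape[0], n_pre + n_post), np.nan)
    for c, lab in enumerate(labels):
        if lab.responsive:
            entry = electrified[lab.first_significant_entry - 1]
        else:
            entry = electrified[0]
        f = entry.entry_frame
        lo, hi = f - n_pre, f + n_post
        src_lo, src_hi = max(lo, 0), min(hi, n_frames)
        traces[c, src_lo - lo : src_hi - lo] = active[c, src_lo:src_hi]
    return np.nanmean(traces, axis=0) * frame_rate
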