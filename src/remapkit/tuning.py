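"""Direction-specific spatial tuning curves and place-cell classification.

Activity is measured in *active frames per second* (Af/s): the mean number of
imaging frames per second in which a cell emitted at least one deconvolved
spike.  A tuning curve assigns one Af/s rate to each of 23 spatial bins for
one running direction.  A cell is classified as a place cell by split-half
reliability: over repeated random splits of the direction's beeline trials,
the Pearson correlation between half-session curves must have a median
p-value below 0.01, the cell must average ≥1 inferred spike per trial, and it
must not fire above 70% of its peak rate over more than half the track
(an interneuron exclusion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .behavior import BIN_WIDTH_CM, N_BINS, BeelineTrial, PositionTrace, bin_index

__all__ = [
    "ActivityRaster",
    "TuningCurve",
    "TuningCurveSet",
    "TuningProperties",
    "PlaceCellLabel",
    "compute_tuning_curve",
    "compute_tuning_curves",
    "tuning_properties",
    "spatial_information",
    "classify_place_cell",
    "classify_place_cells",
]


@dataclass
class ActivityRaster:
    """Deconvolved-spike raster: cells × frames non-negative counts."""

    spikes: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        if self.spikes.ndim != 2:
            raise ValueError("spikes must be a 2-D cells × frames array")
        if np.any(self.spikes < 0):
            raise ValueError("spike counts must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def active(self) -> np.ndarray:
        """Boolean cells × frames indicator of ≥1 inferred spike."""
        return self.spikes >= 1

    @property
    def n_cells(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_frames(self) -> int:
        return self.spikes.shape[1]


@dataclass
class TuningCurve:
    """Af/s rate per spatial bin for one cell in one running direction.

    ``rates`` is NaN where the bin was never occupied.
    """

    rates: np.ndarray  # (n_bins,)
    occupancy_s: np.ndarray  # (n_bins,) seconds
    direction: str
    n_trials: int


@dataclass
class TuningCurveSet:
    """Tuning curves for all cells at once (cells × bins), shared occupancy."""

    rates: np.ndarray  # (n_cells, n_bins), NaN where unoccupied
    occupancy_s: np.ndarray  # (n_bins,)
    direction: str
    n_trials: int

    def __getitem__(self, cell: int) -> TuningCurve:
        return TuningCurve(self.rates[cell], self.occupancy_s, self.direction, self.n_trials)

    @property
    def n_cells(self) -> int:
        return self.rates.shape[0]


@dataclass(frozen=True)
class TuningProperties:
    peak_rate: float
    out_of_field_rate: float
    width_cm: float
    spatial_info: float


@dataclass(frozen=True)
class PlaceCellLabel:
    """Outcome of the split-half place-cell classifier for one cell.

    ``is_place_LR``/``is_place_RL`` are None where the direction had too few
    trials to be classifiable (distinct from False).
    """

    cell_id: int
    is_place_LR: bool | None
    is_place_RL: bool | None
    median_p_LR: float
    median_p_RL: float
    spikes_per_trial: float
    interneuron_flag: bool

    @property
    def is_place_cell(self) -> bool:
        return bool(self.is_place_LR) or bool(self.is_place_RL)


def _trial_frame_bins(
    trace: PositionTrace, trials: list[BeelineTrial], n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated frame indices over trials and their 0-based bins."""
    if not trials:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    frames = np.concatenate([tr.frames for tr in trials])
    bins = np.asarray(bin_index(trace.x[frames], n_bins=n_bins, track_length=trace.track_length)) - 1
    return frames, bins


def trial_bin_stats(
    raster: ActivityRaster,
    trace: PositionTrace,
    trials: list[BeelineTrial],
    n_bins: int = N_BINS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial spatial summaries used by curves and the classifier.

    Returns
    -------
    counts : (n_cells, n_trials, n_bins) array
        Active-frame counts per cell, trial, and bin.
    occ : (n_trials, n_bins) array
        Occupied frame counts per trial and bin.
    """
    n_cells = raster.n_cells
    counts = np.zeros((n_cells, len(trials), n_bins))
    occ = np.zeros((len(trials), n_bins))
    active = raster.active
    for k, tr in enumerate(trials):
        frames = tr.frames
        bins = (
            np.asarray(bin_index(trace.x[frames], n_bins=n_bins, track_length=trace.track_length))
            - 1
        )
        np.add.at(occ[k], bins, 1.0)
        # accumulate active frames per bin for all cells at once
        sub = active[:, frames].astype(float)
        for b in range(n_bins):
            sel = bins == b
            if np.any(sel):
                counts[:, k, b] = sub[:, sel].sum(axis=1)
    return counts, occ


def compute_tuning_curves(
    raster: ActivityRaster,
    trace: PositionTrace,
    trials: list[BeelineTrial],
    direction: str,
    n_bins: int = N_BINS,
) -> TuningCurveSet:
    """Af/s tuning curves for all cells from one direction's beeline trials.

    rate[i] = (active frames in bin i across trials) / occupancy_s[i]; bins
    with zero occupancy are NaN.
    """
    trials = [tr for tr in trials if tr.direction == direction]
    if not trials:
        raise ValueError(f"no trials for direction {direction!r}")
    counts, occ = trial_bin_stats(raster, trace, trials, n_bins)
    occ_s = occ.sum(axis=0) / raster.frame_rate
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = counts.sum(axis=1) / occ_s[None, :]
    rates[:, occ_s == 0] = np.nan
    return TuningCurveSet(rates=rates, occupancy_s=occ_s, direction=direction, n_trials=len(trials))


def compute_tuning_curve(
    raster: ActivityRaster,
    trace: PositionTrace,
    trials: list[BeelineTrial],
    direction: str,
    cell: int,
    n_bins: int = N_BINS,
) -> TuningCurve:
    """Single-cell convenience wrapper around :func:`compute_tuning_curves`."""
    return compute_tuning_curves(raster, trace, trials, direction, n_bins)[cell]


def tuning_properties(curve: TuningCurve, bin_width_cm: float = BIN_WIDTH_CM) -> TuningProperties:
    """Peak rate, out-of-field rate, tuning width, and spatial information.

    * peak = max Af/s over occupied bins;
    * tuning width = bin width × N50, with N50 the number of bins above 50%
      of peak;
    * out-of-field rate = mean over bins strictly below 50% of peak (0 when
      that set is empty, e.g. for a flat curve).
    """
    valid = ~np.isnan(curve.rates)
    if not np.any(valid):
        raise ValueError("tuning curve has no occupied bins")
    r = curve.rates[valid]
    peak = float(np.max(r))
    half = 0.5 * peak
    n50 = int(np.sum(r > half))
    below = r[r < half]
    oof = float(np.mean(below)) if below.size else 0.0
    return TuningProperties(
        peak_rate=peak,
        out_of_field_rate=oof,
        width_cm=bin_width_cm * n50,
        spatial_info=spatial_information(curve),
    )


def spatial_information(
    curve: TuningCurve,
    skaggs: bool = False,
    renormalize_over_active: bool = True,
) -> float:
    """Spatial mutual information of a tuning curve, in bits per active frame.

    Let B be the set of occupied bins with non-zero Af/s rate, r_i the rate in
    bin i, p_i the occupancy probability, and r̄ = Σ_{i∈B} p_i r_i the
    occupancy-weighted mean rate over B.  The default output is

        −r̄ log2 r̄ + Σ_{i∈B} r_i p_i log2 r_i

    which equals r̄ × Skaggs information; ``skaggs=True`` returns the
    per-active-frame Skaggs form Σ p_i (r_i/r̄) log2(r_i/r̄) instead.  By
    default p_i is renormalized over B; ``renormalize_over_active=False``
    normalizes over all occupied bins.  Empty B yields 0.
    """
    valid = ~np.isnan(curve.rates)
    rates = curve.rates[valid]
    occ = curve.occupancy_s[valid]
    active = rates > 0
    if not np.any(active):
        return 0.0
    r = rates[active]
    if renormalize_over_active:
        p = occ[active] / occ[active].sum()
    else:
        p = occ[active] / occ.sum()
    rbar = float(np.sum(p * r))
    if skaggs:
        return float(np.sum(p * (r / rbar) * np.log2(r / rbar)))
    return float(-rbar * np.log2(rbar) + np.sum(r * p * np.log2(r)))


def _rowwise_pearson_p(x: np.ndarray, y: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Two-sided Pearson p-values for each row pair, over mutually valid bins.

    ``x``, ``y``: (n_rows, n_bins); ``valid``: boolean mask of bins defined in
    both rows.  Rows with <3 valid bins or zero variance get p = 1.
    """
    m = valid.sum(axis=1)
    safe_m = np.maximum(m, 1)
    xm = np.where(valid, x, 0.0)
    ym = np.where(valid, y, 0.0)
    mx = xm.sum(axis=1) / safe_m
    my = ym.sum(axis=1) / safe_m
    dx = np.where(valid, x - mx[:, None], 0.0)
    dy = np.where(valid, y - my[:, None], 0.0)
    cov = (dx * dy).sum(axis=1)
    vx = (dx * dx).sum(axis=1)
    vy = (dy * dy).sum(axis=1)
    p = np.ones(x.shape[0])
    ok = (m >= 3) & (vx > 0) & (vy > 0)
    r = np.zeros_like(cov)
    r[ok] = cov[ok] / np.sqrt(vx[ok] * vy[ok])
    r = np.clip(r, -1.0, 1.0)
    df = m - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(df / (1.0 - r**2))
    exact = ok & (np.abs(r) >= 1.0)
    p[exact] = 0.0
    rest = ok & ~exact
    p[rest] = 2.0 * stats.t.sf(np.abs(tstat[rest]), df[rest])
    return p


def _split_half_median_p(
    counts: np.ndarray,  # (n_trials, n_bins) active counts for one cell
    occ: np.ndarray,  # (n_trials, n_bins) frame counts
    n_splits: int,
    rng: np.random.Generator,
) -> float:
    n_trials = counts.shape[0]
    half = (n_trials + 1) // 2  # ceil
    perms = np.argsort(rng.random((n_splits, n_trials)), axis=1)
    sel = np.zeros((n_splits, n_trials), dtype=bool)
    np.put_along_axis(sel, perms[:, :half], True, axis=1)
    c1 = sel @ counts
    c2 = (~sel) @ counts
    o1 = sel @ occ
    o2 = (~sel) @ occ
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = c1 / o1
        r2 = c2 / o2
    valid = (o1 > 0) & (o2 > 0)
    p = _rowwise_pearson_p(np.nan_to_num(r1), np.nan_to_num(r2), valid)
    return float(np.median(p))


def classify_place_cells(
    raster: ActivityRaster,
    trace: PositionTrace,
    trials: list[BeelineTrial],
    seed: int = 0,
    n_splits: int = 200,
    alpha: float = 0.01,
    min_trials: int = 4,
    n_bins: int = N_BINS,
    cell_ids: list[int] | None = None,
) -> list[PlaceCellLabel]:
    """Split-half place-cell classification for every cell in the raster.

    Per direction with at least ``min_trials`` trials: the direction's trials
    are randomly split in half ``n_splits`` times; each split yields a Pearson
    correlation (over mutually occupied bins) between the two half-curves and
    its two-sided p-value; the direction passes if the median p < ``alpha``.
    A cell is a place cell if either direction passes, it averages ≥1 inferred
    spike per beeline trial, and the interneuron rule does not fire (rate
    >70% of peak in more than 50% of the track, i.e. ≥12 of 23 bins, in a
    direction-specific curve).

    Each cell's split sequence is seeded from ``(seed, cell_id)`` so labels do
    not depend on which other cells are present.
    """
    by_dir = {
        d: [tr for tr in trials if tr.direction == d] for d in ("LR", "RL")
    }
    stats_by_dir: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    curves_by_dir: dict[str, TuningCurveSet] = {}
    for d, trs in by_dir.items():
        if trs:
            stats_by_dir[d] = trial_bin_stats(raster, trace, trs, n_bins)
            curves_by_dir[d] = compute_tuning_curves(raster, trace, trs, d, n_bins)

    # average inferred spikes per beeline trial, over all trials both directions
    n_trials_total = len(trials)
    all_frames = (
        np.concatenate([tr.frames for tr in trials]) if trials else np.empty(0, dtype=int)
    )
    total_spikes = raster.spikes[:, all_frames].sum(axis=1) if all_frames.size else np.zeros(
        raster.n_cells
    )
    spikes_per_trial = total_spikes / max(n_trials_total, 1)

    if cell_ids is None:
        cell_ids = list(range(raster.n_cells))
    if len(cell_ids) != raster.n_cells:
        raise ValueError("cell_ids must match the raster's cell count")

    labels: list[PlaceCellLabel] = []
    for c in range(raster.n_cells):
        rng = np.random.default_rng([seed, cell_ids[c]])
        med_p: dict[str, float] = {"LR": np.nan, "RL": np.nan}
        passes: dict[str, bool | None] = {"LR": None, "RL": None}
        interneuron = False
        for d in ("LR", "RL"):
            trs = by_dir[d]
            if d in curves_by_dir:
                r = curves_by_dir[d].rates[c]
                rr = r[~np.isnan(r)]
                if rr.size and np.max(rr) > 0:
                    if np.sum(rr > 0.7 * np.max(rr)) >= (n_bins // 2 + 1):
                        interneuron = True
            if len(trs) < min_trials:
                continue  # not classifiable in this direction
            counts, occ = stats_by_dir[d]
            med_p[d] = _split_half_median_p(counts[c], occ, n_splits, rng)
            passes[d] = med_p[d] < alpha
        ok_activity = spikes_per_trial[c] >= 1.0 and not interneuron
        labels.append(
            PlaceCellLabel(
                cell_id=cell_ids[c],
                is_place_LR=None if passes["LR"] is None else (passes["LR"] and ok_activity),
                is_place_RL=None if passes["RL"] is None else (passes["RL"] and ok_activity),
                median_p_LR=med_p["LR"],
                median_p_RL=med_p["RL"],
                spikes_per_trial=float(spikes_per_trial[c]),
                interneuron_flag=interneuron,
            )
        )
    return labels


def classify_place_cell(
    raster: ActivityRaster,
    trace: PositionTrace,
    trials: list[BeelineTrial],
    cell: int,
    seed: int = 0,
    n_splits: int = 200,
    alpha: float = 0.01,
    min_trials: int = 4,
    n_bins: int = N_BINS,
) -> PlaceCellLabel:
    """Classify a single cell; see :func:`classify_place_cells`.

    The split RNG derives from ``(seed, cell)``, so the label is identical to
    the one produced for this cell by a full-population run.
    """
    sub = ActivityRaster(raster.spikes[[cell]], raster.frame_rate)
    return classify_place_cells(
        sub, trace, trials, seed=seed, n_splits=n_splits, alpha=alpha,
        min_trials=min_trials, n_bins=n_bins, cell_ids=[cell],
    )[0]
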