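"""Population-level remapping statistics across session pairs.

Recurring place fields are stacked into co-sorted tuning-curve heatmaps; the
column (population) vectors of a session pair's heatmaps yield a 23×23
Pearson correlation matrix, from which a *stability score* S is computed:
the median, pooled over both running directions, of peri-diagonal ρ values
minus the direction's mean off-diagonal ρ.  High S indicates a stable
population code; S near zero indicates remapping.  A circular-shift shuffle
provides the chance reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import BeelineTrial
from .tuning import ActivityRaster, TuningCurveSet

__all__ = [
    "CellRegistry",
    "Heatmap",
    "PVCorrMatrix",
    "StabilityScore",
    "ZONE_TEMPLATES",
    "recurrence_ratio",
    "build_heatmap_pair",
    "pv_correlation",
    "stability_score",
    "circular_shift_shuffle",
    "field_peak_distribution",
]

#: track-zone templates (1-based column bins): left safe zone, center
#: (contains the 50 cm shock zone centered on bin 12), right safe zone
ZONE_TEMPLATES: dict[str, tuple[int, ...]] = {
    "full": tuple(range(1, 24)),
    "L": tuple(range(1, 9)),
    "C": tuple(range(9, 16)),
    "R": tuple(range(16, 24)),
}


class CellRegistry:
    """Cross-session cell-identity map.

    Wraps a table with rows = global cell IDs and one column per session;
    entries are within-session cell indices, or -1 where the cell was absent.
    """

    ABSENT = -1

    def __init__(self, table: pd.DataFrame):
        self.table = table.astype(int)
        for col in self.table.columns:
            vals = self.table[col]
            present = vals[vals != self.ABSENT]
            if present.duplicated().any():
                raise ValueError(f"registry not injective for session {col!r}")

    @classmethod
    def identity(cls, n_cells: int, sessions: list[str]) -> "CellRegistry":
        data = {s: np.arange(n_cells) for s in sessions}
        return cls(pd.DataFrame(data, index=pd.RangeIndex(n_cells, name="global_id")))

    def local_index(self, global_id: int, session: str) -> int | None:
        v = int(self.table.loc[global_id, session])
        return None if v == self.ABSENT else v

    def present_in(self, session: str) -> np.ndarray:
        return self.table.index[self.table[session] != self.ABSENT].to_numpy()

    @property
    def global_ids(self) -> np.ndarray:
        return self.table.index.to_numpy()


@dataclass
class Heatmap:
    """Tuning curves of recurring place cells (rows) × spatial bins (columns),
    rows ordered by peak location in a designated sort session."""

    rates: np.ndarray  # (n_cells, n_bins), raw Af/s
    cell_ids: np.ndarray  # global ids, aligned with rows
    direction: str

    @property
    def n_rows(self) -> int:
        return self.rates.shape[0]

    def normalized(self) -> np.ndarray:
        """Row-normalized copy for display; analysis uses raw Af/s."""
        peaks = np.nanmax(self.rates, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(peaks > 0, self.rates / peaks, self.rates)


@dataclass
class PVCorrMatrix:
    """Pearson ρ between column population vectors of two heatmaps."""

    rho: np.ndarray  # (n_bins, n_bins), NaN where undefined
    direction: str
    pair: str = ""


@dataclass
class StabilityScore:
    S: float
    zone: str
    peri_values: list[float]  # pooled peri-diagonal ρ (both directions)
    rho_off_LR: float
    rho_off_RL: float


@dataclass(frozen=True)
class RecurrenceResult:
    RR: float
    n_recurring: int
    n_total: int
    recurring: frozenset  # (global_id, direction) keys
    non_recurring: frozenset


def recurrence_ratio(
    selective_a: set[tuple[int, str]],
    selective_b: set[tuple[int, str]],
    active_a: set[tuple[int, str]],
    active_b: set[tuple[int, str]],
) -> RecurrenceResult:
    """Place-field recurrence ratio RR = NR / NT across a session pair.

    Fields are (global cell id, direction) keys.  A field *recurs* if it met
    the spatial-selectivity criteria in at least one session and generated at
    least one inferred spike in that direction's subsampled trials in both
    sessions; it is *non-recurring* if selective in one session but silent in
    the other.  NT counts recurring plus non-recurring fields.
    """
    candidates = selective_a | selective_b
    if not candidates:
        raise ValueError("no selective fields in either session; RR undefined")
    recurring = {f for f in candidates if f in active_a and f in active_b}
    non_recurring = candidates - recurring
    nr, nt = len(recurring), len(candidates)
    return RecurrenceResult(
        RR=nr / nt,
        n_recurring=nr,
        n_total=nt,
        recurring=frozenset(recurring),
        non_recurring=frozenset(non_recurring),
    )


def _row_peaks(rates: np.ndarray) -> np.ndarray:
    """Row argmax with NaN treated as -inf; ties -> lowest bin."""
    return np.nanargmax(np.where(np.isnan(rates), -np.inf, rates), axis=1)


def build_heatmap_pair(
    curves_a: TuningCurveSet,
    curves_b: TuningCurveSet,
    cell_ids: np.ndarray,
    direction: str,
    sort_by: str = "a",
) -> tuple[Heatmap, Heatmap]:
    """Co-sorted heatmap pair for one direction's recurring place fields.

    ``curves_a``/``curves_b`` hold the recurring cells' curves (same row
    identity); rows are sorted by peak bin in the ``sort_by`` session
    ("a" or "b"), ties broken by global cell id.
    """
    if curves_a.rates.shape != curves_b.rates.shape:
        raise ValueError("heatmap pair must share row identity and shape")
    cell_ids = np.asarray(cell_ids)
    if cell_ids.size != curves_a.rates.shape[0]:
        raise ValueError("cell_ids must match row count")
    if cell_ids.size == 0:
        empty = np.empty((0, curves_a.rates.shape[1]))
        return (Heatmap(empty, cell_ids, direction), Heatmap(empty.copy(), cell_ids, direction))
    ref = curves_a.rates if sort_by == "a" else curves_b.rates
    order = np.lexsort((cell_ids, _row_peaks(ref)))
    return (
        Heatmap(curves_a.rates[order], cell_ids[order], direction),
        Heatmap(curves_b.rates[order], cell_ids[order], direction),
    )


def pv_correlation(heatmap_a: Heatmap, heatmap_b: Heatmap) -> PVCorrMatrix:
    """23×23 matrix of Pearson ρ between columns of the two heatmaps.

    Entry (i, j) correlates column i of A with column j of B across cells;
    entries are NaN where either column is constant or has missing rates.
    """
    A, B = heatmap_a.rates, heatmap_b.rates
    if A.shape[0] < 2:
        raise ValueError("insufficient population: need >= 2 rows")
    n_bins = A.shape[1]

    def _zscore(M: np.ndarray) -> np.ndarray:
        mu = M.mean(axis=0, keepdims=True)
        sd = M.std(axis=0, ddof=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (M - mu) / sd
        Z[:, (sd == 0).ravel()] = np.nan
        return Z

    # columns containing NaN rates (cell missing in a bin) are undefined
    Za, Zb = _zscore(A), _zscore(B)
    rho = (Za.T @ Zb) / (A.shape[0] - 1)
    bad_a = np.isnan(Za).any(axis=0)
    bad_b = np.isnan(Zb).any(axis=0)
    rho[bad_a, :] = np.nan
    rho[:, bad_b] = np.nan
    return PVCorrMatrix(rho=rho, direction=heatmap_a.direction)


def stability_score(
    mat_lr: PVCorrMatrix,
    mat_rl: PVCorrMatrix,
    zone: str = "full",
    band: int = 1,
    templates: dict[str, tuple[int, ...]] | None = None,
) -> StabilityScore:
    """Place-tuning stability score S for one session pair.

    Each direction contributes one peri-diagonal ρ value per template-zone
    bin: the diagonal entry ρ_{i,i} of that bin's column.  The ``band``
    parameter defines the peri-diagonal buffer: entries with |i − j| ≤ band
    are excluded from the direction's mean off-diagonal ρ (computed
    matrix-wide over |i − j| > band).  S is the median, pooled over both
    directions, of the per-bin values minus the direction's off-diagonal
    mean, so a pair of identity-like matrices scores 1 and constant matrices
    score 0.  Missing ρ entries are excluded rather than imputed.
    """
    templates = templates or ZONE_TEMPLATES
    if zone not in templates:
        raise ValueError(f"unknown zone {zone!r}")
    cols = np.asarray(templates[zone]) - 1

    diffs: list[float] = []
    peri_all: list[float] = []
    rho_offs: dict[str, float] = {}
    for name, mat in (("LR", mat_lr), ("RL", mat_rl)):
        if mat.rho.shape[0] != mat.rho.shape[1] or mat.rho.shape != mat_lr.rho.shape:
            raise ValueError("correlation matrices must be square and same shape")
        n = mat.rho.shape[0]
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        off = np.abs(ii - jj) > band
        off_vals = mat.rho[off]
        rho_off = float(np.nanmean(off_vals)) if np.any(~np.isnan(off_vals)) else np.nan
        rho_offs[name] = rho_off
        peri_vals = np.diagonal(mat.rho)[cols]
        peri_vals = peri_vals[~np.isnan(peri_vals)]
        peri_all.extend(peri_vals.tolist())
        if not np.isnan(rho_off):
            diffs.extend((peri_vals - rho_off).tolist())
    if not diffs:
        raise ValueError("no defined peri-diagonal correlations")
    return StabilityScore(
        S=float(np.median(diffs)),
        zone=zone,
        peri_values=peri_all,
        rho_off_LR=rho_offs["LR"],
        rho_off_RL=rho_offs["RL"],
    )


def circular_shift_shuffle(
    raster: ActivityRaster,
    trials: list[BeelineTrial],
    seed: int | np.random.Generator = 0,
) -> ActivityRaster:
    """Chance control: circularly shift each cell's spikes within each trial.

    Within every beeline trial, each cell's spike vector is independently
    rotated by a uniform random offset, destroying the spike–position
    relationship while conserving per-trial spike counts and the temporal
    autostructure within the trial.  Frames outside trials are untouched.
    """
    rng = seed if hasattr(seed, "integers") else np.random.default_rng(seed)
    spikes = raster.spikes.copy()
    n_cells = raster.n_cells
    for tr in trials:
        s, e = tr.start_frame, tr.end_frame + 1
        length = e - s
        offsets = rng.integers(0, length, size=n_cells)
        block = spikes[:, s:e]
        idx = (np.arange(length)[None, :] - offsets[:, None]) % length
        spikes[:, s:e] = np.take_along_axis(block, idx, axis=1)
    return ActivityRaster(spikes=spikes, frame_rate=raster.frame_rate)


def field_peak_distribution(heatmap: Heatmap) -> np.ndarray:
    """Histogram (length n_bins) of row peak locations; ties -> lowest bin."""
    if heatmap.n_rows < 1:
        raise ValueError("empty heatmap")
    peaks = _row_peaks(heatmap.rates)
    return np.bincount(peaks, minlength=heatmap.rates.shape[1])
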