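"""Synthetic sessions with ground-truth place fields, remapping, and shocks.

The generator emulates the structure of a linear-alternation avoidance task:
a rat runs beeline traversals between two reward zones on a 250 cm track at
~11 Hz, with a population of cells whose per-frame activity is driven by
direction-specific Gaussian-bump rate maps.  Cross-session field recurrence
and dropout, a controllable remapping fraction, and shock-evoked activity
bursts in a 2 s post-entry window are all parameterized, so every downstream
analysis stage can be validated against known ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .behavior import N_BINS, PositionTrace
from .tuning import ActivityRaster

__all__ = [
    "GroundTruthCell",
    "SimConfig",
    "SessionEvents",
    "Session",
    "generate_population",
    "generate_session",
    "generate_shock_session",
]

_SELECTIVITIES = ("LR_only", "RL_only", "both", "untuned")


@dataclass
class GroundTruthCell:
    """Generative parameters of one simulated cell."""

    cell_id: int
    direction_selectivity: str  # LR_only | RL_only | both | untuned
    field_center_LR: int | None  # bin index 1..23, present iff LR selective
    field_center_RL: int | None
    field_width: float  # cm, s.d. of the Gaussian bump
    peak_rate: float  # Af/s
    baseline_rate: float  # Af/s
    shock_responsive: bool
    recurs: bool

    def __post_init__(self) -> None:
        if self.direction_selectivity not in _SELECTIVITIES:
            raise ValueError(f"bad selectivity {self.direction_selectivity!r}")
        if not self.peak_rate > self.baseline_rate >= 0:
            raise ValueError("need peak_rate > baseline_rate >= 0")
        has_lr = self.direction_selectivity in ("LR_only", "both")
        has_rl = self.direction_selectivity in ("RL_only", "both")
        if has_lr != (self.field_center_LR is not None):
            raise ValueError("field_center_LR present iff LR selective")
        if has_rl != (self.field_center_RL is not None):
            raise ValueError("field_center_RL present iff RL selective")


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults emulate a single subsampled session: 200 cells of which half are
    spatially tuned (split 1/3 LR-only, 1/3 RL-only, 1/3 both), 20 beeline
    trials per direction at ~45/40 cm/s, 11 Hz imaging on a 250 cm track.
    """

    n_cells: int = 200
    n_trials_per_direction: int = 20
    frame_rate: float = 11.0
    track_length: float = 250.0
    n_bins: int = N_BINS
    remap_fraction: float = 0.0
    recurrence_prob: float = 0.85
    untuned_fraction: float = 0.5
    tuned_class_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    speed_mean: tuple[float, float] = (45.0, 40.0)  # cm/s, (LR, RL)
    speed_sd: tuple[float, float] = (8.0, 8.0)
    dwell_s: float = 2.0  # reward-zone dwell between traversals
    field_width_cm: float = 12.0
    peak_rate_mean: float = 3.0  # Af/s, lognormal mean
    peak_rate_sd: float = 1.5
    baseline_rate: float = 0.1  # Af/s
    shock_responsive_frac: float = 0.35
    shock_gain: float = 10.0  # rate multiplier in the 2 s post-entry window
    shock_window_s: float = 2.0
    reward_zone_cm: float = 15.0  # extent of each end zone
    shock_zone: tuple[float, float] = (100.0, 150.0)  # 50 cm center segment
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("remap_fraction", "recurrence_prob", "untuned_fraction",
                     "shock_responsive_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_cells", "n_trials_per_direction"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("frame_rate", "track_length", "field_width_cm",
                     "peak_rate_mean", "dwell_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(sum(self.tuned_class_probs) - 1.0) > 1e-9:
            raise ValueError("tuned_class_probs must sum to 1")
        if self.shock_gain < 1.0:
            raise ValueError("shock_gain must be >= 1")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")


@dataclass
class SessionEvents:
    """Per-session annotations consumed by the analysis stages."""

    reward_zones: tuple[tuple[float, float], tuple[float, float]]
    shock_zone: tuple[float, float]
    shock_on_time: float | None  # seconds; None = never electrified
    condition: str = "drug_free"


@dataclass
class Session:
    """One simulated session: trace + raster + events + realized ground truth.

    ``trial_table`` holds the generative (start_frame, end_frame, direction)
    spans of the beeline traversals, for validating trial detection.
    """

    trace: PositionTrace
    raster: ActivityRaster
    events: SessionEvents
    cells: list[GroundTruthCell]
    trial_table: list[tuple[int, int, str]] = field(default_factory=list)

    def __iter__(self):
        # allow (trace, raster, events) tuple-style unpacking
        return iter((self.trace, self.raster, self.events))


def generate_population(config: SimConfig) -> list[GroundTruthCell]:
    """Draw a population of ground-truth cells under the configured conditions.

    Tuned/untuned status is Bernoulli(1 − untuned_fraction); tuned cells fall
    into the LR-only / RL-only / both classes with ``tuned_class_probs``;
    field centers are uniform over bins.  Reproducible given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0x706F70])
    cells: list[GroundTruthCell] = []
    # lognormal peak rates matched to the configured mean/sd
    mu, sd = config.peak_rate_mean, config.peak_rate_sd
    sigma2 = np.log(1 + (sd / mu) ** 2)
    lmu = np.log(mu) - sigma2 / 2
    for cid in range(config.n_cells):
        if rng.random() < config.untuned_fraction:
            sel = "untuned"
        else:
            sel = _SELECTIVITIES[rng.choice(3, p=config.tuned_class_probs)]
        c_lr = int(rng.integers(1, config.n_bins + 1)) if sel in ("LR_only", "both") else None
        c_rl = int(rng.integers(1, config.n_bins + 1)) if sel in ("RL_only", "both") else None
        peak = float(np.exp(rng.normal(lmu, np.sqrt(sigma2))))
        peak = max(peak, config.baseline_rate + 0.5)
        cells.append(
            GroundTruthCell(
                cell_id=cid,
                direction_selectivity=sel,
                field_center_LR=c_lr,
                field_center_RL=c_rl,
                field_width=config.field_width_cm,
                peak_rate=peak,
                baseline_rate=config.baseline_rate,
                shock_responsive=bool(rng.random() < config.shock_responsive_frac),
                recurs=bool(rng.random() < config.recurrence_prob),
            )
        )
    return cells


def _build_trajectory(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, str]]]:
    """Alternating beeline traversals separated by reward-zone dwells."""
    dt = 1.0 / config.frame_rate
    L = config.track_length
    x_left, x_right = config.reward_zone_cm / 2, L - config.reward_zone_cm / 2
    dwell_frames = max(int(round(config.dwell_s * config.frame_rate)), 1)

    xs: list[np.ndarray] = [np.full(dwell_frames, x_left)]
    trial_table: list[tuple[int, int, str]] = []
    pos = len(xs[0])
    n_total = 2 * config.n_trials_per_direction
    for k in range(n_total):
        direction = "LR" if k % 2 == 0 else "RL"
        i = 0 if direction == "LR" else 1
        mu, sd = config.speed_mean[i], config.speed_sd[i]
        sigma2 = np.log(1 + (sd / mu) ** 2)
        speed = float(np.exp(rng.normal(np.log(mu) - sigma2 / 2, np.sqrt(sigma2))))
        span = x_right - x_left
        n_frames = max(int(np.ceil(span / (speed * dt))) + 1, 2)
        ramp = np.linspace(x_left, x_right, n_frames)
        if direction == "RL":
            ramp = ramp[::-1]
        trial_table.append((pos, pos + n_frames - 1, direction))
        xs.append(ramp)
        pos += n_frames
        end_x = x_right if direction == "LR" else x_left
        xs.append(np.full(dwell_frames, end_x))
        pos += dwell_frames
    x = np.concatenate(xs)
    t = np.arange(x.size) * dt
    return t, x, trial_table


def _apply_remap(
    population: list[GroundTruthCell], config: SimConfig, rng: np.random.Generator
) -> list[GroundTruthCell]:
    """Re-draw field centers for a remapping fraction of tuned cells.

    Silencing of the non-recurring fraction uses each cell's pre-drawn
    ``recurs`` flag (Bernoulli(recurrence_prob) at population creation), so
    repeated post sessions drop the same cells.
    """
    out: list[GroundTruthCell] = []
    for cell in population:
        c = dataclasses.replace(cell)
        tuned = c.direction_selectivity != "untuned"
        if tuned and rng.random() < config.remap_fraction:
            if c.field_center_LR is not None:
                c.field_center_LR = int(rng.integers(1, config.n_bins + 1))
            if c.field_center_RL is not None:
                c.field_center_RL = int(rng.integers(1, config.n_bins + 1))
        out.append(c)
    return out


def _rate_matrix(
    cells: list[GroundTruthCell],
    config: SimConfig,
    x: np.ndarray,
    directions: np.ndarray,
    active_mask: np.ndarray,
) -> np.ndarray:
    """Per-frame expected Af/s rate for every cell.

    ``directions``: per-frame code 0 = dwell, 1 = LR run, 2 = RL run.
    ``active_mask``: cells silenced in this session get all-zero rates.
    """
    width = config.track_length / config.n_bins
    n_frames = x.size
    rates = np.zeros((len(cells), n_frames))
    for ci, cell in enumerate(cells):
        if not active_mask[ci]:
            continue
        r = np.full(n_frames, cell.baseline_rate)
        for code, center_bin in ((1, cell.field_center_LR), (2, cell.field_center_RL)):
            if center_bin is None:
                continue
            sel = directions == code
            mu_cm = (center_bin - 0.5) * width
            bump = np.exp(-0.5 * ((x[sel] - mu_cm) / cell.field_width) ** 2)
            r[sel] = cell.baseline_rate + (cell.peak_rate - cell.baseline_rate) * bump
        rates[ci] = r
    return rates


def _frame_directions(n_frames: int, trial_table: list[tuple[int, int, str]]) -> np.ndarray:
    codes = np.zeros(n_frames, dtype=np.int8)
    for s, e, d in trial_table:
        codes[s : e + 1] = 1 if d == "LR" else 2
    return codes


def generate_session(
    population: list[GroundTruthCell],
    config: SimConfig,
    remap_from: list[GroundTruthCell] | None = None,
    session_seed: int = 1,
    shock_on_time: float | None = None,
    condition: str = "drug_free",
) -> Session:
    """Simulate one session for a population.

    If ``remap_from`` is given, the session is generated from a *remapped*
    copy of that prior population: a fraction ``config.remap_fraction`` of
    tuned cells receive fresh uniform field centers and a fraction
    ``1 − config.recurrence_prob`` of cells are silenced.  Per-frame activity
    is Bernoulli with p = rate / frame_rate (clipped to [0, 1]), so the
    expected number of active frames per second equals the cell's Af/s rate.
    """
    rng = np.random.default_rng([config.seed, session_seed])
    if remap_from is not None:
        if len(remap_from) != len(population):
            raise ValueError("remap_from population must match cell count")
        cells = _apply_remap(remap_from, config, rng)
        active_mask = np.array([c.recurs for c in cells])
    else:
        cells = [dataclasses.replace(c) for c in population]
        active_mask = np.ones(len(cells), dtype=bool)

    t, x, trial_table = _build_trajectory(config, rng)
    directions = _frame_directions(x.size, trial_table)
    rates = _rate_matrix(cells, config, x, directions, active_mask)

    if shock_on_time is not None:
        rates = _apply_shock_gain(rates, cells, config, t, x, shock_on_time, active_mask)

    p = np.clip(rates / config.frame_rate, 0.0, 1.0)
    spikes = (rng.random(p.shape) < p).astype(np.int16)

    trace = PositionTrace(t=t, x=x, frame_rate=config.frame_rate,
                          track_length=config.track_length)
    raster = ActivityRaster(spikes=spikes, frame_rate=config.frame_rate)
    events = SessionEvents(
        reward_zones=(
            (0.0, config.reward_zone_cm),
            (config.track_length - config.reward_zone_cm, config.track_length),
        ),
        shock_zone=config.shock_zone,
        shock_on_time=shock_on_time,
        condition=condition,
    )
    return Session(trace=trace, raster=raster, events=events, cells=cells,
                   trial_table=trial_table)


def _apply_shock_gain(
    rates: np.ndarray,
    cells: list[GroundTruthCell],
    config: SimConfig,
    t: np.ndarray,
    x: np.ndarray,
    shock_on_time: float,
    active_mask: np.ndarray,
) -> np.ndarray:
    """Multiply responder rates by shock_gain for 2 s after each electrified
    shock-zone entry."""
    lo, hi = config.shock_zone
    inside = (x >= lo) & (x <= hi)
    entries = np.flatnonzero(inside[1:] & ~inside[:-1]) + 1
    win = int(np.ceil(config.shock_window_s * config.frame_rate))
    boost = np.zeros(x.size, dtype=bool)
    for e in entries:
        if t[e] >= shock_on_time:
            boost[e : e + win] = True
    if not np.any(boost):
        return rates
    responders = np.array([c.shock_responsive for c in cells]) & active_mask
    rates = rates.copy()
    rates[np.ix_(responders, boost)] *= config.shock_gain
    return rates


def generate_shock_session(
    population: list[GroundTruthCell],
    config: SimConfig,
    session_seed: int = 2,
    shock_on_frac: float = 0.5,
    condition: str = "drug_free",
) -> Session:
    """Simulate a training session whose shock zone becomes electrified
    partway through (after ``shock_on_frac`` of the session's duration).

    Cells flagged ``shock_responsive`` have their per-frame rate multiplied
    by ``config.shock_gain`` for 2 s after each electrified-zone entry;
    non-responders are unchanged.
    """
    probe = np.random.default_rng([config.seed, session_seed])
    t, _, _ = _build_trajectory(config, probe)
    shock_on = float(t[-1]) * shock_on_frac
    return generate_session(
        population, config, session_seed=session_seed,
        shock_on_time=shock_on, condition=condition,
    )
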