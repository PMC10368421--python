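"""End-to-end orchestration: session analysis, session-pair comparison, and
multi-arm experiments on synthetic data.

The canonical flow mirrors the longitudinal design: a *pre* session and a
later session (training or post-extinction) are each analyzed for beeline
trials, tuning curves, and place cells; recurring place fields are then
compared through population-vector correlation matrices, stability scores
per track zone, the recurrence ratio, and (optionally) cross-session
position decoding.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import behavior, decoding, population, synth, tuning

__all__ = [
    "ExperimentConfig",
    "SessionAnalysis",
    "PairResult",
    "analyze_session",
    "compare_sessions",
    "run_experiment",
    "validate_inputs",
]


@dataclass
class SessionAnalysis:
    """Per-session analysis products."""

    session: synth.Session
    trials: list[behavior.BeelineTrial]
    curves: dict[str, tuning.TuningCurveSet]  # direction -> all-cell curves
    labels: list[tuning.PlaceCellLabel]
    selective: set[tuple[int, str]]  # (cell_id, direction) passing selectivity
    active: set[tuple[int, str]]  # (cell_id, direction) with >=1 spike

    @property
    def place_cell_ids(self) -> list[int]:
        return [lab.cell_id for lab in self.labels if lab.is_place_cell]


@dataclass
class PairResult:
    """Cross-session comparison of recurring place fields."""

    rr: population.RecurrenceResult
    heatmaps: dict[str, tuple[population.Heatmap, population.Heatmap]]
    pv: dict[str, population.PVCorrMatrix]
    stability: dict[str, population.StabilityScore]  # zone -> S
    decoding: decoding.DecodingResult | None = None

    def summary(self) -> dict:
        out = {
            "RR": self.rr.RR,
            "n_recurring": self.rr.n_recurring,
            "n_total_fields": self.rr.n_total,
        }
        for zone, s in self.stability.items():
            out[f"S_{zone}"] = s.S
        if self.decoding is not None:
            out["median_DE_cm"] = float(np.nanmedian(self.decoding.de_cm))
            out["mean_DAI"] = float(np.nanmean(self.decoding.dai))
        return out


def analyze_session(
    session: synth.Session,
    seed: int = 0,
    n_splits: int = 200,
    alpha: float = 0.01,
    end_zones: tuple[float, float] | None = None,
    omit_fastest: float = 0.0,
    omit_last: float = 0.0,
) -> SessionAnalysis:
    """Detect beeline trials, apply behavioral subsampling, build tuning
    curves, and classify place cells."""
    trace, raster = session.trace, session.raster
    if end_zones is None:
        rz = session.events.reward_zones
        end_zones = (rz[0][1], rz[1][0])
    trials = behavior.detect_beeline_trials(trace, end_zones=end_zones)
    if omit_last:
        trials = behavior.omit_last_fraction(trials, omit_last)
    if omit_fastest:
        trials = behavior.omit_fastest_fraction(trials, omit_fastest)
    curves = {}
    for d in ("LR", "RL"):
        if any(tr.direction == d for tr in trials):
            curves[d] = tuning.compute_tuning_curves(raster, trace, trials, d)
    labels = tuning.classify_place_cells(
        raster, trace, trials, seed=seed, n_splits=n_splits, alpha=alpha
    )
    selective: set[tuple[int, str]] = set()
    for lab in labels:
        if lab.is_place_LR:
            selective.add((lab.cell_id, "LR"))
        if lab.is_place_RL:
            selective.add((lab.cell_id, "RL"))
    active: set[tuple[int, str]] = set()
    for d in ("LR", "RL"):
        trs = [tr for tr in trials if tr.direction == d]
        if not trs:
            continue
        frames = np.concatenate([tr.frames for tr in trs])
        has_spike = raster.spikes[:, frames].sum(axis=1) >= 1
        active.update((int(c), d) for c in np.flatnonzero(has_spike))
    return SessionAnalysis(
        session=session, trials=trials, curves=curves, labels=labels,
        selective=selective, active=active,
    )


def compare_sessions(
    a: SessionAnalysis,
    b: SessionAnalysis,
    zones: tuple[str, ...] = ("full", "L", "C", "R"),
    decode: bool = False,
    decode_kwargs: dict | None = None,
) -> PairResult:
    """Recurrence, heatmaps, population-vector correlations, S, decoding."""
    rr = population.recurrence_ratio(a.selective, b.selective, a.active, b.active)
    heatmaps: dict[str, tuple[population.Heatmap, population.Heatmap]] = {}
    pv: dict[str, population.PVCorrMatrix] = {}
    curves_for_decode: dict[int, dict[str, np.ndarray]] = {0: {}, 1: {}}
    for d in ("LR", "RL"):
        gids = np.array(sorted(c for (c, dd) in rr.recurring if dd == d), dtype=int)
        if gids.size == 0 or d not in a.curves or d not in b.curves:
            continue
        sub_a = dataclasses.replace(a.curves[d], rates=a.curves[d].rates[gids])
        sub_b = dataclasses.replace(b.curves[d], rates=b.curves[d].rates[gids])
        hm_a, hm_b = population.build_heatmap_pair(sub_a, sub_b, gids, d, sort_by="a")
        heatmaps[d] = (hm_a, hm_b)
        if hm_a.n_rows >= 2:
            pv[d] = population.pv_correlation(hm_a, hm_b)
        curves_for_decode[0][d] = sub_a.rates
        curves_for_decode[1][d] = sub_b.rates

    stability: dict[str, population.StabilityScore] = {}
    if "LR" in pv and "RL" in pv:
        for zone in zones:
            stability[zone] = population.stability_score(pv["LR"], pv["RL"], zone=zone)

    dec = None
    if decode and "LR" in curves_for_decode[0] and "RL" in curves_for_decode[0]:
        kw = dict(n_subsample=20, n_shuffles=200, seed=0)
        kw.update(decode_kwargs or {})
        gids_by_dir = {
            d: np.array(sorted(c for (c, dd) in rr.recurring if dd == d), dtype=int)
            for d in ("LR", "RL")
        }
        dec = decoding.decode_session_pair(
            {d: a.curves[d].rates[gids_by_dir[d]] for d in ("LR", "RL")},
            {d: b.curves[d].rates[gids_by_dir[d]] for d in ("LR", "RL")},
            (a.session.raster.active, b.session.raster.active),
            (a.session.trace, b.session.trace),
            (a.trials, b.trials),
            cell_indices=gids_by_dir,
            **kw,
        )
    return PairResult(rr=rr, heatmaps=heatmaps, pv=pv, stability=stability, decoding=dec)


@dataclass
class ExperimentConfig:
    """Configuration for a multi-arm synthetic experiment.

    Each arm maps a condition label to the remapping fraction applied between
    its pre and post sessions (e.g. high for remembered shock, low for
    scopolamine or barrier arms).  Subsampling fractions default to the
    condition-policy values of the behavioral downsampling procedures (36%
    fastest, 29% last, 20%/25% additional fastest).
    """

    sim: synth.SimConfig = field(default_factory=synth.SimConfig)
    arms: dict[str, float] = field(
        default_factory=lambda: {"drug_free": 0.6, "scopolamine": 0.1, "barrier": 0.1}
    )
    n_splits: int = 200
    alpha: float = 0.01
    decode: bool = False
    seed: int = 0
    omit_fastest: float = 0.0
    omit_last: float = 0.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = synth.SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)


def run_experiment(config: ExperimentConfig, outdir: str | Path | None = None) -> dict:
    """Run pre/post analysis for every arm and return a summary dict.

    Fully deterministic given the config seeds: per arm, one population is
    drawn, a pre session and a remapped post session are generated, both are
    analyzed, and the pair is compared.  If ``outdir`` is given, the summary
    JSON (with a provenance block of the generating parameters) is written
    there.
    """
    summary: dict = {"provenance": _provenance(config), "arms": {}}
    for i, (arm, remap) in enumerate(sorted(config.arms.items())):
        cfg = dataclasses.replace(
            config.sim, remap_fraction=remap, seed=config.sim.seed + 1000 * i
        )
        pop = synth.generate_population(cfg)
        pre = synth.generate_session(pop, cfg, session_seed=1, condition=arm)
        post = synth.generate_session(pop, cfg, remap_from=pop, session_seed=2,
                                      condition=arm)
        sa = analyze_session(pre, seed=config.seed, n_splits=config.n_splits,
                             alpha=config.alpha, omit_fastest=config.omit_fastest,
                             omit_last=config.omit_last)
        sb = analyze_session(post, seed=config.seed, n_splits=config.n_splits,
                             alpha=config.alpha, omit_fastest=config.omit_fastest,
                             omit_last=config.omit_last)
        try:
            pair = compare_sessions(sa, sb, decode=config.decode)
        except ValueError as exc:
            raise RuntimeError(f"stage 'population' failed for arm {arm!r}: {exc}") from exc
        summary["arms"][arm] = {
            "remap_fraction": remap,
            "n_place_cells_pre": len(sa.place_cell_ids),
            "n_place_cells_post": len(sb.place_cell_ids),
            **pair.summary(),
        }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def _provenance(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config)
    d["schema_version"] = 1
    # canonical JSON form (tuples -> lists) so in-memory and on-disk agree
    return json.loads(json.dumps(d))


def validate_inputs(session: synth.Session) -> list[str]:
    """Structural checks on a session bundle; returns failure strings
    (empty when clean) and never raises on content problems."""
    failures: list[str] = []
    trace, raster = session.trace, session.raster
    if trace.n_frames != raster.n_frames:
        failures.append(
            f"length mismatch: trace has {trace.n_frames} frames, "
            f"raster has {raster.n_frames}"
        )
    if trace.t.size > 1 and not np.all(np.diff(trace.t) > 0):
        failures.append("timestamps not strictly increasing")
    if np.any(trace.x < 0) or np.any(trace.x > trace.track_length):
        failures.append("positions outside track")
    if np.any(raster.spikes < 0):
        failures.append("negative spike counts")
    for s, e, d in session.trial_table:
        if not (0 <= s < e < trace.n_frames):
            failures.append(f"trial span ({s}, {e}) outside session")
    return failures


def validate_registry(registry: population.CellRegistry, n_cells: dict[str, int]) -> list[str]:
    """Check a cell registry against per-session cell counts."""
    failures = []
    for sess, n in n_cells.items():
        if sess not in registry.table.columns:
            failures.append(f"registry missing session {sess!r}")
            continue
        vals = registry.table[sess]
        if (vals >= n).any():
            failures.append(f"registry points past cell count for session {sess!r}")
    return failures
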