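# Methods

## Scope and data model

`remapkit` analyzes longitudinal recordings of hippocampal CA1 populations
on a linearized 250 cm track sampled at ~11 Hz.  Its inputs are the outputs
of a standard miniscope preprocessing chain: a timestamped 1-D position
trace, a cells × frames deconvolved-spike raster aligned to the same
timestamps, a cross-session cell-identity registry, and per-session event
annotations (reward-zone bounds, shock-zone bounds, shock-on time,
condition label).  Motion correction, source extraction, deconvolution, and
cross-session contour registration are upstream of this package.

Activity is binarized per frame: a cell is *active* in a frame if it has at
least one inferred spike.  All rates are *active frames per second* (Af/s),
so a tuning-curve bin value is (active frames in bin) / (occupancy seconds).
The track is partitioned into 23 bins of span/23 ≈ 10.8 cm each; the final
bin is closed so the partition is exact.  Tuning width is reported as
10.8 cm × N50 regardless of the partition's exact width, matching the
nominal bin width used in the field.

## Beeline trials and behavioral subsampling

Only *beeline trials* are analyzed: traversals from one end zone to the
other whose per-frame displacement never opposes the travel direction by
more than a jitter tolerance (default 1 cm, absorbing tracking noise; the
exact tolerance behind "monotone" is a free choice and is exposed).  End
zones default to the reward-zone boundaries; trial mean speed is span /
duration.

The subsampling procedures used to equate behavior across sessions and
conditions are implemented exactly as count-based rules: omit the fastest
round(fraction·n) trials per direction (round half away from zero; speed
ties broken by removing the lower original index), omit the chronologically
last fraction, and equalize two sessions' per-direction counts by dropping
the larger session's fastest trials.  The printed condition-policy fractions
(36%, 29%, 20%, 25%) are defaults in `ExperimentConfig`, not hard-coded.

The 48 h retention ratio A = N₊₄₈/N₋₄₈ uses condition-specific cutoffs:
drug-free rats *failed* retention when A > 0.6; scopolamine rats *retained*
when A < 0.31.

## Spatial information

The spatial information of a curve is reported as

    −r̄_B log₂(r̄_B) + Σ_{i∈B} r_i p_i log₂(r_i)

where B is the set of occupied bins with non-zero rate, p_i the occupancy
probability and r̄_B the occupancy-weighted mean rate over B.  With the
weighted mean this expression equals r̄ × the Skaggs per-active-frame
information and is non-negative; with an unweighted mean it can go negative
under non-uniform occupancy, which is why the weighted reading was adopted.
The pure Skaggs form is available via `skaggs=True`, and normalization of
p_i over all occupied bins (rather than over B) via
`renormalize_over_active=False`.  0·log 0 is taken as 0; an empty B yields
0.

## Place-cell classification

Per direction with ≥ 4 trials, the trials are randomly split ⌈n/2⌉/⌊n/2⌋
200 times; each split yields the Pearson correlation between the two
half-session curves over mutually occupied bins and its two-sided p-value
from the exact t-transform with df = (common bins) − 2 (p = 1 when fewer
than 3 common bins or zero variance).  A direction passes when the median p
< 0.01.  A cell is a place cell if either direction passes, it averages
≥ 1 inferred spike per beeline trial, and its direction-specific curve does
not exceed 70% of peak in ≥ 12 of 23 bins (interneuron exclusion).  Each
cell's split sequence is seeded from (global seed, cell id), so adding or
removing cells never changes another cell's label.  Directions with < 4
trials are *not classifiable* (None), distinct from False.

The median-of-splits statistic is conservative under the null: in 500-cell
untuned simulations the false-positive rate of the selectivity criterion is
well below the nominal 1% (the test suite bounds it at 2%).

## Cross-session statistics

A field (cell × direction) *recurs* across a session pair when it met the
selectivity criteria in at least one session and emitted ≥ 1 spike in that
direction's subsampled trials of both; it is *non-recurring* when selective
in one session but silent in the other.  RR = N_R / (N_R + N_nonrecurring).

Heatmaps stack recurring fields' raw Af/s curves, co-sorted by peak bin in
a designated reference session (ties by cell id).  Row normalization is
display-only: Pearson correlation is location/scale invariant per *column*
vector, so row scaling would alter the population vectors being compared.
The population-vector matrix correlates column i of one heatmap with column
j of the other; entries are missing where a column is constant or contains
unoccupied bins, and missing entries are excluded (never imputed) from all
downstream medians and means.

The stability score S takes, per direction, one peri-diagonal value per
template-zone bin — the diagonal entry ρ_{i,i} — subtracts the direction's
mean off-diagonal ρ (entries with |i−j| > band, band default 1, computed
matrix-wide), and returns the median of the pooled differences across both
directions.  With this definition identity-like matrices score exactly 1
and constant matrices 0.  The band is a buffer: near-diagonal entries
belong to neither the peri-diagonal set nor the off-diagonal mean, since
neighboring-bin correlations are inflated by field width rather than coding
stability.  Zone templates (columns): L = 1–8, C = 9–15 (contains the 50 cm
shock zone centered on bin 12), R = 16–23; both the band and the templates
are configurable because only graphical definitions exist for them.

The chance reference circularly shifts each cell's spikes independently
within each beeline trial, preserving per-trial spike counts and
within-trial autostructure while destroying the spike–position
relationship; cross-session S on shuffled references averages to ~0.

## Shock responses

Zone entries are first-inside frames after ≥ 1 outside frame; an entry is
electrified iff its timestamp is at or after shock-on.  For each of the
first two electrified entries (later entries are ignored so detection power
does not grow with the number of shocks received), the baseline λ is the
mean active-frame count over same-direction non-electrified entry windows
(2 s, ceil(2·frame rate) frames).  λ is floored at one active frame per
total baseline frames — a zero-rate baseline would otherwise make any
single active frame significant.  The threshold is the smallest k with
P(X ≥ k | Poisson(λ)) < 0.01 (the mean is the Poisson MLE); windows
truncated at session end scale λ proportionally.  Population shock averages
take exactly one window per cell: the first significant entry for
responders, the first electrified entry for non-responders.

Approach/departure classification reflects RL curves across bin 13 so bins
1–12 always face the direction of approach; a center peak is resolved by
comparing the area under bins 1–12 versus 14–23.

## Position decoding

Decoding is memoryless Bayesian MAP over bins with a uniform prior
(occupancy prior optional).  The emission is per-cell independent Bernoulli
on active frames with p = clip(rate/frame rate, 1e−6, 1−1e−6) — chosen
because Af/s is the activity currency throughout the package; a
Poisson-count emission is available behind a flag.  Ties go to the lowest
bin; predicted position is the bin center in cm.

For a session pair, both decode directions (A→B, B→A) and both running
directions are evaluated; cell counts are equalized across running
directions by random subsampling to min(n_LR, n_RL) cells (default 100
iterations; the per-frame error is averaged over iterations).  The shuffle
reference permutes cell identities against the rate maps (2000 permutations
by default, identity not excluded) and decodes every frame.  Per bin, the
decoding error is the median absolute error over visits; G is the median of
(per-frame median shuffled error − error); the Wilcoxon signed-rank test is
applied to those per-frame differences (pairing the per-frame shuffle
*median* against the observed error), and DAI = −log₁₀(p)·sign(G) − 2.  G
is positionally biased (larger gains are attainable near track ends); DAI,
being rank-based, is not, and no bias correction is applied to G itself.
All-zero differences leave the test undefined; p and DAI are reported
missing.  With a single cell the shuffle is the identity and G = 0 by
construction.

## Synthetic-data generator

The generator emulates the study conditions rather than idealized data:

| parameter | default | rationale |
|---|---|---|
| n_cells | 200 | order of per-session CA1 yields with a large-FOV miniscope |
| untuned fraction | 0.5 | ≈ half of imaged cells classify as place cells |
| tuned classes | ⅓ LR-only, ⅓ RL-only, ⅓ both | observed direction-selectivity split |
| trials/direction | 20 | order of subsampled per-direction beeline counts |
| frame rate | 11 Hz | 22 Hz acquisition kept at every other frame |
| speeds (LR, RL) | 45, 40 cm/s, lognormal per trial | realistic beeline speeds with direction asymmetry |
| field width | 12 cm s.d. | ~30–50 cm fields on a linear track |
| peak rate | lognormal, mean 3 Af/s | sub-frame-rate peaks typical of deconvolved rasters |
| baseline | 0.1 Af/s | sparse out-of-field activity |
| recurrence prob | 0.85 | cross-session dropout without starving pair analyses |
| shock-responsive fraction | 0.35 | ≈ one-third of place cells respond to shocks |
| shock gain | 10× for 2 s | clearly supra-threshold evoked bursts |
| dwell | 2 s | inter-trial reward dwell; no published statistic exists, so it is a parameter |

Trajectories are alternating constant-speed beeline traversals separated by
reward-zone dwells (no intra-trial reversals); per-frame activity is
Bernoulli with p = rate/frame rate, which makes the expected active-frame
rate equal the cell's Af/s rate by construction.  Remapped sessions re-draw
field centers uniformly over bins for a `remap_fraction` of tuned cells
(uniform re-draw matches the absence of net field migration) and silence
the cells whose pre-drawn recurrence flag is false.  Shock sessions
electrify the center zone halfway through and multiply responder rates by
the shock gain for 2 s after each electrified entry.

What the generator does **not** emulate: calcium-indicator dynamics and
deconvolution artifacts, theta-timescale spike timing, intra-trial speed
modulation, overdispersed or correlated trial-to-trial variability, reward-
related off-track activity, and drift in field shape (remapping is all-or-
none re-centering).  Passing tests therefore demonstrate that the analysis
chain recovers known structure under a faithful-but-idealized emission
model; they do not certify behavior under real deconvolution noise.

## Problem sizes and determinism

The test suite and the acceptance script run multi-seed simulations at
moderate sizes chosen as sufficient for the statistics being checked:
120–150-cell populations and 12–14 trials per direction for stability
parameter-recovery (20 seeds), 500 null cells for classifier calibration,
200 cells for shock-response power, and 20 subsample × 200 shuffle
iterations for decoding summaries.  Every stochastic component takes an
explicit seed; identical configurations produce bit-identical outputs,
including the experiment summary JSON.

## Known limitations

- The stability score's peri-diagonal definition (per-bin diagonal values
  with a band buffer) and the zone templates are configurable
  reconstructions; published definitions are graphical.
- Decoding with very sparse populations (few recurring place cells per
  direction) yields noisy per-bin Wilcoxon p-values; bins without visits are
  reported missing rather than interpolated.
- The Poisson shock test conditions on ≥ 1 same-direction baseline entry;
  sessions without one raise an error rather than borrowing a baseline from
  the other direction.
- `recurrence_ratio` treats selectivity and activity sets as inputs; it does
  not re-validate them against the registry.
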