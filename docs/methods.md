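# Methods

This note documents the models, estimators, and numerical choices behind
`navcode`, and what the synthetic-data generator does and does not emulate.

## Preprocessing model

Raw somatic fluorescence is corrected for surrounding-tissue contamination
as `F_corr = F_cell − 0.7·F_np`.  The baseline `F0` is a morphological
opening of `F_corr` — a rolling minimum followed by a rolling maximum, both
over a 60 s window — then Gaussian-smoothed with σ = 10 samples at the
acquisition rate.  The opening removes positive transients shorter than the
window while tracking slow drift; it preserves constants and is
translation-equivariant, which the unit tests verify directly.  Edges use
nearest-sample padding (equivalent to shrunken windows for min/max
filters).  `ΔF/F0 = (F_corr − F0)/F0`; neurons whose baseline dips below a
small fraction (1e-6 of the median `F0`) anywhere are flagged invalid
rather than raising.

Event amplitudes are recovered by inverting a single-exponential calcium
kernel with decay τ_ca = 1.5 s (appropriate for GCaMP6s): the trace is
modeled as `c[t] = γ·c[t−1] + s[t]` with `γ = exp(−1/(rate·τ_ca))` and the
non-negative event train `s` minimizing `‖c − ΔF/F‖²` is found by a
pool-adjacent-violators pass with no sparsity penalty.  On noise-free
forward-synthesized traces the inversion is exact to 1e-6, a property the
acceptance suite checks by round trip.  The solver is written in-package;
only the kernel is fixed, no sparsity or baseline parameters are estimated.

The 3-SD significant-transient rule uses a robust noise scale,
MAD·1.4826 per neuron, so the transients themselves do not inflate the
threshold; the convention for computing this SD varies across labs, and
the MAD choice is deliberately conservative.  The rule is applied to
neuropil-corrected ΔF/F.  Lap reliability is the fraction of laps with at
least one flagged sample; a neuron is task-active if lap reliability or
visual reliability strictly exceeds 0.3.

## Behavior

Speed is computed from wrap-corrected position differences and smoothed
with a 0.5 s boxcar (the simplest estimator consistent with the wrap).  Running epochs are maximal stretches with
speed ≥ 5 cm/s; gaps shorter than 0.5 s are merged *before* the ≥ 1 s
duration filter, so that the duration criterion applies to the final merged
epochs rather than to the raw fragments.  Lap segmentation converts positions to monotone belt
progress (wrap-corrected increments, accumulated, running maximum); the lap
index is the number of whole track lengths in that progress.  This is
hysteretic by construction: jitter across the 0 cm seam cannot produce
spurious laps, and the index is non-decreasing.  Occupancy is time per
1.5 cm bin inside running epochs, normalized to 1; bins are half-open and
0-based, so position exactly L maps to bin 0.

## Position tuning

Maps use 100 bins (1.5 cm on the 150 cm belt).  Per trial (lap) and bin,
summed event amplitude is divided by time in the bin, running epochs only;
bins a trial never visits are missing for that trial and excluded from the
across-trial mean and SEM (SEM uses n−1).  Smoothing is a circular Gaussian
(SD = 3 bins) applied per trial via normalized convolution so missing bins
do not bleed zeros into their neighbors.

Significance uses a circular-shift null: each neuron's event train is
shifted in time by an amount drawn uniformly from [20 s, T − 20 s]
(independently per neuron and shuffle, 200 shuffles), and the trial-
averaged map is recomputed.  The neuron is significant when its observed
mean − SEM exceeds the per-bin 97.5th percentile of the shuffled maps in at
least one bin.  Shuffled values could equally be pooled across bins into
one null distribution; per-bin percentiles are used here because the
exceedance criterion itself is evaluated bin by bin.
The conservative mean − SEM lower bound offsets the 100-bin maximum: on
position-independent neurons under the default noise model the measured
false-positive rate is a few percent (the acceptance suite bounds it at
10%).  Circular shifting is a permutation, so event sums are preserved
exactly.

Fields are circularly contiguous runs above
`baseline + 0.3·(peak − baseline)` on the smoothed mean map, with the map
minimum as the baseline ("baseline activity" has no unique definition on
a circular map; the minimum is the conservative choice);
widths must lie in [15, 120] cm, and a field must be present — trial mean
over the field span above the same threshold — in strictly more than one
third of trials.  A neuron is position-tuned iff shuffle-significant with
at least one valid field; the reported width is the widest field and the
field count is capped at 3.  Spatial information is
`SI = Σ pᵢ (fᵢ/f) log2(fᵢ/f)` in bits/event (a KL divergence, hence ≥ 0 and
scale-invariant); trial reliability is the median pairwise Pearson
correlation between per-trial maps over mutually visited bins.

## Bayesian decoding

The encoding model `fᵢ(pos)` is the occupancy-normalized event rate
(events/s) per neuron and 1.5 cm bin, estimated from training laps during
running epochs and floored at 1e-3 of the grand-mean rate so the
log-likelihood stays finite.  Decoding evaluates

    P(pos | a) ∝ (∏ᵢ fᵢ(pos)^{aᵢ}) · exp(−τ Σᵢ fᵢ(pos))

in the log domain, with τ one imaging frame (1/rate) by default and `aᵢ`
the neuron's deconvolved amplitude in the frame, clipped at 0.  The
Poisson-form likelihood requires non-negative exponents, so deconvolved
events are the default input; raw ΔF/F can be supplied instead but is
clipped the same way.
The decoded position is the maximum-posterior bin, ties to the lowest
index.  Cross-validation splits laps odd/even (odd-numbered laps train) or
into 5 contiguous folds.  The decoding error is the linear absolute
difference |decoded − actual|; a circular option exists behind a flag.
The chance reference is defined as 50 bins (75 cm), half the belt.
Display smoothing of the error trace (Gaussian, σ = 10 frames) is never
used for statistics.

## Visual tuning

Trials are regrouped into canonical condition order (direction, then SF,
then TF ascending); each snippet is baseline-corrected by the median of the
5 frames before onset.  The reliability index is the 75th percentile of
pairwise Pearson correlations between the condition-ordered repetition time
courses, concatenated across conditions (whether pairs were computed per
condition and pooled is a genuine design choice; concatenation is used).  The scalar
response per condition is the mean corrected ΔF/F over the 3 s stimulus
window.  OSI/DSI are computed on the 12-point direction curve at the
preferred SF/TF combination only, after rectifying negative means to 0 so
both indices stay in [0, 1]; R_ortho averages both orthogonal directions.
Selectivity thresholds are strict (> 0.33), as is the responsiveness
threshold (> 0.3).

## Widefield retinotopy

Pixels are normalized to the pre-stimulation baseline, contrast-enhanced
with a rolling min-max filter (window 10 s by default, configurable, with
a small δ guard so constant pixels map to 0), trial-
averaged, and projected onto `exp(−i2πft)` at the stimulus frequency.  For
a pixel `b + A·cos(2πft − φ)` the recovered amplitude is `A` normalized by
the pixel's temporal mean and the recovered phase is `φ` exactly (to 1e-6
for noiseless input over integer cycles; a Hann window is applied with a
warning otherwise).  Positive phase means a later response.  HSV rendering
maps phase to hue, normalized amplitude to value, saturation 1.  Atlas
registration is out of scope; a landmark affine would slot in after the
maps.

## Input tracing

Labeled cells are aggregated up a rooted region ontology to any antichain
("major" = children of the root, or an explicit acronym list); unresolvable
acronyms go to a rejects report and counts are conserved at every level.
Input fractions divide by the target's total; densities divide by the sum
of leaf volumes; within-group fractions renormalize inside one group (e.g.
VIS subregions).  The bias index is `log2(f_posterior/f_anterior)` —
antisymmetric under target swap, 0 for equal composition.  When any count
is zero, one pseudocount cell per region × target is added before fractions
(raw counts are always reported alongside).  Dorsoventral topography compares per-target coordinate CDFs with
a two-sample KS test.  The bundled ontology is a ~40-region synthetic
fixture with nominal volumes — densities are only internally comparable —
and any atlas-derived CSV with the same columns can replace it.

## Statistics

Scalar session-level comparisons use the two-sided Mann–Whitney U (exact
null for tie-free samples with min n ≤ 8, tie-corrected normal
approximation otherwise, no continuity correction so identical samples give
p = 1); pooled neuron-level distributions use the two-sample KS test with
the asymptotic p-value.  Stars: p < 0.05 (*), < 0.01 (**), < 0.001 (***).

## Synthetic sessions: what they emulate, and what they do not

The generator reproduces the study conditions: a 150 cm circular belt with
cues at 50/100 cm and reward at 0 cm; 30 Hz sampling (a 7.5 Hz volumetric
preset exists); run/pause behavior as a two-state Markov bout model (mean
run speed 15 cm/s, SD 3 cm/s, dwell times 30 s running / 3 s paused) that
exercises the epoch detector; place fields as circular Gaussians (SD 10 cm)
riding on a 0.2 events/s baseline with peak extra rate 2 events/s; Poisson
events convolved with the 1.5 s kernel; fluorescence
`F0·(1 + signal) + 0.7·shared neuropil + Gaussian noise` (noise SD 0.05 of
F0); a pseudo-randomized 12 × 3 × 2 grating protocol (3 s on / 2 s gray)
with von-Mises direction tuning and an SF/TF preference surface; periodic
widefield movies; and multinomial region-count tables.  Per-neuron event rates and SNR vary widely across real preparations, so
the defaults are chosen for realism and testability, not fidelity to any
particular dataset.

A separate `high_snr_config` preset (peak rate 10 events/s, noise SD 0.02)
defines the "strongly driven" condition used by the recovery checks.  At
the realistic default rate, peak-position estimates jitter by ~2 cm SD from
Poisson sampling alone — verified to be identical when the pipeline is fed
the ground-truth event trains, i.e. a property of the data volume rather
than the estimators — so sub-bin recovery guarantees are only meaningful in
the high-rate regime.

What the generator does not model: biophysical indicator nonlinearity
(single-exponential kernel only), motion artifacts and ROI cross-talk,
behavioral state changes, licking, eye movements, or VR rendering.
Passing tests therefore demonstrate correctness of the estimators under the
stated noise model, not robustness to every artifact of real recordings.

## Problem sizes

Tests and the acceptance script run the full stack at desk scale, chosen as
the smallest sizes at which the measured properties are stable: 600 s /
200-neuron sessions for shuffle calibration, power, and decoding; 100
position-independent neurons for the null rate; a 10 + 10-session cohort of
360 s / 50-neuron sessions (tuned fractions 0.45 vs 0.21) for the
group-level design; 10,000-cell multinomial tables; 200 shuffles
throughout, matching the analysis default.
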