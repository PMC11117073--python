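# Methods

This note documents the models behind `plusend`, the defaults that matter,
what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Filament model and simulator

Each filament's plus end is a continuous-time jump process over the states
`free`, `formin`, `formin_pfn1`, `cp_capped`, `decision_complex` and
`iqgap1_paused`. Between jumps the filament elongates linearly at

    speed (µm/s) = state_growth_rate (su s⁻¹ µM⁻¹) × [actin] (µM) / 370 (su/µm),

using actin's linear subunit density of 370 subunits per micron. Default
growth rates: free ends 10.2, formin alone 7.6, formin with profilin 52.4
subunits s⁻¹ µM⁻¹; the capped, decision-complex and paused states add
nothing (an invariant the configuration validator enforces).

Residence times are exponential with the configured transition rates,
with one exception: pause-type states (`iqgap1_paused`) hold the end for
a Gaussian-distributed duration, N(20.6 s, 5 s²) by default, truncated at
zero by rejection. Pause durations are empirically unimodal, not
exponential, and the truncation is negligible four standard deviations
from zero. The default pause entry rate (0.002 s⁻¹ from the free state)
yields roughly 1.2 pauses per filament over a 600 s movie — the order of
one-plus pauses per filament seen in pausing conditions.

Sampling: tracks are observed on a fixed frame grid (5 s default, the
standard acquisition interval; 3.2 s is typical for four-colour
acquisition), with additive Gaussian localisation noise of 0.05 µm
(sub-pixel at the default 0.16 µm/px). Nucleation times are uniform over
the movie so filaments appear throughout, or all at t = 0 on request.
Each simulation call uses a single explicitly seeded NumPy generator; the
same config and seed are bit-reproducible.

What the generator does **not** emulate: point-spread-function rendering,
camera noise models, kymograph images, filament crossing/bundle occlusion,
drift, or segmentation/tracking errors other than i.i.d. localisation
noise. Passing recovery tests therefore demonstrate the correctness of
the estimators on clean tracks and traces, not robustness to tracking
artefacts in raw movies.

Other generators:

- **Photobleaching**: an n-mer with labeling efficiency p carries
  k ~ Binomial(n, p) fluorophores; k = 0 molecules are omitted (only
  fluorescent molecules can be scored). Each fluorophore bleaches at an
  independent Exponential(bleach_rate) time; traces are sampled at 0.2 s
  over 120 s with Gaussian noise.
- **Dwell events**: dissociation is exponential with a per-species mean;
  an optional displacement hazard adds a competing exponential clock, so
  realised dwells are Exponential(1/mean + hazard). Molecules bound past
  the movie end are right-censored.
- **Spot fields**: a fraction of channel-A spots receive a jittered
  channel-B partner; the remaining channel-B density is filled with
  independent uniform spots at density_B × (1 − fraction) so per-channel
  densities stay comparable across mixture fractions.
- **Bundle pixels**: a two-component intensity mixture (singles at unit
  mean, bundles at ≥ 2× unit) plus symmetric noise; a minority of bundle
  pixels produces the right tail that the skewness metric reads out.

## Kinetics

Elongation rates are ordinary least-squares slopes over ≥ 4 samples
(robust regression is deliberately not used; the estimate mirrors a
straight-edge slope over a handful of points). `fit_r2` is 1 − SSres/SStot.

Pause detection marks a frame-to-frame increment as stalled when
|Δlength| < `stall_epsilon` (default 0.1 µm ≈ one pixel at 60×, well
above the 0.05 µm localisation noise; the value is configurable and
carried in CLI output metadata). Maximal runs of ≥ `min_frames` (default
3) stalled increments become pauses; runs touching the last frame are
flagged as truncated and excluded from duration fitting by default, which
avoids censoring bias. Two stalled runs separated by a growing increment
are distinct pauses.

Whole-track rates (pause frames included) are the default reported mean —
the drop of the population mean below the free-end rate is exactly the
pausing signal. With `exclude_pauses` the pause frames are dropped *and
the time axis is spliced across each pause* before the fit; without the
splice, the vertical offsets between growth segments bias a single-line
slope low by about 5% per 20 s pause in a 600 s track, which would defeat
the 2%-recovery property the growth-phase rate is meant to satisfy.

## Pause-duration distributions

Histograms bin durations into uniform bins [k·w, (k+1)·w) starting at
zero (default width 5 s = one frame interval); `bin_centers` are
midpoints. Starting the first full-width bin at zero keeps a decaying
sample monotone in its counts — a half-width first bin would fake a peak.
Fits operate on counts; the amplitude parameters absorb any count
rescaling, leaving x̄, SD and k invariant.

Both models are fit by bounded Levenberg–Marquardt (trust-region) least
squares with deterministic data-driven starts: weighted bin mean/SD and
max frequency for the Gaussian; first-half log-linear slope for the decay
constant. The Gaussian mean is constrained to be non-negative because it
is reported as the mean pause duration; unconstrained, a half-Gaussian
with mean → −∞ mimics exponential decay on decaying histograms and the
fit diverges. Model comparison uses R² only (no AIC/BIC), with equal R²
reported as a tie. Note the two families genuinely overlap at a few
hundred events: a mean-zero Gaussian remains a competitive rival on
exponential samples in roughly 8% of 300-event replicates.

## Step photobleaching

Labeling efficiency from spectroscopy:
dye = A_dye/ε_dye; protein = (A_protein − CF·A_dye)/ε_protein; the ratio
is clipped at 1. The predicted visible-step distribution is the binomial
expansion of (X + Y)ⁿ with X = labeled and Y = unlabeled fraction,
renormalised over k ≥ 1 by default (the unconditional form is also
available — whether published predictions condition on visibility is
ambiguous, so both are computed).

Hand scoring of steps is replaced by changepoint detection: recursive
binary segmentation on the CUSUM mean-shift statistic, accepting a split
when the level gap clears both half the step threshold and a 3σ
finite-sample guard; downward shifts between adjacent segment means of at
least `min_step` count as bleaching steps. `min_step="auto"` uses 3× a
robust noise scale, 1.4826·median|Δ|/√2 from first differences. Two
fluorophores bleaching within one frame merge into a single larger drop
and are counted once — with the default sampling this costs ~2% of dimer
traces and is the main detection error mode.

State inference compares observed step proportions (tail pooled at 4+)
with each candidate's conditional pmf by Pearson chi-square distance
(total variation behind a flag). Bins a candidate deems impossible
contribute their observed mass directly rather than an infinite term, so
a single miscounted molecule cannot disqualify an otherwise matching
candidate. Histograms under 30 molecules set a warning flag rather than
failing.

## Dwell survival and colocalization

Kaplan–Meier (via `lifelines`) is the default censoring treatment: it
keeps movie-end-censored molecules in the risk set and reduces exactly to
the empirical survival when nothing is censored; `censoring="drop"`
excludes them. Both are exposed because it is equally defensible to treat
movie-end-bound molecules as events or as censored observations.

Colocalization matches spots greedily in increasing distance order
(deterministic distance-then-index tie-break), one-to-one, within a match
radius (default 0.4 µm ≈ 2.5 px at 0.16 µm/px, half a 5-pixel particle
size). At single-molecule densities greedy matching is indistinguishable
from optimal assignment. The first-listed channel is the reference for
the percentage. The chance-corrected estimate subtracts the spatial-
Poisson chance level p = 1 − exp(−λ_B·π·r²) and rescales by 1 − p; λ_B is
taken from the full channel-B density, which slightly overcorrects (the
partnered spots are not available for chance matches) — under a percent
at the default densities.

## Cell-scale metrics

Skewness is the biased third standardised moment m₃/m₂^1.5 (undefined —
NaN — at zero variance). Circularity is 4πA/P² clipped at 1, with the
perimeter from the traced 0.5-level contour reweighted by the classic
corner-corrected coefficients (0.980 per axial unit, 1.406 per diagonal
step, −0.091 per direction change): raw chain length overestimates a
digitised circle by ≈ 5%, and with the correction a radius-200 px disk
scores ≥ 0.99 while a 1:10 rectangle lands within 0.02 of its analytic
0.26. Masks must contain a single 8-connected component; anything else is
an error listing component sizes.

Wound closure reports the difference form T12 − T0 as the primary value
(the two published definitions — difference and ratio — are inconsistent
with each other; the difference matches "normalized closure" usage) with
the ratio alongside. Molecule budgets use N_A = 6.02 × 10²³, convert
µm³ → L at 10⁻¹⁵, and round oligomer counts down; the free-end pool is
filament density × footprint area. The conservative 1,720-end figure used
for the remaining-ends bound corresponds to 172 filaments/µm² over the
1 × 10 µm footprint and is treated as a printed constant, not derived.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use populations of 75–1800
filaments, 300 photobleaching molecules (the standard per-protein design),
5000 dwell records and ~2000 spots per channel — sizes at which each
Monte-Carlo check is stable across seeds while the whole suite runs in
well under a minute. Distribution-level assertions (fit R², selection
rates) are made at ~1000 events where their sampling noise is small;
event-count-sensitive examples are also exercised at the ~300-event scale.
All randomness flows through explicit integer seeds; hypothesis-based
property tests run derandomised.

## Known limitations

- The simulator's jump-process kinetics are a minimal mechanism chosen to
  reproduce the measured readouts (rates, pause statistics, dwell times);
  it is not a molecular model of end-binding competition.
- Step detection assumes piecewise-constant intensity with i.i.d. noise;
  fluorophore blinking, drift and uneven illumination are out of scope.
- Spot detection from raw images is not implemented; coordinates are the
  input contract.
- The stall tolerance used when pauses were scored by eye is unknowable;
  it is exposed as a parameter rather than asserted.
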