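# Methods

## Scope and data model

The package analyzes stimulus-locked EEG responses to sustained (10-s)
somatosensory stimulation blocks: focal vibration (FVS) at five intensities
(1.9, 1.6, 1.3, 1.0, 0.7 G) and neuromuscular electrical stimulation (NMES)
at three threshold-referenced levels (motor threshold, the median between
perceptual and motor thresholds, perceptual threshold).  The unit of
acquisition is a 4-minute continuous trial containing six blocks of one
scheme separated by 25-s quiet gaps (any schedule with gaps ≥ 20 s is
accepted); the unit of analysis is a 15-s epoch spanning a 5-s pre-onset
baseline and the 10-s block, with half-open spans ([−5, 0) baseline,
[0, 10) block; the onset sample belongs to the block).  Per participant,
features are averaged across the six blocks of a trial; these block means
are the *reading units* consumed by all statistics.

The default montage is a 62-channel 10-10 cap (a standard 64-electrode
layout minus the FCz reference and AFz ground); it is a documented constant
(`eegstim.montage.CHANNELS_62`) and configurable.  The full factorial
enumeration — 15 subjects × 2 arms × 2 muscle unions × 8 schemes ×
6 blocks × 62 channels — yields 178,560 episodes per group.

## Synthetic signal model

Each simulated channel is the sum of:

1. **Pink noise** — white Gaussian noise shaped to a 1/√f amplitude
   spectrum (flat below 1 Hz), scaled to 5 µV RMS by default.
2. **Band oscillators** — sinusoids at 6 (θ), 10 (α), 20 (β) and 40 Hz (γ)
   with base amplitudes 4, 6, 3 and 1.5 µV, each multiplied by a unit-mean,
   non-negative random envelope varying on a ~2-s timescale (linear
   interpolation of Gaussian knots, ±30% modulation).  These amplitudes
   sit in the range typical of adult scalp EEG and leave the injected
   effects recoverable at n = 10 subjects — the regime the study design
   operates in.
3. **Event-related desynchronization** — inside each block the α/β
   envelopes on sensorimotor channels are multiplied by
   `1 − depth·w_ch·exp(−t/τ)` with τ = 6 s, so suppression is maximal at
   onset and adapts back toward baseline.  The per-hemisphere weight `w_ch`
   splits the effect between the hemisphere contralateral to the stimulated
   arm (weight = laterality, default 0.7) and the ipsilateral one
   (1 − laterality).
4. **Theta synchronization** — the θ envelope is multiplied by a gain
   (default up to 2.5 at maximal drive) over the first 0.5 s of each block,
   with the same laterality split.
5. **P300** — a raised-cosine positive half-wave (width 0.3 s) added to
   midline channels (weights: Cz 1.0, Pz 0.9, Fz 0.8, plus small
   parasagittal spread), centred `latency` seconds after each onset.

Scheme intensity maps to a drive in [0, 1] (FVS: G/1.9; NMES: 1.0 / 0.7 /
0.4 for motor / median / perceptual).  Default effects are monotone in
drive: P300 amplitude 8·drive µV (FVS) or 7·drive µV (NMES); latency
0.55 − 0.17·drive s (FVS) vs 0.65 − 0.15·drive s (NMES), so vibration is
always earlier at matched rank; ERD depths 0.30 + 0.40·drive (α) and
0.25 + 0.30·drive (β).  The stroke group scales FVS P300 amplitude, theta
gain and ERD depths by 0.6, leaves NMES amplitude nearly intact (factor
0.95, matching the absence of a group difference under electrical
stimulation), and shifts the laterality weight to 0.35 (toward the
contralesional hemisphere).  Half of the stroke subjects are assigned
left-hemisphere lesions; their recordings exercise the montage-flip stage.

Randomness: one master seed; each trial's substream is
`SeedSequence([master_seed, trial_seed])` with `trial_seed` derived by
counter-based mixing, so trials are reproducible independently of
simulation order.  Synthesis runs in single precision.

**What the generator does not emulate**: volume conduction and channel
covariance (channels are independent), ocular/muscular artifacts, 50-Hz
line interference, inter-subject variability of effect parameters (noise is
the only subject-level variation), non-sinusoidal rhythms, and any
biophysical head model.  Passing recovery tests therefore demonstrate that
the pipeline's estimators and statistics recover known injected structure
through the full processing chain — not that the pipeline would be robust
to every artifact class of real recordings.

## Pre-processing

Filtering is a 4th-order Butterworth band-pass (1–100 Hz) cascaded with a
4th-order band-stop (49–51 Hz), applied forward–backward (zero-phase) so
P300 latencies are not biased; the effective attenuation is the squared
magnitude response.  Epoch rejection replaces operator-dependent screening
with a deterministic rule: drop an epoch if any channel's peak-to-peak
amplitude exceeds 200 µV or any sample is non-finite.  For left-lesion
participants, mirror-paired channel data are swapped across the mid-sagittal
plane (C3↔C4 etc., midline untouched) so the affected hemisphere is on the
right for the whole group; the stimulated-arm side used for region
resolution is mirrored accordingly.

## Spectral estimation

`compute_psd` uses a Hann-tapered periodogram zero-padded to a ≤ 1-Hz grid
for segments shorter than 4 s (the 0.45-s period of interest) and Welch
(2-s Hann segments, 50% overlap) otherwise (the 5-s baseline).  RSP band
integrals use half-open bands on the estimator grid; the 12–13 Hz gap
between α and β is kept deliberately.  The baseline fraction uses the full
5-s baseline by default; a duration-matched mode exists
(`baseline_mode="matched"`).  Note the two RSP terms may therefore come
from different estimators; since each term is a within-segment power
*fraction*, this mixes resolutions but not scales.

## Time–frequency analysis

Morlet wavelets on a 1-Hz grid (2–100 Hz) with `n_cycles = max(3, f/2)`;
output power is decimated in time (default 10–20×) since it varies slowly.
Bins whose wavelet half-support (`n_cycles/2f` seconds) crosses an epoch
edge are flagged invalid, excluded from baseline statistics and from the
significance mask.  ERSP µ/σ are estimated from the epoch's own baseline
bins (the equation indexes them by frequency only); an across-trials
variant was considered and rejected because the pipeline operates per
episode.  The baseline-permutation mask draws, per frequency, 2000
surrogate block-mean values from the pooled baseline bins of the blocks,
computes two-sided empirical p values with the (b+1)/(n_perm+1) convention,
and applies Benjamini–Hochberg FDR across all valid bins.  ERD/ERS
topographies default to the mean over the full 10-s block
(`topo_stat="mean"`); a peak-magnitude variant (`"peak"`) is provided since
summary conventions differ between the mean-over-window definition and
peak-value topographic maps.

## Statistics

The cluster-based permutation test forms clusters of adjacent bins whose
two-sided t statistic exceeds the critical value at `cluster_alpha = 0.05`
(temporal adjacency: consecutive bins; time–frequency: 4-connectivity;
sensor space: Delaunay triangulation of 2-D projected electrode positions
with edges above the 90th length percentile pruned — montage-agnostic and
deterministic).  The cluster statistic is the mass (sum of t); the null is
the maximum |mass| over label shuffles (independent) or sign flips
(paired).  For paired designs with 2ⁿ ≤ n_perm the test enumerates all sign
assignments and the p values are exact (the identity assignment included);
otherwise Monte-Carlo p = (b+1)/(n_perm+1), which never returns zero.

Normality routing uses the Lilliefors composite-normality test at 0.05 —
the phrase "Shapiro–Wilk with Lilliefors correction" conflates two tests,
and Lilliefors is the one with the calibrated null rejection rate; a
constant sample is reported non-normal with p = 0 by convention.
Parametric batteries (mixed ANOVA, RM-ANOVA with Greenhouse–Geisser
correction when ε < 0.75, Bonferroni post hocs, t-tests) run through
pingouin/scipy; nonparametric comparisons use exact Mann–Whitney/Wilcoxon p
values where feasible.  Effect sizes: partial η² (ANOVA), Cohen's d
(t-tests), rank-biserial correlation (rank tests).

## Numerical conventions and degenerate inputs

* P300 peak = maximum sample in the 250–800 ms window, ties to the earliest
  time; no smoothing by default (an optional centred moving average,
  ``smooth_s``, exists but is off — peak means peak).  The 300–750 ms
  window is reserved for the RSP period of interest.
* RSP is undefined (error) when either segment has zero total 1–100 Hz
  power; ERSP errors when a baseline SD is zero, naming the frequency.
* Events closer than 5 s to the record start or 10 s to its end are skipped
  with a logged warning, not an error.
* EDF+ writing quantizes to 16 bits over each channel's physical range and
  requires an integral number of seconds (1-s records); BrainVision writing
  stores IEEE float-32.

## Problem sizes used in tests and the acceptance script

The generator's defaults (1000 Hz, 62 channels, 6 × 10-s blocks, 4-min
trials, effect parameters above) are never reduced.  What is scaled is the
number of cells simulated per run: recovery checks use 8–10 subjects per
group, one arm, one muscle union, and the representative FVS-1/NMES-2
schemes; error-control simulations use 100–200 null datasets at
n_perm = 500 and 8–12 ERSP-mask runs.  These sizes are the package's
choices for a desk-scale validation study; all orderings they test are
injected by construction and recovered with margin.

## Known limitations

* The ERSP baseline-permutation scheme is a declared stand-in with the
  stated resample count and FDR correction; published toolbox
  implementations differ in how they pool baseline bins.
* Channel independence in the generator makes sensor-space cluster tests
  easier than on real data (no spatial correlation under the null);
  the family-wise error calibration is still exact by construction of the
  permutation scheme.
* The parametric battery assumes complete within-factor cells and errors
  otherwise; it does not impute missing reading units.
* No source-space analysis, no inter-trial phase coherence, no artifact
  simulation beyond broadband noise.
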