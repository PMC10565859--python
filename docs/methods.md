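# Methods

`earload` reimplements, on synthetic data, a complete analysis chain for
deciding whether mental workload can be decoded from ear-EEG as well as it
can from conventional cap-EEG: task simulation, preprocessing, spectral
and temporal feature extraction, permutation statistics with FDR
correction, and single-trial classification with step-wise linear
discriminant analysis (swLDA). This note documents the models, the
defaults and the design decisions; everything quantitative below is
computed by the test suite or by `scripts/acceptance.py`, not asserted
from memory.

## Task designs

Two paradigms are simulated as event schedules.

**N-back (working memory).** 4 sessions x 6 two-minute blocks. Each block
presents 48 letter stimuli (500 ms on screen, 2000 ms inter-stimulus
interval; stimulus-onset asynchrony 2.5 s), of which exactly 16 (= round
of 33%) are targets. The three difficulty levels (0-, 1-, 2-back) each
occur twice per session. This yields 1,152 stimulus events per subject,
384 per level.

**Mental arithmetic (cognitive workload).** 2 sessions x 15 one-minute
blocks; five difficulty levels, three blocks each per session. Problem
presentations are self-paced and are not modeled; analysis epochs are
fixed windows inside blocks.

In both tasks the level order is pseudorandom under two constraints:
within a session every level appears once before any level repeats, and
the same level never occurs twice in a row. The sampler draws one
permutation of the level set per round and rejects draws that repeat a
level across a round boundary (bounded retries, then a design-validation
error). A 20 s rest follows each block; the gap between sessions is
modeled as one extra rest. A 5 s pre-roll precedes the first block so
that pre-stimulus epoch windows stay inside the recording. Stimulus
onsets carry a 10 ms lead inside their block (and rests a 1 ms lag after
block end) purely to keep event onsets strictly increasing.

## Signal model of the generator

Recordings are channels x samples in microvolts at 500 Hz, on a montage
of 12 scalp channels (10-20 names), two sub-ocular EOG channels, ten
around-ear cEEGrid channels (L1-L7, R1-R7 subsets) and two in-ear
channels (E1, E2). Signals are generated directly in a common reference;
the `rereference` operation exists for data recorded against a physical
reference.

Per channel, the signal is a sum of:

1. **1/f background** — Gaussian noise with power spectral density
   proportional to `f^-exponent` (default exponent 1, total SD 8 uV),
   spectrally *notched* over the seven canonical oscillation bands
   (delta 1-3, theta 4-7, alpha 8-12, beta1 13-19, beta2 20-30, gamma1
   30-50, gamma2 50-100 Hz).
2. **Band oscillators** — per band, Gaussian noise carrying the 1/f
   spectral shape inside the band, with amplitude
   `sqrt(osc_std[band]^2 + notched-background share)`. During a block of
   level L, the band's amplitude is multiplied by
   `sqrt(band_gain[L][band])`. Because each band carries *all* in-band
   power, the ratio of mean epoch band powers between two conditions
   converges to the configured power gain — this is the generator's
   central calibration property and is tested at 20% tolerance with >=
   300 epochs per condition. The oscillator partition defaults to the
   seven canonical bands but is configurable (`osc_bands`), so condition
   effects can be narrowband. Default oscillator SDs (uV): delta 2.5,
   theta 2.5, alpha 4.0, beta1 1.5, beta2 1.2, gamma1 0.9, gamma2 0.7;
   bands outside the map carry the background share only.

   Each (channel, band) oscillator additionally carries a slow
   multiplicative log-normal amplitude envelope
   (`amplitude_modulation_std`, default sigma 0.4; ~4 s knots,
   normalized to unit mean power). This emulates arousal-linked
   band-power co-fluctuation and is what gives epoch band powers the
   heavy-tailed, outlier-rich distributions seen in real data. It is
   also statistically decisive: without it, periodogram bins are
   independent, so averaging a band's bins divides the noise by the bin
   count and a coarse band feature becomes a matched filter for any
   within-band-uniform effect — coarse feature models would then
   *outperform* fine ones, the opposite of what happens on real EEG.
   With band-wide common modulation, coarse averaging no longer buys
   noise reduction beyond the band's independent sub-bands, and fine
   spectral resolution pays off exactly when effects have fine
   structure.
3. **Event-related potentials** — at each stimulus onset, a P100
   (Gaussian bump peaking at 100 ms, sigma 20 ms) plus a P300 (peak
   350 ms, sigma 80 ms) with level-dependent peak amplitudes, scaled per
   recording system (`system_gain`, default cap 1.0 / ear 0.4, reflecting
   the smaller ERP amplitudes of ear electrodes). EOG channels receive no
   ERP.
4. **Blinks** — a 400 ms biphasic template at Poisson-distributed onsets
   (default 15/min, 120 uV with 30% amplitude jitter), applied through a
   fixed rank-one spatial pattern: weight 1.0 on EOG channels, 0.7 at
   Fpz, decaying toward posterior and ear channels. The exact time course
   and unit-norm pattern are attached to `Recording.ground_truth`.
5. **Sinusoidal interference** — a fixed-frequency sinusoid (default
   50 Hz, 2 uV) weighted strongest on in-ear channels, mimicking
   equipment interference concentrated near the ear electrodes.

Default condition effects: for the N-back task, power below 20 Hz
decreases with working-memory load (alpha most strongly, gain 0.6 at
2-back) while high-beta and gamma power increase (gain 1.15-1.30), and
P300 amplitude decreases with load (8 -> 6 -> 4 uV); the 1-back gains are
the geometric midpoint. For the arithmetic task, power increases
broadband with difficulty (gain 1 + 0.07 x (level - 1) in every band).

A second N-back profile, `EffectProfile.nback_narrowband()`, places the
same qualitative effects in ~2 Hz sub-bands with heterogeneous signs at
fine frequency scale: the lower alpha half is strongly suppressed (gain
0.55) while the upper half is mildly enhanced, and narrow gamma slices
over 46-50, 60-70 and 80-95 Hz alternate between enhancement (1.7) and
suppression (0.6) with net enhancement. This is the regime of individual
alpha peaks and circumscribed gamma effects, and it is the study
condition for the parameter-recovery checks: fine spectral feature
models resolve each independently modulated sub-band, coarse band
features partially cancel the alternating structure, and cut-offs at 80
or 45 Hz discard the high-gamma information — reproducing the two
qualitative classifier trends (accuracy falls with coarser resolution
and with lower cut-off frequency).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: volume conduction and spatially correlated
sources (channels are independent), non-stationarity within a block,
muscle/movement artifacts other than blinks, subject-specific spectra,
behavioral responses. The generator validates the *pipeline*, not
physiology.

## Preprocessing

Band-pass 0.5-100 Hz: a cascade of a 2nd-order Butterworth high-pass and
a 10th-order Butterworth low-pass, both applied forward-backward
(zero-phase; offline analysis). The orders were chosen to keep the
squared-magnitude passband within 1 dB over [2·low, 0.9·high] while
rejecting DC completely. Resampling to 256 Hz uses polyphase anti-alias
filtering; only downsampling is supported.

Epoching: stimulus-locked epochs run from -500 ms to +1500 ms around each
stimulus with per-channel baseline correction over [-200, 0) ms (epochs
extending past a recording edge are dropped with a warning); fixed-window
epochs are 2 s windows every 1 s placed strictly inside each block, so a
60 s block yields 59 windows. All windows are half-open in samples.

Artifact rejection replaces visual trial inspection with an automatic
peak-to-peak criterion on non-EOG channels. The default limit of 200 uV
was calibrated once against the generator defaults (after blink removal)
so that fewer than 5% of trials are rejected while a 10x amplitude spike
is still caught.

Blink removal is specified as a contract, not an algorithm: after
cleaning, (a) frontal channels correlate < 0.2 with the generator's known
blink time course, and (b) alpha band power on blink-free segments
changes by < 5%. The implementation fits FastICA on 5x-decimated data
(the unmixing is purely spatial), automatically selects up to three
components whose time courses correlate >= 0.6 with a 6 Hz-low-passed EOG
reference, and subtracts each selected component *gated* to the segments
where its amplitude exceeds 4 robust SDs (dilated 200 ms, smoothed with a
100 ms ramp). Gating is what makes contract (b) achievable: subtracting
the full component time course removes a share of genuine ongoing
activity from high-loading channels, which we measured at up to ~25% of
quiet-segment alpha power on EOG/frontal channels. If the decomposition
fails or no component passes the threshold the recording is returned
unchanged with a logged warning.

## Spectral and temporal features

PSDs are one-sided Hann-window periodograms per 2 s epoch (native grid
0.5 Hz at 256 Hz), density-scaled so the integral equals the
window-compensated mean square. Six binning models aggregate the grid
(counts per channel at the 100 Hz cut-off): bin05 — every native bin
(200); bin1 — 1 Hz bins centered on 1..100 Hz, each averaging the native
bins at k-0.5 and k (100); mixed5 — delta/theta/alpha plus 5 Hz-wide
half-open bins over 13-100 Hz, last bin truncated (21); band12 — delta
through beta2 plus 10 Hz gamma bins (12); band7 — the seven canonical
bands (7); band5 — delta, theta, alpha, beta 13-30, gamma 30-cutoff (5).
Cut-offs of 45, 80 and 100 Hz truncate the upper bins; band7 at 45 Hz is
rejected (it would duplicate the mixed5 features). Shared edges between
adjacent constructed bins are half-open so no native bin is counted
twice; band features are the *mean* PSD over their native bins (bands of
unequal width stay comparable, and downstream statistics are invariant to
this monotone choice).

Temporal features (N-back only) are the 20 Hz-low-passed, 100
Hz-resampled amplitudes at 0, 10, ..., 990 ms after stimulus onset (100
per channel); the grid starts at 0 ms — either convention gives 100
features. Fusion concatenates bin1 spectral and temporal features (200
per channel). A 4-point centered moving average (shrinking edge windows)
exists for display smoothing only and is never part of a feature set.

For cross-subject band-power summaries, each subject-band is divided by
its own 90th percentile (linear interpolation between order statistics),
and boxplot summaries use whiskers at 2.5 x IQR with values above 2.5
flagged as extreme and clipped for display.

## Statistics

Condition comparisons use a label-permutation test on the difference of
condition means (the natural statistic for the band-power framing;
permutations shuffle labels without replacement, 5,000 by default). The
observed statistic is standardized against the permutation null
(mean/SD), giving a signed z — positive when the more demanding condition
is higher. Significance uses the one-tailed normal threshold on |z|:
alpha 0.01 <-> |z| > 2.3262, alpha 0.001 <-> |z| > 3.0902; this
convention reproduces both printed z/p pairs. Per subject, one-tailed
p-values over all (channel x cell) comparisons are Benjamini-Hochberg
adjusted at alpha (BH rather than BY: it is the procedure plainly called
"the FDR method", and the realized per-subject thresholds it produces lie
in the expected sub-alpha range); heatmaps count per cell how many
subjects survive correction. The permutation statistic choice (mean
difference vs a t statistic) does not affect the threshold conventions.

## Classification

swLDA codes the two classes as -1/+1 and regresses on mean-centered
features by ordinary least squares (no variance scaling: partial-F tests
are scale-invariant). Forward step: among excluded features, the
candidate whose partial F (equivalently, squared partial correlation with
the current residual) has the smallest p-value enters if p < p_in = 0.1.
Backward step: after each inclusion, any retained feature with partial
p > p_out = 0.15 is removed, largest first. p_in < p_out prevents
add/remove cycling; a cap of 60 forward inclusions (a conventional
budget, configurable) bounds the loop regardless. The final weights are
the least-squares solution on the selected features; the decision
threshold is the midpoint of the class mean scores. If no feature passes
p_in the model predicts the majority class and is flagged.

Cross-validation uses a frozen round-robin partition (trial i -> fold
(i mod 10) + 1), identical across feature models of a subject, so model
comparisons are paired fold-by-fold. The reported selected-feature count
is the per-fold mean; a full-data fit gives its own count separately.
Chance level follows the Combrisson-Jerbi binomial inversion: the
(1 - alpha) quantile of Binomial(n, 1/2) as a percentage of n, which
gives 57% at 500 trials and alpha 0.001. Models are compared with a
two-sided paired t-test on per-(subject, fold) accuracies at alpha 0.001.

## Problem sizes and numerical choices

The statistical-validity checks run at alpha 0.05 with 1,000 permutations
and the type-I/null-classifier simulations use 10-20 repetitions; the
parameter-recovery runs use one full-scale synthetic subject per task and
5,000 permutations. These sizes keep the whole suite desk-scale while
leaving the binomial/Monte-Carlo error far below the tested margins.
Degenerate inputs fail loudly: zero permutation spread, non-positive
normalization percentiles, empty p-value lists and single-class training
sets all raise errors rather than returning silent defaults. Constant or
collinear feature columns are skipped during selection, not fatal.

## Known limitations

- Independent-channel synthesis means spatial filters (re-referencing,
  ICA) face an easier problem than on real, volume-conducted EEG.
- The fixed-window count of 59 per 60 s block follows from strict-inside
  placement; pipelines that pad or center differently may count 58.
- The permutation test treats epochs as exchangeable. Overlapping fixed
  windows are weakly correlated, and — more importantly — slow band-power
  modulation combined with block-wise condition assignment makes
  trial-level permutation intrinsically anticonservative (this caveat
  applies to real EEG too). The null profile therefore disables the slow
  modulation so that the type-I validity checks test the statistics
  under their own assumptions.
- EDF recordings can be read (via mne) but not written; the native
  on-disk format is the documented float32 matrix container with a JSON
  sidecar.
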