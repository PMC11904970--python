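# Methods

`flavorsense` re-implements, as a tested library, the analysis chain for a
flavor-perception experiment in which participants sip and swallow a drink
while 64-channel EEG, two submental EMG electrodes and transcutaneous
auricular vagus nerve stimulation (tVNS) run concurrently. The chain has
four measurement stages — swallow detection, swallow-locked ERPs, eye-blink
rate, and a family-structured statistical plan — plus a synthetic-session
generator that provides ground truth for every stage.

## Session model

A session is seven contiguous blocks: five-minute rest blocks and two
ten-minute sipping blocks (#2 and #5). The stimulator is active in blocks
#4–#6 with a 30 s on / 30 s off duty cycle; the on half-cycle is taken to
start at the block boundary, so off windows are [30, 60), [90, 120), … s.
Each sipping block carries 10 cue cycles of five sip cues. Cue cycles occupy
the off half-cycles only (antisynchronization), so the 10 cycles tile the
600 s block with one cue window every 60 s; within a 30 s cycle, cues sit at
(j + ½)·6 s offsets, giving 6 s spacing with a 3 s guard on either side of
the on/off transitions. The same placement is used in the unstimulated
sipping block so both sipping blocks share a cue geometry. A consequence of
the alternate-window placement is that with one sip per cycle consecutive
cues are one full duty period (60 s) apart, not one cycle length; the
antisynchronization constraint was given priority over contiguous cycles.

Conventions everywhere: 0-based sample indexing, half-open intervals
[start, end), amplitudes in µV, API times in ms converted to samples by
flooring. The native container is HDF5 (`/signal`, `/markers`, `/meta`);
BrainVision is read-only, with marker descriptions mapped through a
caller-supplied dictionary because annotation naming is site-specific, and
marker positions taken from the `.vmrk` table directly (1-based data
points) so out-of-range markers raise instead of being silently dropped.

## Synthetic sessions

The generator renders, additively:

* **EEG**: 1/f (exponent 1) background noise, default SD 10 µV per channel.
  Pink noise is the standard resting-EEG texture; it also stresses the
  detectors with realistic slow excursions.
* **Blinks**: raised-cosine "tents" (default 300 ms, 150 µV) on Fp1, Fp2,
  AF7, AF8 with channel gains (1.0, 0.95, 0.7, 0.65) and ±15 % lognormal
  amplitude jitter; counts are Poisson with per-block rates (defaults
  15/min rest, 20/min sipping, reflecting the consumption-related increase
  the measure is meant to expose).
* **Swallow bursts** on the two EMG channels with opposite polarity (so the
  bipolar montage recovers the full burst): broadband noise carriers under
  a raised-cosine envelope, default 800 ms and 30 µV peak envelope over a
  2 µV white baseline. One cued burst per cue at a truncated-normal latency
  (mean 1000 ms, SD 300 ms, support [0, 4000) ms) plus Poisson spontaneous
  bursts (default 1/min) that never overlap existing bursts.
* **Swallow-locked potential**: raised-cosine time course (200 ms wide,
  peak 500 ms after the EMG peak — the window where real responses
  concentrate) times a smooth spatial profile, default 5 µV.
* **Stimulation artifact**: 25 Hz pulse train during on half-cycles,
  rendered as ±1-sample biphasic pairs. A 250 µs pulse cannot be resolved
  at 1 kHz; only duty-cycle timing matters to the pipeline, so no
  band-limited pulse shape is modelled.

Cohorts assign the four stimulation locations (sham, C, T, CT) to sessions
with the four Williams orders, round-robin over participants, matching the
reported allocation (4, 4, 4, 3 for n = 15). Per-participant lognormal
random effects (SD 0.1) scale blink rate and burst amplitude; an effect map
can multiply blink rate, burst amplitude or ERP amplitude per location and
block. Sessions are yielded lazily to bound memory.

What the generator does **not** emulate: eye movements other than blinks,
ECG/EMG crosstalk into EEG, electrode drift and impedance changes, subject
motion, or any physiologic response to stimulation. Recovery results on
synthetic sessions therefore certify the detectors' logic and calibration,
not their performance on recorded data.

## Swallow detection

Per block, on the bipolar submental derivation (configurable to a single
electrode or the mean): DC removal → 5th-order Butterworth 25–400 Hz →
mains notch (50 Hz, Q 30) → Teager–Kaiser energy operator → sym4 wavelet
decomposition keeping the level-4 approximation (≈ < 31 Hz envelope content
at 1 kHz) → sliding RMS (50 ms window, 10 ms step, interpolated back to one
value per sample). All filtering is forward–backward so reported latencies
carry no filter delay. The stage order (TKEO before the smoothing stages)
follows the burst-onset-detection convention of the method's sources.

The detection threshold is envelope median + 5·MAD per block — an
algorithmic stand-in for the original per-block visual threshold; a manual
override remains in the config. Suprathreshold runs merge across gaps
< 200 ms and must last ≥ 200 ms; the burst peak is the envelope argmax
(earliest sample on ties). A burst peaking in [cue, cue + 4000 ms) is a
*cued* swallow if it is the first for that cue; later bursts in the window,
and all bursts outside every window, are *spontaneous*. If malformed input
makes adjacent cue windows overlap, the earlier cue claims the burst.
Features per swallow: peak latency re cue, envelope peak amplitude, and
trapezoidal AUC over the burst run (µV·ms), computed on the RMS envelope
(a config switch computes them on the rectified wavelet approximation
instead, since the source description is ambiguous on this point).

## Eye-blink rate

Per block and frontal channel: zero-phase 1–20 Hz bandpass; candidate
intervals are maximal runs strictly above mean + 1.5·SD (both moments per
block, since consumption changes the signal statistics between blocks). A
run containing several prominent maxima — two blinks fused into one run —
is split at the valley between peaks (prominence ≥ 1.5·SD). Candidates are
scored by Pearson correlation against a raised-cosine prototype rescaled to
the candidate length (±100 ms context) and by SNR = peak amplitude over the
SD of the signal outside all candidate intervals; acceptance requires
correlation ≥ 0.90 and SNR ≥ 2.0. The block's rate is taken from whichever
of Fp1/Fp2/AF7/AF8 keeps the most accepted blinks (ties resolved in that
order). Blocks shorter than 3 min are computed but flagged unreliable.

The correlation and SNR thresholds are conservative defaults; the source
algorithm's exact values are not published. Absolute rates are therefore
not interpretable — overlapping or contaminated blinks are discarded by
design (recovery on synthetic sessions runs ≈ 5–10 % low), and pure 1/f
noise with no blinks at all still yields occasional false accepts because
the thresholds are relative and slow pink-noise bumps are genuinely
tent-shaped. Within-session block *differences* are the meaningful output.

## Swallow-locked ERPs

EEG channels are bandpassed 1–50 Hz (zero-phase, order 6 so the
forward–backward gain at 60 Hz stays below 0.1), re-referenced (average
reference by default; the original recording reference was FCz), and
epoched −2000…+1999 ms around each swallow peak — 4000 samples at 1 kHz.
Peaks too close to a recording edge are dropped with reason `edge`. No
baseline correction is applied by default; a pre-window baseline is
available in the API.

Two single-pass rejection criteria follow:

* **Joint probability**: per channel, a histogram (Freedman–Diaconis bins)
  of all epoch samples gives an empirical amplitude distribution; each
  epoch's mean log-probability is z-scored across epochs, and an epoch is
  rejected when any channel exceeds |z| > 5 or the channel aggregate
  exceeds |z| > 3.
* **Kurtosis**: excess kurtosis per epoch × channel, z-scored the same way
  with the same thresholds. Constant epoch-channels have undefined kurtosis
  and are rejected with reason `degenerate`.

Rejection is single-pass (no iterative re-estimation) for determinism, and
with fewer than 10 epochs both criteria accept everything, since the
across-epoch z-scores are not meaningful. ICA-based ocular pruning is a
pluggable stage: a precomputed mixing/unmixing pair plus exclusion list is
applied after epoching (the ordering the original pipeline used); the
decomposition itself is outside this package. Retention bookkeeping always
reports accepted + rejected = total and the retained percentage to one
decimal.

## Statistics

Repeated-measures ANOVA is computed through orthonormal (Helmert)
contrasts: for an effect with contrast matrix C, per-participant scores
z_i = C y_i give SS_eff = n‖z̄‖² and SS_err = Σᵢ‖zᵢ − z̄‖², with
df₁ = Π(k_f − 1) and df₂ = df₁(n − 1). Greenhouse–Geisser epsilon is
tr(E)²/(df₁·tr(E²)) with E the covariance of the scores (the Kronecker
contrast is used for interactions), clipped to [1/df₁, 1]; k = 2 forces
ε = 1. Effect size is partial eta squared. Corrected and uncorrected dfs
and p-values are always reported side by side, since published tables mix
both conventions. Participants with missing cells are dropped listwise.
Session order enters, when requested, as a between-participant blocking
factor in a split-plot variant whose interaction term decides whether
order-adjusted statistics are reported.

Holm (step-down) and Benjamini–Hochberg (step-up) adjustments are delegated
to statsmodels and applied within declared families; mass-univariate
one-sample and paired t maps record zero-variance points as missing rather
than ±∞.

The cluster-based permutation test thresholds the observed t (two-sided
95th-percentile quantile by default) or F map (95th percentile), clusters
suprathreshold points over channel adjacency (Euclidean sensor distance
below threshold) plus temporal adjacency, sums the statistic as cluster
mass (positive and negative t clusters kept separate), and builds the null
from the permutation distribution of the maximal mass: participant sign
flips for one-sample/paired designs (enumerated exhaustively when 2ⁿ does
not exceed the requested count), within-participant label permutation for
factorial designs. Cluster p = (1 + #{perm max ≥ observed})/(n_perm + 1),
so the smallest attainable p is 1/(n_perm + 1). Sign-flip t maps are
computed in closed form for all flips at once (the per-point sum of squares
is flip-invariant), which keeps a 500-permutation test on 15 × 16 × 100
data below half a second.

### Calibration

The test's family-wise error under the null is measured by simulating
paired two-condition datasets of pure 1/f noise (15 subjects, 16 channels
on a 4 × 4 grid adjacency, 100 time samples, 500 permutations) and counting
datasets with any cluster p < 0.05. At 200 datasets the acceptance suite
requires the empirical rate not to exceed 0.05 beyond the binomial 95 %
margin (≈ 0.08). The same computation, seeded, is what
`scripts/acceptance.py` reports.

## Problem sizes in the test suite

Structural tests run sessions at 100–250 Hz with 4 EEG channels; the
swallow detector is exercised at the full 1 kHz (its passband requires it)
with the minimal 4-channel EEG montage; recovery claims average 20 seeds.
These sizes were chosen so the whole suite certifies every stage at
realistic signal scales while remaining comfortably runnable on one CPU.

## Known limitations

* The blink detector's absolute rates depend on unpublished thresholds of
  the reference algorithm; only block contrasts are interpretable.
* The joint-probability criterion uses per-channel histograms, not kernel
  densities; very small epoch counts fall back to accept-all.
* The two-way GG epsilon for interactions follows the contrast-covariance
  definition; other packages differ on this term (and warn that they do).
* The factorial cluster-permutation null permutes full condition labels
  within participants, which is approximate for main effects in the
  presence of other effects; the paired/one-sample sign-flip null is exact.
* BrainVision support covers the common multiplexed binary dialects that
  the underlying reader handles; vectorized/ASCII dialects raise an
  explicit unsupported-dialect error.
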