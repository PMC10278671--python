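# Methods

This note documents the models and numerical choices behind `readrhythm`:
what the synthetic generator plants and why, how each inference stage is
calibrated, and where genuinely open design decisions were resolved.

## The synthetic cohort

The generator emulates the structure of a co-registered reading corpus:
12 participants, ~300 sentences in six equally sized blocks, eye-tracking
and EEG both sampled at 500 Hz, fixations averaging 220 ms (SD 25 ms),
~21% backward (regressive) saccades, sentences read in ~7.4 s (SD ~2.6 s).
These are the generator defaults (`SimulationConfig`); analysis runs in the
test suite and acceptance script use fewer sentences per participant so
each simulation stays within seconds while keeping every rate and moment at
its default value.

**Ocular events.** Saccade onsets form a gamma renewal process
(default shape 10) with mean interval `1/sacc_rhythm_hz` (4.4 Hz). Shape 10
gives a unimodal spectral peak with realistic timing jitter; shape 1
(exponential intervals, a Poisson process) is the null condition for
spectral calibration, and the inter-onset floor is a minimal 2 ms
anti-collision clamp so that the exponential null is not distorted by an
artificial refractory period. Recorded fixation durations are drawn from
`mean_fix_ms + fixdiff_amp_ms·sin(2π·fixdiff_rhythm_hz·t + φ_p) + N(0, sd_fix_ms)`,
truncated to [60, 1000] ms, with `final_lengthening_ms` added on
sentence-final words (the wrap-up effect). Duration values are deliberately
decoupled from event timing: the clock advances by expected rather than
realized durations. If realized (modulated) durations fed back into onset
times, a circle-map entrainment would lock sentence-final onsets to the
duration modulation and plant a boundary phase effect even at zero boundary
locking — the null conditions would not be null. Regressions are inserted
after eligible words with a probability calibrated (including an
eligibility correction for the first two and final words of a sentence) so
the long-run backward-saccade fraction equals `p_regression`.

**EEG.** Each scalp channel carries 1/f-shaped Gaussian background noise
(exponent 1, SD 1 in signal units). On designated posterior channels a
theta component (default 5 Hz, amplitude 1) is *entrained* to saccades: its
phase trajectory passes exactly through a von Mises(0, `theta_lock_kappa`)
angle at every saccade onset, interpolating smoothly (frequency modulation)
in between. This keeps the signal narrowband — hard phase resets would
splash energy across the spectrum and the wavelet-measured phase at onsets
would no longer reflect the planted concentration. κ = 0 draws uniform
angles, which is exactly "no locking". On designated occipital channels a
delta component shares the phase of the fixation-duration modulation with
coherent weight `I₁(κ)/I₀(κ)` at κ = `delta_lock_kappa` (the mean resultant
length of the matching von Mises distribution), the remainder being an
independent oscillator with slowly diffusing phase. When
`boundary_lock_kappa` > 0, the coherent delta phase is additionally steered
toward a von Mises angle at each sentence-final fixation onset (reset
300 ms before the onset, relaxing over 1.5 s). EOG channels follow a
latent step-wise gaze trajectory (horizontal word position, vertical line
position, ~1% samples lost) and leak into scalp channels through an
anterior-weighted mixing matrix; because the leakage is linear in the
recorded EOG, least-squares regression removes it exactly, which the
acceptance suite verifies to numerical precision.

What the generator does **not** emulate: 2-D gaze coordinates and spatial
preprocessing, saccade kinematics, parafoveal preview, volume conduction
with real head geometry, non-stationary artifacts (blinks, drifts), or
evoked (as opposed to oscillatory) EEG responses. Passing tests therefore
demonstrate the correctness and calibration of the *analysis chain* on
data satisfying its assumptions, not robustness to everything real
recordings contain.

## Eye series

Thresholds are read literally: fixations with 60 ≤ duration ≤ 1000 ms and
saccades with duration ≤ 80 ms are kept (boundaries inclusive). Duration
differences are never computed across block boundaries (recalibration gaps
are non-reading time) but are computed across sentence boundaries within a
block, since the long Welch windows necessarily span sentences. Outside its
anchor support the fixdiff series is masked undefined rather than
zero-padded — zero-filling would inject spurious low-frequency power.
Event-to-sample mapping rounds to the nearest sample with ties rounding up.
The binary train is rebuilt (not decimated) when a lower rate is needed;
the fixdiff series is decimated with an anti-alias FIR low-pass.

## Spectral inference

Welch PSD uses Hamming tapers and per-segment mean detrending (the taper
was an open choice; Hamming is a common default), with segments drawn only
from fully defined stretches. Surrogates: duration shuffles over fixed
onsets (fixdiff) and time shuffles of the binary vector (saccade train),
200–1000 per participant, paired across participants by permutation index.
Both surrogate ensembles are computed by exact fast paths — a direct sparse
DFT over event positions for the binary train, and a vectorised
linear-interpolation gather for fixdiff — verified in the test suite to
equal the naive rebuild bit-for-bit. The per-frequency p-value is the
add-one rank `(1 + #{perm ≥ obs}) / (1 + n_perm)` of the observed group
mean in the surrogate group means (the "exceeds 95% of permuted values"
decision rule, as a valid p-value), followed by Benjamini–Hochberg FDR at
q = 0.05 across frequencies.

A consequence of rank-based p-values worth knowing: with `n_perm`
surrogates the smallest attainable p is `1/(n_perm+1)`, so a spectrally
*narrow* planted modulation (a pure sinusoid occupying 1–2 grid bins) can
fail BH correction across a wide analysis band even when its peak beats
every surrogate — the acceptance report shows the recovered peak frequency
alongside the count of FDR-significant bins for exactly this reason.

## EEG conditioning

High-pass (0.1 Hz) and notch (50 ± 3 Hz) filters are Hamming-windowed
linear-phase FIRs applied by centred convolution (group delay compensated,
net zero phase), with reference orders 16 500 and 826 at 500 Hz scaled to
the sampling rate and capped below the signal length for short synthetic
recordings. The channel mean is removed before high-passing so DC is
rejected exactly. EOG regression projects each scalp channel onto the EOG
channels plus intercept over the whole recording (per-block regression was
an open choice; whole-recording is the default) and reports the per-channel
removed variance as the topography of ocular activity. Clock
synchronization fits an affine map (offset + drift) to shared block
markers by least squares.

## ISPC and coherence inference

Morlet wavelets use 5 cycles (configurable); the implementation is a batch
FFT convolution verified against MNE's `tfr_array_morlet` to ~10⁻⁶
relative accuracy, and samples within half a wavelet length of either edge
are flagged invalid per frequency. Saccade-locked epochs (±200 ms) are
dropped when they touch a sample invalid at the lowest analyzed frequency,
which quantifies the "epochs near block edges are disregarded" rule.

Raw ISPC has a frequency-dependent floor under the null: phases of slow
components decorrelate over many inter-saccade intervals, so neighbouring
epochs are dependent and the expected resultant length rises toward low
frequencies. Comparing each frequency only against the mean of the other
frequencies leaves that profile in place and breaks the sign-flip null
(every null simulation produced a "significant" low-frequency cluster).
The pipeline therefore first subtracts a per-participant floor estimated
by circularly shifting the whole onset train within the valid region
(default 8–16 shifts) — preserving both the EEG autocorrelation and the
train's interval structure while destroying genuine alignment — and then
applies the nontarget-frequency baseline and the cluster test. With this
correction the empirical null cluster rate is at the nominal level (checked
over 40 simulations in the acceptance suite) while planted theta locking
is detected reliably.

Cluster inference: per-cell paired one-tailed t across participants
(cluster-forming threshold α = 0.05, an open choice resolved to the field
default), suprathreshold cells clustered by sensor adjacency (distance
below 1.5× the median nearest-neighbour spacing) plus grid adjacency in
frequency and lag, maximum cluster-sum t as the permutation statistic,
sign-flip null enumerated exhaustively when `2^n ≤ n_perm` (exact rank p
including the identity) and sampled with an add-one p otherwise.

Multitaper coherence uses per-epoch DPSS families with time-halfbandwidth
`duration × 0.5 Hz`, per-epoch mean removal, zero-padding to a shared
transform length chosen so the 0.5 Hz grid falls exactly on FFT bins, and
pooling of cross-/auto-spectra jointly over epochs and tapers. Sentences
shorter than 2 s are dropped before epoching.

## Boundary phase

Signals are low-passed at 2.5 Hz (8th-order Butterworth, forward–backward),
Hilbert-transformed, and read out at the sample nearest each
sentence-final fixation onset; angles follow the cosine convention (0 at a
signal peak) in (−π, π]. The observed statistic is the participant-mean
Rayleigh `z = n·R̄²`; each of the (default 1000) surrogate draws samples,
per participant, as many non-final fixation onsets as that participant has
final ones (without replacement when possible, flagged otherwise), and the
add-one rank of the observed mean in the surrogate means is the p-value,
FDR-corrected across electrodes when several are tested. The default
electrode set is the significant low-frequency coherence cluster, falling
back to the channel with maximal low-frequency coherence. The same test
applied to the fixdiff series is supported and reported — on synthetic data
with planted final lengthening it is typically significant, since the
lengthening itself is ground truth there.

EOG regression matters for this test on realistic data: the latent gaze
trajectory (return sweeps) is genuinely sentence-locked, so unremoved
ocular leakage produces boundary phase clustering of purely ocular origin.
The acceptance suite runs the boundary analysis on regression-cleaned
channels for exactly this reason.

## Problem sizes

The test suite and acceptance script scale the cohort down (5–20 sentences
per participant, 4–16 channels, 200–1000 surrogates, 256–4096 sign-flip
permutations) while keeping every generative rate, moment and coupling at
its corpus-like default; detection checks are repeated over 20 seeded runs
and null calibrations over 40, with Monte-Carlo tolerances of two standard
errors on the nominal 5% level.

## Known limitations

* The sign-flip cluster test assumes symmetric per-participant differences
  under the null; the shift-surrogate correction makes this hold to good
  approximation but not exactly.
* The boundary surrogate treats non-final fixations as exchangeable with
  final ones; temporal autocorrelation within sentences makes individual
  draws mildly dependent, which the participant-mean statistic absorbs.
* The generator's theta entrainment ties the oscillator's instantaneous
  frequency to saccade timing; dissociating "oscillation vs. sequence of
  evoked responses" is out of scope by design.
* EDF files can be read (via MNE) but not written; the native interchange
  format is CSV + JSON sidecar.
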