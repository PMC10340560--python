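# Methods

`eegfocus` implements a two-stage decision-support pipeline for temporal
lobe epilepsy (TLE) on bipolar scalp EEG: first, ictal (during-seizure)
versus interictal (between-seizure) classification of fixed-length epochs;
second, lateralization of the epileptic focus to the left or right
hemisphere from the energy asymmetry of symmetric channel pairs.

## Montage

Recordings use 18 longitudinal bipolar 10–20 derivations. The two midline
channels (Fz-Cz, Cz-Pz) carry no left/right information and are dropped
for analysis, leaving eight symmetric (left, right) pairs:
(Fp1-F7, Fp2-F8), (F7-T3, F8-T4), (T3-T5, T4-T6), (T5-O1, T6-O2),
(Fp1-F3, Fp2-F4), (F3-C3, F4-C4), (C3-P3, C4-P4), (P3-O1, P4-O2).
The canonical 16-channel order is pair-major (eight left members, then
eight right members), so pair *i* is always the index pair (i, i+8) —
the lateralization stage never needs a name lookup. Channel-name matching
is case-insensitive and treats `-`/`_` as the same separator, since EDF
label conventions vary.

## Preprocessing

1. **Low-pass** Butterworth, cutoff 64 Hz, applied forward–backward
   (zero-phase) so waveform morphology is preserved. The single-pass
   order is 6; zero-phase application squares the magnitude response,
   giving ≈56 dB attenuation at 100 Hz and <0.001 dB deviation at 5 Hz.
   Order 6 was chosen so the stopband contract (≥40 dB at 100 Hz)
   holds; an order-4 design, a common default, only reaches ≈31 dB there.
2. **Notch** at 50 Hz (second-order IIR, 2 Hz −3 dB bandwidth,
   zero-phase) for power-line noise. This matters even though 50 Hz is
   below the low-pass cutoff: after resampling, 50 Hz lands inside the
   32–64 Hz detail band and would otherwise contaminate its energy.
3. **Resampling** to the 128 Hz analysis rate by polyphase rational
   resampling. 128 Hz is the one rate at which a nine-level dyadic tree
   reproduces the nominal band table exactly (D1 = 32–64 Hz down to
   A9 = 0–0.125 Hz, i.e. band edges at Nyquist/2^k with Nyquist 64 Hz).
   The 64 Hz cutoff sits at the new Nyquist; the resampler's own
   anti-aliasing filter guards the decimation.
4. **Epoching** into consecutive, non-overlapping windows of 4096
   samples (32 s at 128 Hz); the trailing partial window is discarded.
   An epoch is ictal when ≥50 % of its samples fall inside ictal
   annotations — annotations label intervals, not epochs, and majority
   occupancy is the least surprising conversion. Epochs covered by no
   annotation default to interictal (seizures are islands in an
   interictal background); an `exclude` policy is available.

All sample intervals are half-open `[start, end)`, 0-based.

## Subband energies

Each epoch channel is decomposed with a nine-level discrete wavelet
transform (Daubechies db4, periodization boundary). db4 is orthonormal
and periodization makes the transform square, so the coefficient energies
of {D1..D9, A9} sum exactly to the signal energy (checked to 1e-8
relative; in practice machine precision). Energies are therefore computed
on coefficients directly — no band-limited reconstruction is needed.

The D2 set (16–32 Hz) is split once more with a single-level db4 DWT to
separate beta (16–24 Hz) from gamma (24–32 Hz). Inside a detail subband
the frequency axis is mirrored by the decimation, so the *detail* child
of D2 is the lower half and the *approximation* child the upper half;
the package maps children to bands by physical frequency and verifies the
orientation with sine-probe tests. Composite bands: Delta = D5+…+D9+A9
(0–4 Hz), Theta = D4, Alpha = D3. Thirteen named bands are exposed; Beta
is the default classifier feature (rhythmic ictal discharges in TLE are
typically beta/theta-band).

The feature for one epoch is the vector of per-channel band energies
(µV²·samples), 16 values in the default lateral-channel mode.

## Epoch classifier

A single-layer LSTM with 128 hidden units over the per-epoch energy
vector (presented as a length-1 sequence), followed by a fully connected
layer and softmax. The network, backpropagation-through-time, Adam, and
global-norm gradient clipping are implemented directly on numpy — the
model is small enough that a framework would add nothing but a heavier
dependency — and the analytic gradients are verified against finite
differences in the test suite.

Training options: mini-batch 150, up to 100 passes, Adam at initial
learning rate 0.001, gradient-norm threshold 2, cross-entropy loss.
Features are standardized per column with training-split statistics
before the network: raw band energies span orders of magnitude and
unscaled input stalls training. Model selection keeps the parameters of
the pass with the best validation accuracy.

Data handling:

* **Split** 70/15/15 train/validation/test, stratified by label and
  shuffled by seed.
* **Balancing**: clinical data are heavily imbalanced (on the order of
  one ictal epoch per twelve interictal). Each ictal *training* row is
  duplicated k = round(n_interictal / n_ictal) times, bringing the class
  ratio into roughly [1/2, 2]. Without this a classifier reaches high
  accuracy by calling everything interictal (accuracy 12/13 ≈ 0.92 with
  zero sensitivity on 1:12 data). Balancing runs strictly after
  splitting and only on the training split, so no duplicate of a
  validation or test row can leak into training. Interictal rows and all
  feature values are never altered.
* Splits are epoch-wise by default; recordings of one patient may span
  splits. A subject-wise split can be emulated by partitioning the
  recording list before feature extraction.

Evaluation reports the confusion counts with ictal positive, plus
accuracy, sensitivity (TPR) and specificity (TNR).

## Lateralization

Seizure activity raises signal energy on the focus side. For each
symmetric pair, the asymmetry score over the ictal samples is

    A = Σ x_left[n]² / Σ x_right[n]²

computed on the broadband preprocessed signal (a band-restricted variant
would only require swapping the energy source). Decision rules:

* pair vote: +1 if A > 1, else −1. A = 1 exactly votes −1 — the rule
  defines only A > 1 and A < 1, and folding the boundary into the
  right-sided else-branch keeps the vote total an even-stepped integer;
  the event has measure zero on real signals.
* recording: votes of the eight pairs are summed; sum > 0 → left,
  otherwise (including 0) → right.
* patient: majority over the patient's recording-level sides; a tie
  again falls to right, mirroring the else-branch convention.

Per-pair energies are pooled across all ictal epochs of a recording (sum
energies, then one ratio per pair); a per-epoch-majority mode is provided
as an option. A pair whose right channel has exactly zero pooled energy
is excluded from the vote instead of contributing an infinite score.
Ictal epochs can come from expert annotations (`gold`) or from the
classifier (`predicted`); both are supported because either is a
defensible deployment mode.

Lateralization evaluation treats left as the positive class.

## Synthetic data

Real ictal EEG of focal epilepsy patients is rarely shareable, so the
generator produces cohorts with the statistical structure the method
relies on, at 500 Hz on the 18-channel montage:

* background: per-channel 1/f^α noise (α = 1; EEG spectra are
  approximately power-law) at 30 µV RMS, plus a 50 Hz power-line
  sinusoid at 10 µV;
* seizures: inside each annotated window, a rhythmic oscillation at a
  random frequency in 16–24 Hz, Hann amplitude envelope (no hard onset
  edge), random phase per channel, peak amplitude 70 µV — with the Hann
  envelope this puts the window-average oscillation power at
  approximately the background power (≈0 dB SNR) — added to all 16
  lateral channels;
* asymmetry: focus-side channels carry the oscillation scaled by
  γ = 1.5 in amplitude (2.25× in energy), the excess the lateralization
  stage detects;
* cohorts: one focus side per patient shared by all their recordings;
  per-recording seeds derive from (master seed, patient, recording)
  through `SeedSequence`, so cohorts are reproducible bit for bit.

What the generator does **not** model: artifacts (blink, EMG, electrode
pops), spike/sharp-wave morphology, seizure propagation and evolution,
inter-patient spectral variability, non-stationary background. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
recovers planted structure; they do not certify clinical performance on
real recordings.

## Problem sizes and numerical choices

* Tests and the acceptance script run on scaled-down cohorts (e.g. 12
  single-recording patients of ~6 minutes each for classification, 40
  recordings for lateralization recovery), sized so a full run completes
  in minutes on one CPU core. The classification cohorts are kept large
  enough (~130 epochs) that the 150-row mini-batch still yields a
  non-degenerate number of optimizer steps across 100 passes; far
  smaller cohorts starve the optimizer long before the method itself is
  at fault.
* The matrix on-disk format writes floats with `%.17g` and parses with
  round-trip precision, so write→read is bit-exact.
* EDF export quantizes to 16 bits; the writer reuses its own 8-character
  header rendering of the physical range so reader and writer agree on
  calibration exactly.
* Determinism: all randomness flows through explicit
  `numpy.random.Generator` objects seeded from configuration; pipeline
  reports are rendered with sorted keys so identical runs are
  byte-identical.

## Known limitations

* The classifier treats each epoch independently (length-1 sequences);
  temporal context across epochs is supported by the network but not
  exercised by the default pipeline.
* Lateralization assumes exactly one focus side; bilateral or
  multifocal cases are out of scope.
* No artifact rejection; a strongly asymmetric artifact (e.g. unilateral
  electrode failure) would bias the asymmetry votes. The degenerate-pair
  exclusion only guards the exact-zero case.
* Band names follow the dyadic grid (Alpha = 8–16 Hz, Beta = 16–24 Hz),
  which is close to, but not identical with, conventional clinical band
  limits.
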