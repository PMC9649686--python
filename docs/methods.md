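# Methods

## Signal model and preprocessing

A fingertip PPG record is modelled as a per-beat pulse waveform (systolic
upstroke, systolic peak P, dicrotic notch, diastolic — reflected — wave D)
on a respiratory baseline with additive broadband noise. Records are 60 s
at 500 Hz with three 20 s luminous-intensity segments; only the
medium-intensity segment is analysed (selection is by segment metadata,
with the middle third as a documented fallback when no map is present).

Filtering is a 4th-order Butterworth band-pass, 0.2–20 Hz, applied
forward–backward (`sosfiltfilt`). The order is a package choice: the
band edges fix what the filter removes (baseline wander below 0.2 Hz,
noise above 20 Hz), while the zero-phase application guarantees that no
group delay biases the interval features; with a causal filter every
timing feature would inherit a frequency-dependent shift.

**Onset detection.** A slope-sum function (sum of positive first
differences over a 128 ms window) is thresholded at 60 % of its trailing
3 s maximum with a 300 ms refractory period; the onset (systolic notch N,
the pulse foot) is the local minimum of the filtered PPG preceding each
triggering upstroke. Two pruning rules reject physiologically impossible
trains: onsets whose following 300 ms rise is below 45 % of the
90th-percentile rise amplitude (these are triggers on the *diastolic*
upstroke of deeply notched beats), and the weaker onset of any interval
shorter than 0.55× the median. On noiseless synthetic trains the
detected onsets sit within ±10 ms of the planted pulse feet with
sub-millisecond mean bias.

**Signal quality.** The SQI is the mean pairwise correlation of all beats
resampled to the median beat length (threshold 0.8), with hard failures
for fewer than 5 beats, ≥ 1 % of samples at an amplitude rail, or a
median rate outside 30–180 bpm. No quality criterion is standard in this
setting; a deterministic, documented gate is what makes cohort
accounting reproducible.

## Fiducial points

Each beat (onset-to-onset, half-open) is min–max normalized and
differentiated twice with central differences after a ~40 ms
moving-average smoothing. The smoothing window is deliberately wider than
a bare noise filter: the landmark rules below are *zero-crossing* and
*local-extremum* rules, and at realistic SNR (≈ 25 dB) they must see the
pulse, not the residual noise. All landmark rules therefore read the
smoothed waveform, and the width/area features are computed on the same
smoothed beat for consistency. Timing bias introduced by the symmetric
smoothing is absorbed by the closed-loop cohort calibration (below).

* P — maximum of the PPG within the first 60 % of the beat.
* A, B — first APG local maximum after the onset and the following local
  minimum (the systolic acceleration couple).
* E, F — largest APG local maximum after P (announcing the reflected
  wave) and the following local minimum, with an 80 ms guard band at the
  beat end so the next beat's upstroke curvature cannot masquerade as E.
* D — primary rule: first positive-to-negative VPG zero crossing after
  P (80 ms guard on both sides) whose PPG neighbourhood maximum is
  interior *and* preceded by a genuine dicrotic dip (≥ 1.5 % of the pulse
  amplitude below the candidate). If no crossing qualifies — the
  "inconspicuous diastolic peak" case, which is common in real
  recordings — D falls back to the F-projection, flagged
  `d_from_fallback`. The decision is per beat.

The interior-maximum and dicrotic-dip qualifications are the package's
operationalization of "inconspicuous": they reject noise-induced
crossings on the systolic shoulder, which would otherwise place D tens of
milliseconds early at moderate noise.

## Features

Time-domain features follow their standard contour-analysis definitions
(Tp = T_P−T_N, Td = T_D−T_N, HR = 60000/(T_{N+1}−T_N), RI = Y_D/Y_P,
SI = height/(T_D−T_P), T_RD, rising/falling slopes, the
systolic/diastolic area ratio by trapezoid, the signed APG ratios
Y_A/Y_B and Y_A/Y_E — VDab is typically negative and no absolute value is
taken — and the pulse widths at 25/50/75 % of the systolic peak with
linear interpolation). Per-record aggregation is the median over beats
(robust to residual artifact beats).

**Welch harmonics.** The PSD is the average of windowed periodograms
(segment length M = 4096, stride S = 1024 so consecutive segments overlap
by 3072 samples; any final partial segment is dropped; Hann window;
periodogram normalized by the window energy), converted to dB. The
harmonic powers O₁..O₆ are the dB values at the PSD local maxima nearest
k·f₀ (±0.3 Hz), f₀ = HR/60, and H₁..H₅ = O_{k+1}/O₁.

Because these are ratios of *dB magnitudes*, they depend on the absolute
dB reference. Signals are therefore standardized to a reference RMS of 12
(a nominal fingertip-device ADC amplitude) before PSD estimation. This
choice is load-bearing and deliberate: at unit-variance scaling the dB
values of a physiological pulse sit near 10–30 dB and the printed
physiological range of the ratios (H1 ≈ 0.85 falling to H5 ≈ 0.45) is
unreachable for smooth waveforms, whereas at a device-like reference the
natural harmonic profile of an ordinary pulse lands in exactly that
range. A linear-power ratio mode is available via the PSD object for
sensitivity analyses.

**Wavelet packets.** 8-level `sym6` decomposition in periodization mode;
terminal nodes are re-ordered from tree (Paley) order to natural
frequency order before band labelling, so band j covers
[(j−1)·0.977, j·0.977) Hz at 500 Hz. E1..E10 are the normalized energies
of the ten lowest bands (≥ 99 % of a clean pulse's energy); Eall is the
total energy, reported in dB as the feature. Energy conservation against
the raw sum of squares holds to < 1 %.

## Cohort statistics

Retention: subjects with fewer than five records are excluded first (the
filter is applied once — later exclusions do not retroactively drop a
subject), then records of subjects missing any required demographic field
(age, height, weight by default; height is required by SI), then records
failing the quality gate. The ledger reconciles counts at every stage.

Group comparison: two-sided Mann–Whitney U per feature, exact by
enumeration of labelings for combined n ≤ 12 (correct under ties) and the
tie-corrected normal approximation otherwise; significance at a flat
p < 0.01 with no multiple-testing correction (an optional Holm flag
exists but is off by default, matching common practice in this
literature).

## Risk models

Four families produce a continuous risk score in [0, 1]: logistic
regression (probability output) and support-vector, random-forest and
XGBoost *regressors* whose clipped predictions are read as risk scores.
Evaluation is ten-fold stratified CV at the record level: inside each
fold the training split is randomly down-sampled to class balance, the
Z-score transform (sample SD) is fitted on that balanced set, and the
untouched test split is scored. Sensitivity and specificity are reported
at the per-fold Youden-optimal threshold — the paired values reported for
this kind of balanced-training protocol imply a tuned threshold rather
than a fixed 0.5. Grid search maximizes mean five-fold AUC with ties
broken toward the simpler model. Record-level splitting means records of
one subject can appear in both train and test; subject-level grouping is
the stricter alternative and is recommended when subjects contribute many
records. All randomness derives from a single master seed through a
seed-derivation scheme.

## Synthetic cohort generator

Each beat template is built on one beat period from circularly wrapped
components (tails flow through the pulse foot, so the template is
periodic and the foot is a sharp minimum): a generalized-Gaussian
systolic wave (rise exponent 4 by default in calibrated cohorts — steep
foot, flat top, as real upstrokes have), a Gaussian-rise/slow-fall
diastolic wave, and a subtractive dicrotic-notch component. The template
is rolled to start at its minimum; beats are tiled with beat-to-beat
period jitter, a ~0.25 Hz baseline wander and white noise at a configured
SNR (25 dB default). The first six Fourier harmonics of the template can
be rescaled (magnitudes only, phases preserved) to plant a harmonic power
structure.

**Per-record planting.** When targets are set, the diastolic wave's
center and amplitude are solved per record so that the template's actual
secondary peak sits at the drawn peak-to-peak delay with the drawn
relative height, and the notch is deepened until the peak's prominence
survives smoothing and noise (with a guard that the notch never becomes
the global minimum, which would misplace the pulse foot). This makes the
planted quantities nearly the extracted ones by construction, leaving
only pipeline-level biases to calibrate.

**Group calibration** is closed-loop by design: generate, extract with
the real pipeline, adjust, repeat — because the filter, smoothing and
search windows all shift extracted values, and because several cohort
means are *mixture* properties of the planted spreads (the half-height
width mixes records whose diastolic wave does or does not reach half
height; the stiffness index is a mean of ratios). The loop is a damped
Newton iteration on fixed antithetic common-random-number draw sets (the
objective is then smooth and deterministic), with a numerically probed
Jacobian, Levenberg–Marquardt ridging against probe noise, sign guards on
the diagonal, mid-run re-probing, and restarts on stalls. A final
self-check on an independent cohort must reproduce every targeted mean
within 3 % (or three standard errors, whichever is larger) or the
calibration raises. The circularity is explicit and bounded: recovery
tests demonstrate that the chain
generation → filtering → onset detection → annotation → features is
consistent at cohort scale, not that the generator matches real
physiology.

Default study conditions: 20 s records at 500 Hz, SNR 25 dB, heart rate
72 ± 6 bpm (50–95 clip), cohort demographics age 61.6 ± 11.2 y, height
167.4 ± 8.2 cm, weight 69.9 ± 12.4 kg, SBP 127.4 ± 19.6 / DBP
80.3 ± 12.0 mmHg, ~4 % positive-record rate, and the published
negative/positive group feature means and SDs as planting targets. The
planted peak-to-peak interval is clipped to 150–325 ms — outside that
band the diastolic wave collides with the neighbouring beat and the
template family inverts.

**What the generator does not emulate:** real morphology classes
(aging/stiffness subtypes, arrhythmia), motion artifacts, sensor contact
loss, inter-record correlation within a subject beyond shared group
parameters, or any true physiological link between bleeding risk and
contour shape — group differences are planted, not mechanistic. Passing
recovery tests therefore validates the measurement pipeline, not the
clinical claim.

## Numerical choices and problem sizes

Acceptance-style experiments use 200-record cohorts (≈ 25 s of signal
processing) and a calibration that typically finishes in one to three
Newton attempts; all seeds derive from a single master seed and stay
below 2³¹. Degenerate inputs are handled explicitly: constant beats raise,
all-zero signals yield empty onset trains, vacuous Mann–Whitney tests
return p = 1, zero-variance features are centered with a warning, and
beats with no locatable systolic peak are rejected per beat rather than
failing the record.

## Known limitations

* The D-point rules are tuned for 500 Hz adult waveforms; very high heart
  rates (> 150 bpm) compress the diastolic search windows.
* Record-level CV can leak subject identity across folds; use the
  subject-grouped mode for honest generalization estimates on real data.
* The amplitude-based onset pruning assumes roughly stationary pulse
  amplitude within a 20 s segment, which holds for resting fingertip
  recordings but not for severe motion artifact.
* Extracted cohort SDs are approximately, not exactly, the planted ones:
  calibration targets means; the spreads inherit extraction noise.
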