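# Methods

This note documents the generative model behind the synthetic sessions,
the estimators in the analysis chain, the numerical choices that were
genuinely open, and what the package's tests do and do not establish
about real recordings.

## The scientific setting

During translational locomotion the rat hippocampus is dominated by the
6–10 Hz theta rhythm, paced by the medial septum. During stationary
running (wheel, treadmill, virtual reality) a second, slower 3–5 Hz
oscillation appears alongside theta. Inactivating the medial septum with
muscimol abolishes theta but spares the slow rhythm, whose amplitude
stays positively coupled to running speed — evidence that the two
rhythms are generated independently. The pipeline quantifies this
dissociation with autocorrelogram periods, band powers and peak
frequencies, amplitude/frequency–speed correlations, and spike-train
rhythmicity statistics.

## Synthetic-session model

A session is a sequence of alternating maze and wheel trials (default
15 s each — stationary wheel runs last about that long — separated by
2-s near-zero-speed gaps).

**Speed.** Running speed is an Ornstein–Uhlenbeck process, exactly
discretized at 50 Hz and reflected at zero:
`v' = μ + (v − μ)·exp(−Δt/τ) + σ·sqrt(1 − exp(−2Δt/τ))·ξ`, with
μ = 60 cm/s (wheel) or 40 cm/s (maze), σ = 10 cm/s, τ = 2 s. Maze trials
receive Poisson-placed "stop" segments (mean 2 per trial, 1.5 s,
raised-cosine edges) so the 10 cm/s gate has realistic work to do. The
post-muscimol condition scales μ by 0.7.

**LFP.** `lfp(t) = A_s(t)·sin φ_s(t) + A_θ(t)·sin φ_θ(t) + η(t)` at
1250 Hz, with

* amplitudes `A_x(t) = max(0, a_x0 + g_x·v(t))`; defaults
  a_s0 = 20 µV, g_s = 0.8 µV/(cm/s) (slow amplitude grows with speed),
  a_θ0 = 40 µV, g_θ = 0 (theta decoupled from speed; a negative g_θ
  enables the opposing-coupling mode);
* the slow component multiplied by `maze_slow_scale` (default 0) during
  maze epochs — the rhythm is specific to stationary running;
* phases integrated as an ODE,
  `dφ_x/dt = 2π·(f_x + h_x·(v(t) − v_ref))`, f_s = 4 Hz, f_θ = 8 Hz,
  h_s = 0.01, h_θ = 0.02 Hz/(cm/s). Coupling frequency to speed
  *deviations* (v_ref = the context's configured mean speed, falling
  back to the trace mean) keeps f_x the realized center frequency —
  otherwise a session with maze stops would oscillate measurably above
  its nominal frequency — while preserving the weak positive
  frequency–speed correlation;
* `η(t)`: 1/f^β noise (β = 1, RMS 15 µV) made by shaping the rFFT of
  white noise with f^(−β/2). The background spectrum of real LFP is
  approximately 1/f; the exponent and scale are free parameters.

**Spikes.** Each neuron is an inhomogeneous Poisson process with a
double von Mises phase modulation,
`λ(t) = r0 · exp(κ_s·s(t)·cos(φ_s − μ_s) + κ_θ·cos(φ_θ − μ_θ)) / Z`,
where `s(t)` is the per-sample slow-component scale (so slow
entrainment vanishes where the slow rhythm does) and Z is the numerical
time-average of the exponential, making r0 the mean rate. Simulation is
by thinning against max λ. Defaults: interneurons r0 = 15 Hz,
κ_s = 2.0, κ_θ = 1.5; pyramidal cells r0 = 3 Hz, κ_s = 1.0, κ_θ = 0.8.

**Post-muscimol transform.** Theta amplitude × 0; both center
frequencies × 0.93 (the reported post-injection peak-frequency
reduction); speed mean × 0.7; interneuron rate × 0.6 (interneuron rates
drop, pyramidal rates do not change significantly); all κ × 0.5.
Correct-choice labels are drawn at 0.94 (pre) / 0.60 (post) per
maze/wheel pair — labels only, no cognitive model.

## Preprocessing

* **Notch**: zero-phase (forward–backward) 4th-order Butterworth
  band-stop, 55–65 Hz; pass-band gain below 30 Hz within 1%.
* **Artifacts**: samples with |x − mean| > 2·SD (SD over the whole
  session, computed after the notch) are threshold crossings; crossings
  are dilated ±0.25 s into candidate intervals so filter transients
  around an artifact are excluded with it. A stationary oscillatory or
  Gaussian signal crosses 2·SD at its crests/tails a few percent of the
  time with no artifact present — dilating *every* crossing would excise
  most of a clean session, preferentially its high-amplitude (fast
  running) epochs. A candidate interval is therefore flagged only if it
  contains a gross excursion ≥ 4·SD, a transient the stationary signal
  statistics essentially never produce (Gaussian rate ≈ 6×10⁻⁵). The
  raw crossing mask is exposed for inspection; `gross_mult=None`
  flags every dilated crossing.
* **Speed gate**: speed > 10 cm/s, evaluated on the 50-Hz behavioral
  clock and upsampled to the LFP clock by zero-order hold; only samples
  inside labeled trial epochs are analyzable. Masks carry separate
  artifact/slow-speed/trial flags and compose commutatively.

## Spectral estimators

* **Band filters**: two-pass (zero-phase) least-squares FIR, order
  3·⌊fs/lo⌋, 15% transition bands — the eegfilt dialect. The narrow pass
  band is weighted 50× in the least-squares objective; unweighted, the
  wide stop bands dominate the fit and the pass-band gain overshoots by
  ~8% per pass. Resulting two-pass center-band gain 0.97, stop-band
  leakage ≤ 1% one octave out.
* **Instantaneous metrics**: Hilbert analytic signal; frequency is the
  gradient of the unwrapped phase × fs/2π, median-filtered over 0.1 s
  (removes phase-slip spikes; the window is well below one slow-rhythm
  cycle) and clipped to [0, fs/2].
* **PSD**: Welch, Hamming taper, density scaling, per-window mean
  subtraction; LFP uses 1-s windows with 90% overlap, spectrograms 2-s
  windows. Spectra are zero-padded 8× (grid step 0.125 Hz at 1-s
  windows) and peak frequencies refined by 3-point parabolic
  interpolation — needed to resolve ~0.1 Hz peak-frequency contrasts on
  a 1-Hz raw grid. Masked signals are estimated per contiguous kept run
  and combined weighted by window count, so no taper spans a gap.
* **Relative PSD** is sum-normalized over a fixed 0–50 Hz grid, making
  the denominator independent of the estimator's Nyquist rate. The
  **power index** (max relative PSD in the 4–6 or 8–15 Hz spike band
  minus the value at the 6 or 15 Hz edge) cancels baseline offsets
  between conditions; the theta edge at 15 Hz follows the 4-Hz
  definition by symmetry.

## Autocorrelogram statistics

**LFP ACG**: ±0.5 s, normalized to 1 at lag 0, per trial (duration-
weighted across the trial's contiguous kept runs of ≥ 1 s), then
averaged across trials.

**Interpeak interval**: the mean spacing of successive positive-lag ACG
peaks. With two concurrent rhythms, ripple from the faster one can split
the slower rhythm's ACG peaks (at 3.1 + 7.8 Hz the theta trough lands
almost exactly on the slow peak), so peaks are detected after
*period-matched smoothing*: the dominant ACG frequency is found by FFT
in 1–12 Hz and the trace is smoothed with a boxcar of half the dominant
period. A boxcar rescales any cosine by a sinc factor without moving its
peaks, and a half-period width strongly attenuates rhythms at twice the
dominant frequency and above. A single detected peak returns its lag
(the second peak of a ~3 Hz rhythm falls outside the ±0.5 s support);
no peak returns NaN (e.g., the post-muscimol maze, where no rhythm
remains above the noise).

**Spike ACG**: pair counts on 10-ms bins within epochs (±0.5 s), the
zero-lag bin removed (it otherwise trivially dominates the maximum),
divided by the number of reference spikes — the conditional probability
of a second spike per bin. The 10-ms bin and the 200-Hz count rate used
for spike PSDs resolve ≤ 15 Hz structure with wide margin. The
rate-matched Poisson chance level per lag (including the finite-epoch
triangular correction) is carried in the result.

**NormACG** is the min–max rescaling to [0, 1]; group traces and the
band-window features (peak amplitude, interpeak interval at 200–300 ms
for 4-Hz, 100–200 ms for theta; ties toward the smaller lag; windows
without an interior local maximum return the boundary value with a
flag) are computed from it.

**Screening**: a neuron enters the group analyses when its mean rate in
the analyzed epochs exceeds 1 Hz (≥ 100 spikes) and its ACG is
rhythmic at the 0.2 level. Because a min–max-rescaled trace always
spans [0, 1], its maximum cannot distinguish rhythmic from Poisson
firing — a Poisson neuron's NormACG max over 50–500 ms lags is ≈ 1 by
construction. The screen therefore thresholds the *chance-normalized
modulation depth*, `max over 50–500 ms of (ACG / chance) − 1 > 0.2`:
zero in expectation for Poisson spiking, independent of rate and bin
width, and > 1 for strongly entrained neurons. At 10 Hz and 300 s this
separates κ = 2 entrainment from Poisson firing with essentially no
overlap (measured: 50/50 modulated included, 1/50 Poisson), and κ = 1
neurons at 5 Hz still pass. The 50 ms lower lag bound excludes the
refractory/burst shoulder.

## Statistics

Binned metrics are per-trial, non-overlapping, anchored at trial start
(1-s or 5-s bins); a bin must have ≥ 80% kept samples. Spearman's rho
uses mid-rank ties and the t approximation for p, with the exact
(fully enumerated) permutation distribution for n ≤ 10. Group
comparisons are normality-gated: Shapiro–Wilk on both groups at
α = 0.05, then paired/unpaired t-test if both pass, otherwise Wilcoxon
signed-rank/rank-sum; identical paired groups return p = 1. No
multiple-testing correction, matching the α = 0.05 convention of the
analysis this reproduces. Speed matching selects wheel trials with mean
speed in 55–63 cm/s per condition and reports a rank-sum check on the
matched speeds.

## Orchestration and I/O

Sessions live in an HDF5 container (`/lfp`, `/behavior`, `/spikes/<id>`,
`/trials`, `/meta`, optional `/ground_truth`; schema 1.0) with bit-exact
numeric round trips; spike trains are ragged, which is why a
hierarchical store was chosen over flat files. Result tables are CSV,
configs JSON. `run_pipeline` simulates the pre/post pair (post uses
seed + 1), analyzes both, and emits per-trial PSD, rhythmicity,
correlation and contrast tables plus a manifest (config hash, seeds,
package version, exclusion log mirroring the analysis filters:
artifact, < 10 cm/s, < 1 Hz, sub-threshold rhythmicity). A documented
adapter stub (`DryadAdapter`) states the contract for mapping a real
deposit into `SessionRecording` without touching analysis code.

## What the synthetic tests show — and what they do not

The generator reproduces the statistical structure the analyses assume:
two oscillators with the configured frequencies, amplitude–speed and
frequency–speed couplings of known sign, 1/f background, phase-locked
spiking of known concentration, and a post condition that abolishes
theta. Recovery tests (ACG periods to a few ms, PSD peaks to < 0.05 Hz,
coupling signs on every seed, screen operating characteristics ≥ 90%/
≤ 10%) therefore validate the *estimators*, not the biology: real LFP
has non-sinusoidal, asymmetric rhythms, nonstationary noise, volume
conduction, and spike trains with bursts and refractoriness, none of
which are modeled. Passing tests mean the chain measures what it claims
to measure when its assumptions hold; they do not certify behavior on
real artifacts (the gross-excursion gate in particular is calibrated
for transients ≥ 4·SD), extreme rhythm asymmetry, or sub-Hz drift.

### Problem sizes used by the recovery checks

Recovery targets use 60 trials of 15 s (the study-scale trial count per
condition is a few hundred; 60 gives the trial-averaged ACG and
group-average PSD their asymptotic shape with sub-ms / sub-0.05 Hz
spread across seeds). Property suites use 6–20 trials or 300-s
single-epoch simulations and 10–50 neurons per arm, sizes at which each
contract holds with a wide margin.
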