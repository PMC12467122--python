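# Methods

## Signal model and simulator

The simulator produces what the pipeline's first stage expects to read from
hardware: a real-valued frame cube of baseband ADC samples, one chirp per
frame.  A point target at range R yields, per frame, a sampled tone at the
beat frequency f_b = 2BR/(cT_c) with starting phase 4πR/λ, where B is the
sweep bandwidth, T_c = n_samples/f_s the sampled sweep duration, and λ the
carrier wavelength.  White Gaussian noise is added at a configurable SNR.
The default timing matches a commercial 60 GHz sensor: 58–63.5 GHz sweep,
3 MHz ADC rate, 128 samples per chirp, one chirp per 50 ms frame (20 Hz
slow-time rate).  With T_c defined by the sampled sweep, the range-bin
spacing is exactly c/2B (≈2.7 cm); the separate chirp-repetition interval of
the real sensor is idle time and does not enter the model.

Chest displacement is a sum of four terms:

* nominal range, default 0.5 m (sun-visor geometry);
* a cardiac pulse train.  The waveform is a raised-cosine pulse
  ((1+cos θ)/2)⁴, zero-meaned and peak-normalised, whose Fourier weights
  (56, 28, 8, 1)/128 give a dominant fundamental plus decaying harmonics —
  the harmonic structure a real ballistic chest pulse shows.  Its
  instantaneous frequency follows the configured HR trace (constant,
  piecewise-linear control points, or an arbitrary callable) through a
  cumulative phase integral.  A pure sinusoid is available as an
  alternative shape.  Default amplitude 0.4 mm (middle of the 0.2–0.6 mm
  physiological range);
* a respiratory sinusoid, default 8 mm at 0.25 Hz (middle of 4–12 mm,
  0.1–0.5 Hz);
* vehicle vibration: Gaussian noise band-limited to 0.5–5 Hz by a
  forward–backward Butterworth filter and rescaled to a configured RMS.
  This is a stand-in spectrum — real road vibration is not characterised
  here beyond its band — so vibration results say how the pipeline copes
  with in-band broadband interference, not with any particular road.

"Moderate vibration", used throughout the synthetic campaigns, means
0.2 mm RMS (comparable to the cardiac amplitude) together with 15 dB ADC
SNR.  All randomness flows from one integer seed; a configuration is
bit-reproducible.

What the simulator does not emulate: body motion and posture changes,
clothing decoupling, multiple reflectors/persons, antenna patterns, RF
non-idealities.  Passing tests therefore demonstrate correctness of the
algorithms under the stated displacement model, not field performance.

## Pre-processing

Range FFT (Hann window, one-sided), then an order-4 Butterworth high-pass
at 0.1 Hz applied forward–backward along slow time per range bin (clutter
removal; recordings shorter than three settling times are flagged).  The
bin with the largest time-averaged magnitude inside 0.2–1.5 m is selected
once per recording — the seated-driver scene is stationary.  The unwrapped
phase at that bin is the motion signal.

One readout subtlety: at a fixed FFT bin the beat tone migrates with range,
and the window's linear phase adds a term exactly proportional to R inside
the main lobe, scaling the phase sensitivity by 1 + Bλ(N−1)/(2cN) (≈4.5%
for the 5.5 GHz sweep).  `extract_phase` divides this known scale out, so
the result obeys the pure 4πR/λ model and the displacement equivalent is
calibrated; a test verifies <1% RMS displacement recovery.

The phase is band-passed to 0.5–3.0 Hz (order-4 Butterworth,
forward–backward; both filters are zero-phase by construction) and then
smoothed by a robust scalar Kalman filter: a constant-velocity state, an
innovation weight w = min(1, δ√S/|ν|) with δ = 1.5 (Huber), and a
measurement variance scaled per sample by the squared analytic-signal
envelope (clipped to [1, 100]) so high-envelope excursions — the signature
of motion artefacts — are trusted less.  The exact robust-filter
formulation is a design choice of this package; the stage is pluggable and
can be disabled in the config.  Finally the phase is differenced.

## Stage 1 — coarse estimate f0

Per 5 s chunk (100 samples): a 3-level DWT (Daubechies-4, symmetric
extension — compact support suits 100-sample windows; configurable) is
inverted keeping only A3 (0–1.25 Hz) and D3 (1.25–2.5 Hz), isolating
0–150 bpm.  Octave filter banks are not brick-wall: content near the
2.5 Hz edge is progressively attenuated (≈20% amplitude loss at 1.5 Hz for
db4, more above 2 Hz).  This shifts no peak positions and is accepted; a
test pins the monotone growth of that leakage.

An AR(12) model is fitted with Burg's method (forward+backward prediction
error; order 12 resolves the 2–4 peaks seen in practice on 100-sample
records without overfitting) and its spectrum evaluated on 512 points over
0.5–2.5 Hz.  Local maxima with prominence ≥5% of the spectrum maximum form
the peak pattern, decided by rules keyed on peak count:

* 1 peak: take it.
* 2 peaks: if f_high/f_low ∈ [1.8, 2.2] take the fundamental (H1); else if
  the amplitude ratio is <1.25 take the mean (M1); else the stronger (A1).
* 3–4 peaks: prune any peak within ±10% of twice a lower retained peak,
  then apply the 2-peak rules to the two largest survivors.
* more than 4: nearest to the history median, else the strongest.

A plausibility gate suppresses jumps: once three estimates have been
accepted, a new f0 further than 15 bpm (0.25 Hz) from the median of the
last three accepted values is marked invalid.  The gate deliberately waits
for three accepted values — a median of fewer would let one wrong
cold-start estimate veto all correct successors.  After four consecutive
rejections the history is cleared (re-acquisition), since a persistent
disagreement means the gate, not the estimator, is wrong.  Both counts are
configurable.

## Stage 2 — fine estimate f1

The chunk is modelled as y = Φx + ε with Φ ∈ R^(100×400): sines in the
first 200 columns, cosines in the last, on an inclusive 0.5–2.5 Hz grid of
200 frequencies.  The sparse solution is obtained by ARD evidence
maximisation in its sequential (fast marginal likelihood) form: starting
from the single atom explaining the most energy, each iteration computes
per-atom sparsity/quality factors and applies the add / delete /
re-estimate action with the largest analytic evidence gain; the noise
variance is re-estimated from the residual each iteration with a relative
floor of 1e−6.  The sequential form was chosen after the jointly
initialised all-atoms iteration proved unstable on this deliberately
coherent dictionary (grid spacing 0.01 Hz versus a 0.2 Hz Rayleigh limit):
it converged to pairs of near-collinear atoms carrying huge cancelling
weights.  The sequential rule admits an atom only while its marginal
evidence is positive, which excludes that failure mode; it is also
deterministic and fast (a few ms per chunk).  An independent sparse
Bayesian implementation (scikit-learn's ARDRegression) cross-checks peak
placement in the tests.

Line energies P(fₘ) = μₘ(sin)² + μₘ(cos)² form the spectrum searched
within ±12.5 bpm (0.208 Hz) of the window centre: f0 when valid, else the
previous fused estimate, else the full band.  Among window-local maxima
(prominence ≥5% of the window maximum, endpoints included — the line
spectrum is spiky), the two strongest peaks are averaged when their
energies are within a factor of 4 (a split line straddling two grid
points); a more dominant line is taken alone, since averaging it with a
weak spurious neighbour systematically drags the estimate.  Setting
`pair_max_ratio: null` restores unconditional averaging.  A window with no
peak falls back to f1 = centre with a flag that makes the fusion stage
inflate the fine-measurement noise fourfold for that chunk.

## Fusion

Both per-chunk measurements observe one scalar HR state (bpm) under a
random-walk model A = H = 1.  Each chunk applies the prediction
(x̂ₖ|ₖ₋₁ = Ax̂ₖ₋₁|ₖ₋₁, Pₖ|ₖ₋₁ = APA' + Q) and two scalar updates in
sequence — f0 with R0, then f1 with R1 — each with gain
K = PH'/(HPH' + R), state correction, and covariance correction.  The
sequential form is algebraically identical to the stacked two-measurement
update; a property test pins the equivalence to 1e−9 and the steady-state
covariance to the scalar Riccati fixed point.

Defaults: Q = 0.5 bpm² (HR drift across 5 s), R0 = 25 bpm², R1 = 9 bpm²
(the fine stage is the more reliable sensor, matching its lower measured
per-chunk error), all configurable — there are no reference values for
these, so they are this package's surrogates tuned on the simulator.  In
the pipeline the state initialises at the median of the first five valid
f0 values with P0 = 25 bpm²: five straddles the re-acquisition window, so
a harmonically locked start cannot dominate the median.  Innovations are
Huber-clipped at 2σ of their predicted spread — an outlier chunk then
moves the fused trace by a bounded amount instead of its full Kalman
weight, while persistent level changes still pull through (no hard gate,
no lock-in).  `sequential_update` keeps the exact textbook update by
default; the clip is opt-in.

## Evaluation

Chunk estimates are paired with the mean of the reference samples inside
each [t, t+5) s interval; chunks without reference samples are dropped and
counted.  MAE and MRE are plain means of |est−ref| and |est−ref|/ref.  The
SD-gated error counts use the reference-HR standard deviation within each
measurement period (one recording; per-recording when ids are given): a
chunk is an error at level k iff |est−ref| > k·SD, and MAE/MRE restricted
to error chunks are reported alongside counts and rates, since both
readings of such gated columns are useful.  A flat reference (SD = 0) falls
back to an absolute 1 bpm tolerance and is flagged.  Bland–Altman reports
bias ± 1.96·SD of the paired differences (sample SD); Pearson r comes with
a two-sided t-test p-value and is NaN for constant traces.

## Problem sizes and determinism

The synthetic campaigns used by the tests and the acceptance script are
ten 90 s drives (18 chunks each) at constant 60/72/90 bpm with respiration
at 0.25 Hz and moderate vibration as defined above — large enough for
stable per-stage error ordering, small enough to run in seconds.  Every
stochastic element (scene noise, vibration, ADC noise) derives from the
scene seed; the estimation pipeline itself contains no randomness, so
identical recordings and configs give identical outputs.

## Known limitations

* The peak-decision rule table and the robust-filter internals are
  documented surrogates for under-specified components; both are
  configurable and their defaults were fixed against the simulator only.
* Octave-band leakage attenuates coarse-stage content above ~2 Hz
  (120 bpm); high heart rates lean correspondingly harder on Stage 2.
* At 60 bpm the cardiac second harmonic (120 bpm) lies in-band and can
  dominate early chunks; the re-acquisition and robust-initialisation
  machinery exists for exactly this case, and residual harmonic locks of a
  few chunks remain the largest error contributor in the campaigns.
* The evaluation treats the reference trace as exact; real chest straps
  carry ~1% error.
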