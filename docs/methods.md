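# Methods

## Problem and model

The classifier decides, for each 3-second mono clip recorded inside a
beehive at 16 kHz, whether the colony is in a normal state or exhibiting
swarm-related activity. The discriminative information is spectral:
swarm precursors (queen piping at 340–450 Hz, defensive hissing near
3 kHz, intensified wingbeat hum near 250 Hz) sit in bands that everyday
flying and fanning sounds (225–285 Hz) occupy only partially.

Two model families are implemented over a shared front-end:

* **Left–right continuous-density HMMs.** Each class (normal, swarm,
  silence) is a chain of emitting states restricted to self-loops and
  single forward moves; emissions are diagonal-covariance Gaussian
  mixtures. Clips are scored against composite networks
  `[optional silence] → activity → [optional silence]` so that quiet
  stretches inside a nominally homogeneous clip are absorbed by the
  silence model rather than biasing the activity models; classification
  is the Viterbi argmax over the candidate networks (a clip that scores
  best as pure silence is reported as silence, which counts as an error
  against an activity reference).
* **Per-class GMMs.** A single mixture per class scores every frame;
  the clip label is the majority frame vote, with silence-frame votes
  excluded from the normal/swarm tally unless every frame is silence.
  Ties go to the larger summed log-density, then to sorted label order.

## Front-ends

Frames are 25 ms with a 10 ms shift (298 frames per 3-s clip), Hamming
windowed after first-order preemphasis (coefficient 0.97 — the standard
speech default; the stage is part of the pipeline but its coefficient is
configurable). MFCC features are 12 cepstra from a 26-filter triangular
mel bank (0–8000 Hz, FFT size 512, orthonormal DCT-II, log floor 1e-10)
plus the log energy of the raw (unwindowed, preemphasized) frame;
regression deltas (window ±2, edge frames replicated) extend the 13
statics to 39 dimensions. Cepstral mean normalization, when enabled,
subtracts per-coefficient static means over the clip — the clip is the
classification unit, so it is also the normalization scope — and the
deltas are recomputed from the normalized statics.

LPC features use order 12 (matching the 12-coefficient static layout of
the MFCC stream so both feed identical model topologies) solved by the
Levinson–Durbin recursion; the default static representation is
LPC-cepstra via the standard recursion, with raw predictor coefficients
selectable. Energy and deltas are appended exactly as for MFCC. Silent
frames (zero autocorrelation) produce zero coefficients with a floored
prediction error.

## Training recipes

**HMM (two stages).** Stage 1: flat start (every state of every model
receives the global mean/variance of all training frames, one component,
uniform legal transitions), then cycles of two embedded Baum–Welch
passes followed by mixture doubling until 16 components per state.
These models forced-align the training set; a clip is an outlier if it
is unalignable or its per-frame normalized log-likelihood falls more
than 3 standard deviations below its class mean. The 3-SD rule is this
package's choice of criterion — the outlier percentages reported for
the original corpus (1.2–1.4%) come with no stated rule, so they are
not asserted as reproducible; on the clean synthetic benchmark the
filter removes well under 2%. Stage 2 discards the stage-1 models,
re-initializes from per-class statistics on the filtered set, and runs
cycles of three Baum–Welch passes with doubling until 32 components.
Snapshots at 2, 8 and 32 components are retained as the
low/medium/high-complexity representatives.

**GMM (single stage).** Flat start at one component, cycles of two EM
passes plus doubling to 32 components, no realignment. With a single
state, embedded Baum–Welch reduces to plain GMM EM, so the first EM
pass already lands on the class sample statistics regardless of
initialization.

Numerical choices: forward–backward runs in the scaled linear domain,
batched over equal-length clips; variance floors are 1e-4 of the global
per-dimension variance (prevents component collapse at 32 components on
modest data); mixture splitting clones every component into a ±0.2 σ
pair with halved weights (the first moment of each state is preserved
exactly); transition rows are re-normalized expected counts with
structural zeros preserved; states with no occupancy in a pass keep
their parameters. Clips shorter than their network's mandatory path are
skipped with a warning and counted, never fatal. EM monotonicity holds
within every fixed-size cycle; the split between cycles may perturb the
likelihood, so training logs record per-cycle histories.

## Noise tooling

SNR is measured full-band at clip level, `10·log10(P_signal/P_noise)`
over mean squared amplitude — the convention for the corpus's single
per-test-set SNR figures, adopted here and documented since no
band-limiting is stated anywhere. Mixing rescales the noise source to
hit the target exactly (well inside the 0.1 dB contract). The synthetic
urban ambiance is a 75% pink / 25% flat-spectrum Gaussian bed (engine
rumble dominates the low end, tire/road noise is broadband) with
randomly timed 500–2000 Hz bursts standing in for passing vehicles;
it is fully seed-determined.

Spectral subtraction is the canonical magnitude-domain form: the
average noise magnitude spectrum — the mean over all frames of the
clip itself (mode `self`), over its 10% lowest-energy frames (mode
`quiet`), or from a supplied noise-only calibration clip — is
oversubtracted (α = 1.0) from each STFT frame with a spectral floor
(β = 0.01), the noisy phase is kept, and a COLA-compliant Hann
analysis/synthesis pair reconstructs the signal, so a zero noise
estimate reproduces the input to numerical precision. Blind (`self`)
estimation necessarily attributes perfectly stationary tonal content
to noise; when a reference recording of the interfering noise exists,
calibration mode is the right tool, and it is the one used for the
SNR-improvement checks. At α = 1 the subtraction leaves roughly 11%
residual power on pure stationary noise (the Rayleigh tail of the
magnitude distribution).
Denoising operates on canonical 16 kHz audio (whether the original
study denoised before or after downsampling is unstated).

## Synthetic corpus

The generator emulates the study conditions: 3-s homogeneous labeled
clips at 16 kHz. Normal scenes are a full-length flying bed plus one or
two fanning events; swarm scenes add piping and/or hissing (the mode is
drawn per clip, making the swarm class deliberately multimodal) over an
elevated flying bed. Event levels are drawn around −20 to −26 dBFS with
±6 dB jitter, fundamentals and amplitude modulation are randomized per
event, and all non-silence clips sit on a −45 dBFS in-hive broadband
floor. Every clip derives a child seed from the master seed:
generation is bit-reproducible and no two clips coincide. A young-bee
variant (flying fundamental multiplied by 1.2–1.5) exists but is off by
default. Benchmark scale is 300 training and 100 test clips per class
plus 60 silence training clips — large enough for the
complexity-accuracy gradient to be visible, small enough for the full
three-architecture benchmark to run in minutes on one CPU.

What passing on this corpus shows — and what it does not: the synthetic
classes carry the documented spectral signatures with realistic
variability, so results demonstrate that the front-ends preserve the
discriminative bands and the models learn them. Real recordings add
reverberation, sensor coloring, non-stationary colony overlaps and
label noise that additive tone models do not reproduce; absolute
accuracies here (typically 88–99.5% depending on architecture and
mixture count) are not comparable to field numbers. At the two studied
noise levels (SNR 42.74 and 27.30 dB) the synthetic task remains
essentially fully separable — the noise-trend check is an ordering
(clean ≥ low-noise ≥ high-noise) that ties satisfy, not a claim of
measurable degradation at this scale.

## Design choices where the design was open

* **Silence topology:** 3 emitting states under the 15-state
  architecture, 1 under the 1-state architecture; quiet audio has
  little temporal structure to justify more.
* **Silence data:** whole clips carry their recording-level class
  label; the optional silence units in the training networks absorb
  pauses, and a small set of explicit silence clips gives the silence
  models direct data.
* **Positive class** for precision/recall/F1 is swarm, the
  alarm-worthy event.
* **Balancing** of over-represented classes is random subsampling with
  the seed recorded in the manifest header.
* **Downmix** is the unweighted channel mean; resampling is polyphase
  band-limited (linear interpolation would alias into the feature
  bands). Upsampling is refused — the corpus convention only ever
  downsamples.
* **Energy term** is log raw-frame energy rather than c0; either
  convention is defensible, this one keeps the cepstra independent of
  overall gain.
* **McNemar's exact test** is available for paired system comparison;
  no significance claims are baked into the pipeline.

## Known limitations

Single-threaded CPU implementation; no streaming/online decoding; no
state tying or discriminative training; the spectral-subtraction
noise estimate is stationary per clip; LPC order and representation
for the original study are unknown, so the defaults here are standard
choices, not assertions about that study. The real-time factor utility
is hardware-dependent and intentionally excluded from correctness
checks.
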