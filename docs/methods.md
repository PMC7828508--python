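# Methods

## Decoding model

The package decodes the direction of auditory attention in dichotic
listening by stimulus reconstruction. The working assumption is that 2–8 Hz
cortical activity tracks the amplitude envelope of attended speech more
strongly than that of ignored speech, and that the mapping from EEG back to
the envelope is linear over short lags.

A backward decoder `D(τ, n)` estimates the envelope as
`Ŝ(t) = Σ_n Σ_τ D(τ, n) R(t + τ, n)`, using EEG *after* the stimulus
sample: reconstruction of `S(t)` reads channels at lags `τ ∈ [0, 250] ms`
(17 lags at 64 Hz). The weights are the ridge solution
`D = (R Rᵀ + λI)⁻¹ R Sᵀ` computed on the raw covariance of z-scored data,
with `λ = 10` by default. The identity regularizes every row, lag 0
included; there is no intercept because all inputs are z-scored. Samples
shifted past a segment end are zero-padded rather than truncated, for both
fitting and reconstruction, so a snippet's design matrix depends only on
the snippet. When `λ = 0` leaves the normal equations singular, the solver
falls back to the pseudo-inverse with a warning.

## Online construction and detection

Each 60 s construction trial is cut into `J = ⌊(T − W)/M⌋ + 1` overlapping
snippets of `W` seconds hopped by `M` seconds (defaults `W = 15`, `M = 1`,
hence `J = 46`). One ridge decoder is fitted per snippet against the
*attended* envelope, and the online model is the unweighted mean of all
`I · J` snippet decoders, accumulated as a running sum so memory is O(1)
in `J`. Snippet arithmetic is done in seconds and converted to samples at
64 Hz; `W` and `M` must give integer sample counts. Direction-biased
decoders average only the left-attended or only the right-attended
construction trials; the pair together consumes the same `I` trials as the
single model.

At test time the reconstruction from each window is Pearson-correlated
with the left and right envelopes. Correlation series are causally
smoothed per trial with a trailing moving average of width
`k ∈ {1, 3, 5, 7}` (the window includes the current value, so `k = 1` is
the identity; early snippets average whatever is available; smoothing never
crosses trial boundaries). The larger smoothed coefficient decides the
side at time `(j − 1)·M + W`; an exact tie repeats the previous decision
within the trial, defaulting to left — a deterministic rule for an event
of essentially zero probability on real-valued data. In attention-switching
trials the ground-truth label of a snippet is the scheduled side at its
detection timestamp (the window end), so windows straddling the transition
are labelled by the post-transition side; a majority-of-window alternative
would shift labels by at most `W` seconds around the transition and is not
implemented. Biased pairs are evaluated matched-side: each snippet uses the
decoder whose bias equals the scheduled side at its timestamp.

Chance level is the smallest `100·k/n` whose exact binomial CDF reaches
`1 − α` (one-sided, `α = 0.05`, no normal approximation). This convention
reproduces standard printed chance levels such as 52.99 % for n = 736 and
53.44 % for n = 552 at p = 0.5.

The snippet count deserves one note: the formula is sometimes written
`⌊(T − W + 1)/M⌋` in 1-based inclusive notation, which coincides with the
window-fitting count at `M = 1` but returns 0 for `W = T` with `M > 1`.
The package counts windows that fit — `⌊(T − W)/M⌋ + 1` — which reduces to
the single full-trial decoder at `W = T` for any hop.

## Preprocessing

Speech envelopes are the power (squared magnitude) of the analytic signal
from the Hilbert transform — the magnitude variant is exposed as an option
but the power reading is the default — polyphase-resampled to 64 Hz and
z-scored per segment. Offline EEG conditioning is zero-phase: 0.5 Hz
high-pass, notches at 60/120 Hz, common average reference over the non-EOG
channels (EOG channels are re-referenced too but never enter the mean),
2–8 Hz band-pass, resampling to 64 Hz, per-channel z-scoring.

The online chain is causal and minimal: CAR, then a 1650th-order
linear-phase FIR band-pass (windowed-sinc, Hamming — the order is fixed,
the window is the conventional default) applied with `lfilter`. A
linear-phase FIR of even order delays its output by exactly order/2 = 825
samples at 1000 Hz; the chain compensates by discarding the first 825
output samples so that output sample `t` aligns with input time `t` before
pairing with the (undelayed) envelopes. Uncompensated, the EEG would lag
the envelopes by 825 ms — more than three times the decoder's entire lag
span. Z-scoring at test time is computed over the processed span of the
accumulated buffer; Pearson correlation is invariant to per-snippet affine
rescaling, so this choice affects training only through the envelope/EEG
scale ratio absorbed by the decoder weights.

## Streaming emulation

The session emulator feeds EEG in `M`-second blocks into a per-trial
buffer, fits each snippet decoder as soon as its window of data has
arrived, and emits one detection per hop during the test phase. Wall-clock
time is virtual — arrival timestamps are bookkeeping — so runs are
deterministic, and the streamed path performs the same snippet fits in the
same order as the batch path, making the two bit-identical. No decision at
time `t` uses raw samples arriving after `t` (modulo the documented FIR
delay compensation).

## Synthetic data

The generator emulates the statistical structure the decoder relies on,
not the biophysics. Envelopes are Gaussian noise low-passed at 8 Hz,
full-wave rectified and band-passed to 2–8 Hz, then z-scored — matching
the rate, normalization and modulation band of preprocessed speech
envelopes. EEG is a causal lagged linear response: channel `n` is
`gain_att · (k_att[n] ∗ S_att) + gain_ign · (k_ign[n] ∗ S_ign) + noise`,
z-scored per channel. Kernels are tri-phasic P1–N1–P2-like responses —
Gaussian components near 50, 100 and 180 ms with the dominant deflection
near 100 ms — with per-channel random amplitude, polarity and latency
jitter (sd 40 ms), spanning at most 250 ms. The latency spread across
channels makes the multichannel response broadband and invertible over
2–8 Hz, which is what lets a lag-limited backward decoder recover the
envelope essentially perfectly in the noise-free limit; a single shared
narrowband kernel would cap reconstruction around r ≈ 0.96 regardless of
noise. An optional "spatial" mode scales the attended response by a
side-dependent channel topography so left- and right-attended states are
spatially distinguishable, which is the premise direction-biased decoders
exploit. In attention-switching trials the attended/ignored composites
swap roles at the transition (default 30 s, i.e. the trial midpoint)
before convolution.

Defaults, chosen once as the package's standard study conditions:

- `gain_att = 1.0`, `gain_ign = 0.4` — attended speech represented more
  strongly than ignored speech.
- `noise_sd = 300` (white at 64 Hz; per-channel signal variance is of
  order 1 before normalization). This places the simulation in the
  operating regime of real single-trial EEG, where the envelope-following
  response is a very small fraction of band-limited EEG variance:
  attended-stream reconstruction correlations come out near 0.05–0.12 and
  fixed-trial accuracy near 75–80 % at `W = 15 s`, `I = 14` — the regime
  in which published envelope-reconstruction AAD systems operate. A 1/f
  noise spectrum is not implemented; white noise overstates the number of
  independent samples per window, which the calibrated amplitude
  compensates for at the default window sizes.
- 16 channels — a desk-scale stand-in for a 64-electrode montage that
  keeps the lag-expanded design matrix (272 rows) cheap. No EOG channels
  are generated; the preprocessing chain's EOG handling is tested on
  constructed signals instead.
- Sessions: 14 construction (7 per side) + 12 attention-fixed + 4
  attention-switching test trials (8 per side among test trials), or the
  30-trial all-fixed simulation layout with up to 15 construction trials.

What passing tests on this generator do *not* show about real data: the
forward kernel is stationary and identical across trials, attention takes
effect instantaneously at the scheduled transition, noise is white and
uncorrelated across channels, and envelopes carry no linguistic or
prosodic structure. Real EEG violates all of these; accuracies obtained on
synthetic sessions therefore validate the pipeline's correctness and its
parameter trends, not expected field performance.

Generation happens at 64 Hz directly; `synthetic.to_raw_rate` upsamples a
trial to an acquisition rate (default 1000 Hz) to exercise the causal
preprocessing chain end-to-end.

## Grid experiments

`grid_search` rebuilds the online model on the first `I` trials of each
session — in session order, no subsetting — for every combination of
`W ∈ {5, 10, 15, 20} s`, `M ∈ {1, 3, 5, 7, 9} s`, `I ∈ {1, 5, 10, 15}`,
and evaluates on *all* remaining trials, so cells with different `I` have
different test sizes (the reported `n_records` makes this explicit).
Per-snippet decoder fits are cached by (W, window start, trial), which
overlapping cells and nested `I` prefixes share; smoothing widths are
applied post hoc to stored correlation series. Summaries report per-cell
mean ± sd across subjects (n − 1 denominator) and per-parameter marginals.
On five seeded synthetic subjects this reproduces the expected qualitative
pattern: accuracy rises monotonically with `W` and `I`, is flat in `M`,
and trailing-average smoothing (k = 7) does not hurt attention-fixed
accuracy. Direction-biased grid cells require an even `I`; the default
grid therefore runs the single model only.

## Numerical choices and degenerate inputs

- Z-scoring uses the population (ddof 0) standard deviation; zero-variance
  slices return zeros with a warning, and zero-variance snippets get
  correlation 0 with a warning rather than NaN.
- Resampling is polyphase with a rational factor (e.g. 8/125 for
  1000→64 Hz), anti-aliased by design; output length differs from
  `duration · 64` by at most one sample.
- Ridge solves use a symmetric dense solver; the independent cross-check
  in the tests is an explicit normal-equations / augmented least-squares
  solve.
- All randomness flows through `numpy.random.Generator` seeds; sessions,
  streaming runs and grid tables are bit-reproducible from a seed.

## Known limitations

- No artifact handling (blinks, ICA), channel selection, or electrode
  geometry; EOG support is limited to reference exclusion.
- The decoder is linear and per-subject; no cross-subject transfer,
  confidence weighting of snippets, or state-space smoothing of decisions.
- The generator's white-noise and stationary-kernel assumptions make the
  synthetic task easier per sample than real EEG at matched correlation
  levels; absolute accuracies are calibrated, not predictive.
- WAV input covers PCM and float mono (first channel of multichannel
  files); no other audio containers.
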