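# Methods

## Problem and model

`lfpclean` repairs artefact-contaminated stretches of a local field
potential using only the affected channel's own history. The working
assumptions are:

* outside artefacts the signal is (locally) stationary, zero-centred and
  band-limited, so a forecaster trained on artefact-free segments captures
  "normal" dynamics;
* artefacts are rare, high-power events, so a per-channel threshold on
  window power separates them from background with high recall;
* each artefact run is preceded by enough clean signal to seed a forecast
  (runs at the very start of a recording are logged unreplaceable and left
  untouched rather than guessed).

### Labelling

Windows are contiguous, non-overlapping and left-aligned; the trailing
partial window is excluded and never replaced. Window power is the mean of
squared samples — not the sum (so values are comparable across window
lengths) and not a tapered spectral estimate (the labelling quantity is a
broadband amplitude statistic, not a PSD). A window is artefactual iff its
power **strictly** exceeds the channel threshold; ties count as clean, so a
threshold derived as "maximum power over clean epochs" never flags the
epochs it came from. Thresholds are per-channel when derived, or one manual
global value.

### Segment extraction

One greedy left-to-right scan per channel classifies each candidate
segment: all windows clean → training segment; clean prefix followed by at
least one artefact window → replacement-evaluation segment; otherwise the
scan jumps past the blocking artefact. A single shared scan (rather than
two independent ones) guarantees clean and artefactual segments never
overlap in sample coverage, so training data cannot leak into replacement
targets. Segments are non-overlapping; the stride-versus-overlap policy of
the original segment counts is not recoverable, so extracted counts are a
property of this scan, not a reproduction of any published count. The
train/validation/test split is segment-level i.i.d. with counts
`round(f·n)` for validation and test and the remainder (favouring training)
to the training set; chronological splitting is a deliberate non-feature at
fixture scale.

### Forecasters

* **LSTM** — scalar-input sequence of length `input_len`, one hidden layer
  of `round(input_len/10)` units (clamped to 1 with a warning below 10
  inputs), linear read-out of `output_len` samples. Gate order in the fused
  weights is forget, input, candidate, output, matching the cell equations.
* **CNN-LSTM** — the 16-row stack (input, folding, conv d=1, batchnorm+ELU,
  conv+ELU d=2/4/8/16, size-1 stride-5 average pooling, unfolding with
  flattening, GRU 128, LSTM 64, dropout 0.25, LSTM 32, dropout 0.25, linear
  regression output). The folded 2-D convolutions are realised as dilated
  convolutions along time with a singleton second dimension, and the
  pooling as stride-5 temporal subsampling. Convolutions are **causal**
  (left zero-padding) so no future samples leak into a forecast. The
  dilation-16 kernel spans 65 samples, so inputs shorter than 80 samples
  are rejected.
* **ARMAX baseline** — `A(q) y = Σ B_i(q) x_i + C(q) e` with
  `A(q) = 1 + a₁q⁻¹ + …`. With no reference channel (the default,
  channel-independent case) it degenerates to ARMA (k = 0). Pure-AR fits
  use exact least squares on the lagged design (which recovers noise-free
  autoregressions to machine precision, where Gaussian MLE with vanishing
  innovation variance is ill-posed); fits with an MA part use
  statsmodels' state-space MLE. Exogenous inputs are supported as
  order-0 regression terms. `orders="auto"` selects by AIC over a small
  grid (AR orders 1–8, MA 0–1). Instability (an AR root on or outside the
  unit circle) is flagged on the fitted spec, not silently repaired.
  Following the refit-per-sequence usage, `ArmaxForecaster` re-estimates
  the polynomials for every forecasting context.

### Training

Adam with β₁ = 0.9 (the printed "momentum" is interpreted as the
first-moment decay), β₂ = 0.999, initial learning rate 1e-4. The loss is
the half-MSE per time step, `(1/2S) Σ_i Σ_j (x_ij − x̂_ij)²`, used directly
for gradients (Adam's per-parameter normalisation makes the absent 1/N
factor immaterial to the update direction). Inputs and targets are z-scored
with training-set statistics stored on the model; forecasts are
de-normalised to mV. Batch size defaults to 128 (the smaller-corpus
setting; 516 is the documented larger-corpus value and is kept as printed,
configurable). Training runs at most `max_epochs` (default 100) with early
stopping on validation loss, patience 10 (a chosen default; the protocol
mentions early stopping without a patience), restoring the best-validation
weights. Examples are cut from segments with stride `output_len` by
default. One master seed drives weight initialisation, dropout and batch
shuffling; everything is float64 and single-threaded, so identical seeds
give bit-identical weights.

The networks run on a minimal in-package reverse-mode autodiff tape;
recurrent layers are single fused tape nodes whose backward pass is
hand-written backpropagation-through-time (verified against central finite
differences to ~1e-10 in the test suite's development).

### Replacement

Runs of consecutive artefact windows are replaced in one recursive pass:
the context is the `context_len = input_len` samples immediately before the
run in the progressively cleaned signal, so earlier replacements feed later
contexts ("the forecast is used as part of the input if the following
window shares the label"). Substitution is hard at window boundaries — no
cross-fading — and per-channel. Where a context partially overlaps an
*unreplaceable* artefact (one at the recording start), true samples are
used as-is; clean-window samples are always preferred and forecasts used
only where replacement happened. Runs longer than an optional
`max_run_windows` emit a warning because pure recursion drifts toward the
process mean.

### Evaluation

The horizon RMSE is implemented exactly as its printed definition,
`sqrt(Σ_i Σ_j (x_ij − x̂_ij)² / N)` with denominator `N` (examples only), so
it grows like `sqrt(S)` for i.i.d. residuals; the per-point variant
`rmse/sqrt(S)` is provided for cross-horizon comparison. Periodograms use a
rectangular window and 'spectrum' scaling (linear bins sum to the mean
square; Parseval holds to <1 %), with a dB floor (default −120 dB) instead
of −∞ for empty bins. Power summaries report the 5/25/50/75/95 %
per-segment power quantiles per group instead of violin plots. Wall-clock
time per forecast is reported but never asserted.

## Synthetic data: what it emulates and what it does not

The generator produces a zero-mean AR(2) background whose pole pair
(radius 0.98) puts a sharp spectral resonance at 8 Hz — a rodent
theta-band-like peak — scaled to σ = 0.05 mV, values chosen once as
representative of awake rodent LFP amplitude and spectral shape. Artefacts
are half-sine amplitude transients, Tukey-windowed 60-Hz bursts and
baseline jumps, with amplitude 10× the background RMS, 1-s duration, and
rates of 2/min (transients) and 1/min (bursts), placed by a seeded
Bernoulli-per-window process (simpler ground-truth bookkeeping than a
continuous-time point process). A 10× amplitude multiplier puts affected
windows at roughly 50× background mean power, far above any threshold
derived from clean activity, which is why labelling recall 1.0 is an
asserted invariant rather than a tuned outcome.

What passing tests on this fixture show: the geometry, labelling,
training, recursion and substitution machinery are correct, and learned
forecasts beat trivial substitution on stationary band-limited background.
What they do not show: performance on real LFP with drifting state
(sleep stages, behaviour), 1/f broadband structure, artefacts that overlap
the physiological band at low amplitude, or non-stationary baselines.
Published RMSE values from real recordings are functions of those datasets
and of stochastic training and are not reproduction targets here.

## Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| labelling window | 1.0 (fixture) / 0.05 (2 kHz-style) | s | block size that is both labelled and replaced |
| segment length | 4.0 | s | training/evaluation segment |
| clean prefix | 1.0 | s | context available before an artefact run |
| split | 0.8/0.1/0.1 | — | train/val/test fractions |
| LSTM hidden | input_len/10 | units | one-tenth rule |
| learning rate | 1e-4 | — | documented training protocol |
| β₁ | 0.9 | — | "momentum" as first-moment decay |
| batch size | 128 | examples | smaller-corpus setting (516 for larger) |
| patience | 10 | val. checks | early-stopping default |
| fixture fs / duration | 250 / 600 | Hz / s | desk-scale study conditions |
| background σ / peak | 0.05 / 8 | mV / Hz | awake-rodent-like amplitude and resonance |
| artefact amplitude | 10 | × background RMS | guarantees labelling recall |

## Problem sizes in the acceptance script

`scripts/acceptance.py` uses the 600-s, 250-Hz fixture (≈ 118 clean and
31 artefactual 4-s segments at seed 1), a 250→25 LSTM trained for 10
epochs, a 250-sample evaluation horizon, and ARMAX with automatic order
selection refit per test segment — sizes chosen so the whole script is a
few minutes of single-core compute while still exercising every stage at
the stated study conditions.

## Known limitations

* Replacement quality degrades with artefact-run length: the recursion has
  no new information, so long substitutions decay toward the mean and lose
  high-frequency detail (hence the optional long-run warning).
* Segments whose neighbourhood has high power but whose own windows stay
  below threshold are not replaced; the replaced-power distribution can
  therefore retain a high tail.
* The power threshold is amplitude-based: low-amplitude artefacts inside
  the physiological band are invisible to it.
* ARMAX forecasting assumes local linearity; on signals retaining
  high-frequency structure its multi-step forecasts deteriorate faster
  than the networks'.
* The CNN-LSTM is substantially more expensive to train on CPU than the
  plain LSTM; at fixture scale the plain LSTM is the default.
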