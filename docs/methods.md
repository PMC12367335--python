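# Methods

## Model

The predictor is a sequence-to-one regressor. A stay's three vital-sign
channels (heart rate in bpm, respiration rate in breaths/min, SaO2 in %)
on the 5-minute grid are truncated to the real-time window (only samples
with offset < `window_hours`·60 from admission; shorter stays contribute
everything they have, and the LOS target is never truncated), imputed
(forward-fill, then back-fill of leading gaps), denoised per channel by
the DWT low-pass cascade, z-scored per channel with statistics fitted on
the training split only, and fed to the LSTM. The linear head reads the
final hidden state; the output is LOS in days, unclamped inside the
model (evaluation floors negative values only in the quantile summaries
and counts them).

### Wavelet front end

* **Filters.** Orthonormal convention `sum(dec_lo) = √2`; the high-pass
  filter is the alternating-sign time reversal of the low-pass
  (quadrature mirror). Any orthogonal PyWavelets family is selectable by
  name; the default is **Daubechies-4** — short enough for 36-sample
  (3 h) windows at level 2 yet markedly smoother than Haar. The
  denoising level defaults to **2**, i.e. the approximation keeps
  content below f_s/8 (periods ≳ 40 min at 5-minute sampling), which is
  the scale of physiological trends rather than monitor noise.
* **Analysis step.** For `zero`/`symmetric` padding the signal is
  extended by L−1 per side, fully convolved, and every second sample
  kept (output length ⌊(n+L−1)/2⌋, identical to the common library
  convention, cross-checked against PyWavelets in the tests). For
  `periodic` padding the transform is the periodized orthogonal DWT
  (output ⌈n/2⌉; odd lengths are wrapped to even first); synthesis is
  the exact transpose, giving perfect reconstruction to ~1e-15.
* **What the LSTM sees.** By default the *approximation coefficients*
  themselves (4× shorter than the window). A full-length low-pass
  *reconstruction* (all detail branches zeroed) is available via
  `output_mode="reconstruction"`; the ablation harness records which
  mode a run used. Level 0 is an exact pass-through, which makes
  "WT-LSTM with level 0" bit-identical to the plain LSTM under equal
  seeds — used as a self-check.
* **Boundary handling** defaults to symmetric extension (smallest edge
  artefacts on short clinical windows); energy and
  perfect-reconstruction arguments use periodic padding, where
  orthonormality is exact.

### LSTM

The six gate equations are implemented literally; gate biases exist but
can be pinned to zero (`bias=False`) to match the bias-free equations —
training enables them by default, as is standard. The linear head reads
the **last** hidden state (a single scalar target makes seq-to-one the
natural reading). `hidden_dim` defaults to 32 (16 in the scaled test
configurations). Weights initialize uniformly in ±1/√h from the run
seed. Variable-length batches are padded at the end and masked so padded
steps copy the state through — stays shorter than the window are
first-class citizens. Forward, BPTT gradients and Adam are NumPy; the
gradients are verified against central finite differences (≤5e-6) and
the forward pass against an independently coded loop over the equations
(≤1e-12).

The BiLSTM baseline runs two independent LSTMs (one over the reversed
sequence, reversal applied within each stay's true length), concatenates
the final hidden states, and regresses through one 2h-wide head. Zeroing
the backward half reproduces the unidirectional model exactly. The
linear baseline is OLS on 9 features (per-channel mean/min/max of the
window); flattening the window is available behind a flag.

## Training protocol

Stratified hold-out: stays are binned into `stratify_bins` LOS-quantile
strata (default 4 — quartiles; the binning rule for a continuous target
is a package decision) and assigned 56.25/18.75/25% to
train/validation/test within each stratum with the run seed. For each
learning rate in {0.08, 0.1, 0.12, 0.15}: Adam, batch 16, ≤100 epochs,
early stopping when validation MSE fails to improve for 10 epochs
(patience is a package decision), best-validation checkpoint restored;
the grid winner is the rate with the lowest validation loss. Non-finite
loss aborts that rate with a warning; if every rate diverges the run
errors. Repeats use seed `master + r` and by default re-split and
re-initialize (`resplit_each_repeat=False` fixes the split). All
randomness flows through `numpy.random.Generator`, so a fixed master
seed makes the entire experiment bit-identical on one machine.

## Synthetic cohort

The generator emulates the structure the method needs, not eICU's
marginals:

* **LOS** ~ lognormal(ln 2.5, 0.7) days — median 2.5 days, pronounced
  right skew, driven by latent severity z ~ N(0,1), so Spearman(z, LOS)
  is exactly 1.
* **Channels**: baseline (85 bpm, 18 /min, 96 %) + subject-level offset
  (sd 10, 3, 1.5) + severity coupling (+8 bpm, +3 /min, −2 % per unit z)
  scaled by an early-phase ramp (doubled at admission, decaying to 1
  over 6 h) so short windows carry signal, matching the qualitative
  finding that the first 3 hours are most informative + AR(1) drift
  (φ=0.9, stationary sd 3, 1.5, 0.8) + white noise (sd 4, 2, 1) +
   2% independently missing cells. SaO2 clipped to [0,100].
* **Presets**: `signal-rich` (strong coupling — analogue of the
  diagnosis cohorts where vitals separate risk well, e.g. rhythm
  disturbance or cardiac arrest) and `signal-poor` (weak coupling —
  analogue of heart failure / pulmonary sepsis / CABG, where all
  patients' vitals are deranged or none are).

What passing tests on this generator do **not** show: performance on
real ICU distributions (multimodal diagnoses, interventions, monitor
dropout bursts, LOS censoring). The built-in denoising benefit — the
level-2 low-pass lying closer to the noise-free trend than the raw
channel in ≥95% of stays — is a property of the white-noise component;
real monitor noise is heavier-tailed.

## Problem sizes used in checks

The bundled checks run at desk scale, chosen once as representative:
oracle comparisons at n≤128; pipeline determinism on 400 stays (2 models
× 2 windows × 2 repeats, hidden 16, 2-point lr grid); the denoising
ablation on 2,000 signal-rich stays, 10 repeats, 3-hour window, hidden
16, single rate 0.1 (a window/rate choice, since neither is pinned by
the protocol); the acceptance script's ablation at those same
conditions; generator statistics at 1,000–10,000 stays. The published
per-cohort MSE values on eICU are inputs to the improvement arithmetic
only; reproducing them requires credentialed data access and is out of
scope, as is the APACHE IV scoring system itself (its MSEs are treated
as external constants).

## Numerical notes and limitations

* CSV round trips are bit-exact (`%.17g` on write,
  `float_precision="round_trip"` on read). Irregular offsets snap to the
  nearest 5-minute grid point; duplicates at a grid point are averaged.
* A zero-variance channel normalizes with sd treated as 1 (warned).
* lr-grid ties resolve to the first grid entry; validation improvement
  uses a 1e-12 threshold.
* The periodized DWT here differs from PyWavelets' `periodization` mode
  by a fixed circular phase (both are orthonormal; ours is
  self-inverse). Zero/symmetric modes match PyWavelets exactly.
* Minimum series length for level j is L·2^(j−1) (L = filter length);
  shorter series raise an error naming that minimum rather than
  silently padding.
* The model is a cohort-level tool: on individual stays the variance of
  the prediction is large, and MSE-trained regressors pull extreme LOS
  toward the mean — the prediction-quantile summaries in `EvalReport`
  exist to make that visible.
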