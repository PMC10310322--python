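# Methods

This note documents the models, numerical choices and limitations of the
package in one place. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is copied from elsewhere.

## The encoder model

Each neuron is modeled by a small feed-forward network mapping the recent
history of P predictor traces to the neuron's activity at the present sample.
The input is a causal window of `history_n` samples per predictor (default 50
samples = 10 s at the default 5 Hz rate); the window's last lag is the
predicted time point, so no future samples can influence a prediction.

The architecture is:

1. **80 linear temporal filters.** Each filter spans the full window, so the
   convolution produces one output per filter per window; convolution +
   flatten is therefore mathematically identical to a single dense linear map
   `D x 80` of the flattened window (`D = history_n * P`), and the layer is
   implemented as such. Having 80 filters is deliberate overparameterization:
   random initial filters provide pre-training variation in temporal feature
   space, which eases learning of indicator dynamics and derivatives.
2. **Two 64-unit dense layers with swish activation** (`x * sigmoid(x)`,
   beta = 1). Swish is twice continuously differentiable, which the Taylor
   analysis requires; ReLU is not.
3. **A scalar linear output.**

For one predictor at 50 lags this totals 13,489 trainable parameters
(with filter biases).

Training minimizes mean squared error plus an L1 penalty (default 1e-3) on
all weight matrices, using Adam (learning rate 1e-3, batch 256) for a fixed
100 epochs. Dropout (rate 0.5) is applied after each dense layer during
training only, so inference is deterministic. The optimizer, learning rate
and batch size are package defaults chosen as stable, standard settings; the
L1 weight, dropout rate and epoch budget jointly bound the model's effective
flexibility (see *Effective degrees of freedom* below). The training split
is strictly temporal: the first two thirds of windows train the model, the
last third measures generalization. A neuron counts as "fit" when its test
correlation reaches `corr_cut` (default 0.5, appropriate for single-cell
traces; 0.1 is the documented lenient setting for blended multi-neuron
signals such as widefield components).

The network and its optimizer are implemented directly in NumPy. At this
scale (tens of thousands of parameters, thousands of samples) NumPy matrix
products train a neuron in about a second on one CPU core, and the
closed-form swish derivatives make input-space gradients and Hessians exact;
unit tests validate both against central finite differences.

## Taylor characterization

All interpretation derives from the value `f`, gradient `J` and Hessian `H`
of the trained network with respect to its *input window*.

**Complexity.** One expansion at the data-mean window scores the variance of
the true network output explained by the first-order truncation (LAS) and
the second-order truncation (SOS), sampling windows every second. Thresholds
LAS ≥ 0.8 (linear), otherwise SOS ≥ 0.5 (second-order) define complexity
classes 0/1/2. The 0.8 cutoff is calibrated by the ROC analysis below.
Whether expansion sampling should use training data only is not critical;
the package samples all windows at the configured stride.

**Predictor attribution.** Because a single global expansion cannot describe
complex neurons, local expansions are made every `taylor_pred_every` samples
(default 5), each predicting the *change* in network output
`taylor_look_ahead` samples ahead (default 25 = 5 s). Changes, not raw
outputs, are compared, so the metric reflects what drives the output rather
than what sets its baseline. The squared correlation between predicted and
true changes (`r2_full`) measures expansion quality. Removing a predictor's
gradient and own-quadratic terms (or a pair's cross terms only) and
rescoring yields the Taylor metric `T = 1 - r2_removed / r2_full`. Expansion
points are bootstrapped (default 1000 resamples); the bootstrap SD is used
as a normal-approximation SE, and a predictor is a significant driver when
`T - z * SE > 0.1` with z one-sided at alpha = 0.05, Bonferroni-corrected
across neurons. Interaction metrics are computed but excluded from neuron
classification by default, since their magnitudes are small even on
ground-truth product neurons.

**Auxiliary nonlinearity metrics.** The curvature proxy averages
`||H(x) u||` over unit-normalized steps `u` between consecutive sampled
windows (the "unit magnitude step" reading; raw-step normalization is the
documented alternative). The nonlinearity coefficient compares linearized
output variance `E[J^T Cov(X) J]` to true output variance and is ~1 for a
linear model on its data distribution.

## Receptive fields and principal dynamic modes

The linear receptive field of a fit neuron is `J` at the training-data-mean
window, reshaped to predictor x lag. Identifiability caveat: on band-limited
stimuli the data only constrain filter components inside the stimulus band —
the same limitation that breaks unregularized Volterra regression (below) —
so exact kernel recovery is only expected for broadband stimuli.

Nonlinear receptive fields come from the eigenstructure of the combined
kernel matrix Q, assembled from `(k0, k1, k2) = (f, J, H)` at the expansion
point — with `k0` in the corner, `k1/2` on the first row/column and `k2` in
the trailing block. Candidate principal dynamic modes are the leading
eigenvectors with the constant-term coordinate stripped and renormalized
(deflating the constant direction instead is a documented alternative).
Because symmetric nonlinearities plant modes with *negative* eigenvalues,
eigenpairs are ranked by eigenvalue magnitude and filters compared by
absolute cosine similarity. For encoder-derived kernels the top 2 candidates
suffice; directly fitted Volterra kernels often carry a constant-term mode,
so the top 3 are searched. With several predictors, Q is built per predictor
from that predictor's `J`/`H` blocks; cross-predictor blocks feed only the
interaction metrics and response landscapes.

**Clustering.** Receptive fields are clustered greedily on cosine
similarity: repeatedly merge the most similar pair (fields or running
cluster means), recompute the mean, stop when no similarity reaches the 0.8
threshold; never-merged fields stay unlabelled (-1). The procedure is
deterministic and order-independent (ties break on the lowest index).
Spectral clustering on the shifted similarity matrix `(S + 1) / 2` is the
faster alternative for large populations and for response-landscape
clustering.

**Response landscapes.** For mixed-selectivity neurons, inputs are built as
`a * RF_a + b * RF_b` with unit-normalized receptive fields ("drives") on a
64 x 64 grid over [-5, 5]; the model's predictions over the grid expose
additive versus gated integration. Landscapes are compared by the maximum of
their normalized 2D cross-correlation, grouping by shape rather than
alignment.

## Volterra baselines and effective degrees of freedom

A second-order Volterra model with 50-tap memory is fit directly by
regression on the polynomial design `[1, lags, unique lag products]`
(unique `i <= j` products, off-diagonals halved on unpacking — identical
model to the full double sum, better conditioned; 1326 columns). OLS falls
back to the minimum-norm solution with a warning when under-determined;
ridge solves the penalized normal equations at configurable alpha (defaults
{0, 1e2, 1e4}). Pre-whitening of the design is intentionally omitted.

Ridge flexibility is the hat-matrix trace `sum(lambda_i / (lambda_i +
alpha))` over eigenvalues of `X^T X`. Network flexibility is estimated by
simulation: fix a signal, redraw i.i.d. output noise across replicates,
retrain, and compute `df = sum_i Cov(yhat_i, y_i) / sigma^2`. This estimator
is exact for linear smoothers (df = trace of the smoothing matrix, verified
in tests) and returns N for an interpolator and 0 for a constant.

## Synthetic ground truth

The generators emulate three study designs:

* **Response catalogue.** Two smooth "sensory" predictors (random mixtures
  of sine/square/triangle waves, component periods 13-200 s), one Poisson
  event train (0.1 Hz) and one normally-scaled Poisson train. Responses are
  linear, rectified, absolute-value, derivative, tanh²(x³), event-driven, or
  rectified-product transforms, convolved with a calcium kernel and
  corrupted with Gaussian noise. The calcium kernel is a single exponential
  (default tau 2.5 s, GCaMP6s-like) — only the existence of a temporal
  kernel matters to the method's claims, not its precise shape. Noise SD
  defaults to 0.25 of the pre-noise response SD. Default trace length is
  3600 samples (12 min at 5 Hz).
* **Linearity calibration.** Labelled cases mix five independent smooth
  stimuli with four responses of the first one: differencing and a random
  double-exponential convolution (linear; rise 0.1-0.5 s, decay 0.5-2 s —
  any causal biphasic kernel serves the linear label), and shift+scale
  softplus rectification and tanh to a random integer power 1-5 (nonlinear).
  Transforms are applied to the raw wave mixture with component amplitudes
  drawn U(1, 3) (trace SD ~ 3): the construction's premise is that
  nonlinear-labelled transforms are *decisively* nonlinear, and saturating
  transforms only are so when driven well beyond their linear range. With
  unit-SD drive, odd tanh powers are ~94% linear and the labels would be
  meaningless.
* **LN-LN system.** One stimulus (white or smooth), two orthogonal 50-tap
  filters, an asymmetric nonlinearity `g_linear(x) = x / (1 + e^(-5x))` and
  a symmetric one `g_nonlinear(x) = (0.25 - e^x / (1 + e^x)^2) * 15`, summed.
  Two filter-pair presets ship (a biphasic/unimodal pair and a smooth pair);
  the linear filter is Gram-Schmidt-orthogonalized against the nonlinear one
  and then scaled so both pathway variances match under white noise
  (Gauss-Hermite calibration) — the stated design goal of the constant in
  `g_nonlinear`.

What the generators do *not* emulate: microscope noise structure, motion
artifacts, spike inference, inter-neuron correlations, or nonstationary
behavior states. Passing tests therefore demonstrate correctness of the
method's machinery under its own assumptions, not performance on real
recordings.

## Reproduction scales and expectations

The test suite and `scripts/acceptance.py` rerun the simulation results at
desk scale on one CPU:

* Linearity ROC and error rates: 50 + 50 cases (instead of 500 sets),
  full-length traces (3600 samples) and the full 100-epoch budget.
* Effective degrees of freedom: 20 noise replicates of the smooth-stimulus
  LN-LN task at 3600 samples.
* Property suites: 20 replicates per response type at 2000 samples /
  50 epochs; 20 white-noise LN-LN simulations at 2400 samples for PDM
  recovery.

Per-neuron local-expansion quality (`r2_full`) is asserted as a median
across the catalogue: complexity-2 responses (absolute value, tanh²(x³))
legitimately fall below 0.8 on individual draws at noise SD 0.25. LAS for
linear response types is likewise asserted per-type as a median over
replicates, since training stochasticity occasionally yields 0.94 on event
types.

## Known limitations

* Gradients/Hessians are exact but the Hessian is dense, `(history_n * P)^2`
  per expansion point; Hessian storage is gated behind `return_hessians`.
* The greedy clustering is O(n³) in the number of receptive fields; use
  spectral clustering beyond a few hundred.
* The NumPy training loop is single-threaded per neuron; batches of neurons
  are processed serially (per-neuron seeds are order-independent, so
  parallelization is safe but not built in).
* With temporally smooth stimuli, train/test distribution shift is real
  (slow components need not repeat across the split); comparison regressions
  with many free columns are more sensitive to this than the regularized
  encoder, which is part of the phenomenon under study.
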