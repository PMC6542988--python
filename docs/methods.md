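# Methods

## Model

Fully connected networks `y_i = W_i a_{i-1}`, `a_i = f(y_i)` with `a_0 = x`
and no bias terms. Activations: tanh, relu, sigmoid, linear; derivatives are
expressed as functions of the activation output (`f'(a) = 1 − a²` for tanh,
`a(1−a)` for sigmoid, `1[a>0]` for relu with `f'(0) = 0`, 1 for linear),
which is the form the local update rules consume. The output layer is linear
and read as logits: the loss is softmax cross-entropy, so the output error
`e = softmax(a_n) − target` is exactly the loss gradient at the logits and
`δa_n = e` needs no activation gate. Everything runs in float64.

Credit rules:

- **BP** — `δa_l = W_{l+1}ᵀ δa_{l+1} ⊙ f'(a_l)`: the chain rule, requiring
  the transposed downstream weights (weight transport).
- **DFA** — `δa_l = B_l e ⊙ f'(a_l)` with a fixed random `B_l` per hidden
  layer; no layer's error depends on any other layer's error or on any
  forward weight, which the test suite enforces with an access-tracking
  double around the weight arrays.
- **SDFA/SSDFA** — the same computation with sparse `B_l`; the per-neuron
  form `(b_row · e) · f'(a)` touches only the nonzero entries and exposes an
  operation counter (one MAC per nonzero plus one multiply) for cost
  validation. With one nonzero per row the error is a three-scalar product.

All rules share the outer-product weight gradient `δW_l = δa_l ⊗ a_{l-1}`,
averaged over the mini-batch (averaging keeps learning-rate semantics
independent of batch size), and plain SGD
`W ← W − η·decay^epoch·δW`. Feedback matrices are never updated. Only SGD
with multiplicative decay is implemented; momentum/adaptive optimizers are
out of scope.

## Weight initialization

`W_i ~ U[−c, +c]` with `c` a configurable function of the layer's fan-out.
Two built-ins are provided — `1/√fan_out` (default, the standard uniform
fan-based scheme) and the literal `1/fan_out` — because reasonable
implementations differ on whether the radical belongs in the bound; nothing
in the test suite depends on which is active. Feedback entries default to
`U[−1/√M, +1/√M]` where `M` is the number of error signals, overridable per
spec.

## Feedback-matrix construction

Target: an `N × M` matrix with exact rank `R`, per-row support size `k`, and
no all-zero column. Feasibility requires `R·(1−S) ≥ 1`; below that threshold
some error column must be entirely zero — those classes would never
propagate back — so generation raises instead.

Construction: `R` base rows are drawn with supports of size `k` whose union
covers all `M` columns (columns dealt round-robin in shuffled order across
the base rows, then each support filled to `k` with random unused columns);
the remaining `N − R` rows are uniform-random nonzero scalar multiples
(magnitude in [0.1, 1], random sign) of uniformly chosen base rows, so they
share the base row's zero pattern and add no rank. Rows are then scattered
into random positions. The achieved rank is verified by SVD
(`numpy.linalg.matrix_rank` at the standard tolerance) and the matrix is
resampled with an incremented seed on the measure-zero failure event, at most
100 times, then errors rather than returning a rank-deficient matrix.

Per-row support size: `k = max(round_half_up(M·(1−S)), ceil(M/R))`. The
second term guarantees the base rows *can* cover all `M` columns; without it
feasible requests near the `R(1−S) = 1` boundary (e.g. `M=10, R=3, S=0.66`,
where `round(3.4)·3 = 9 < 10`) would be uncoverable at constant per-row
support. Under feasibility this keeps the achieved sparsity within `1/M` of
the request. Half-up rounding avoids the surprise of banker's rounding at
`.5` fractions. Per-row support is held constant (the stricter reading of a
fixed per-neuron connection count) rather than only constraining the global
zero fraction.

The single-connection generator deals one distinct column to each of the
first `M` rows (in random order, over a random column permutation) and a
uniformly random column to the rest, so every column is covered at least
`⌊N/M⌋` times, rank is exactly `M`, and sparsity is exactly `(M−1)/M`.

## Alignment angle

For hidden layer `l` in an `n`-layer network the diagnostic is the angle
between `vec(B_l)` and `vec(Pᵀ)` where `P = ∏_{i=l+1..n} W_i`; `P` has shape
`(M × width_l)`, the transpose of `B_l`, and transpose-then-vectorize is the
only shape-consistent comparison. Random feedback against random weights
sits near 90°; the angle falling over training indicates the forward weights
aligning to the fixed feedback. Angles are reported per hidden layer and as
their mean. Zero-norm operands raise rather than returning a convention
value. Near 0° and 180° the arccos is accurate only to ~1e-5 degrees, which
the tests respect.

## Cost model

Counts are words (one weight/activation/error = 1 word) per training
example, per layer, backward pass only:

| rule | reads | writes | MACs | movement |
|------|-------|--------|------|----------|
| BP   | \|W\|+\|A\| | \|W\| | 2\|W\| | \|W\|+\|A\|+\|E_next\| |
| DFA  | \|W\|+\|B\| | \|W\| | \|W\|+\|B\| | \|E\|·\|A\| |
| SDFA | \|W\|+\|b\| | \|W\| | \|W\|+\|b\| | \|e\|·\|A\| |

Movement semantics: BP is modelled on a von Neumann machine (weights,
activations and the downstream error vector pass through main memory); DFA
and SDFA on a near-memory substrate where the only movement is error words
received per neuron, multiplied by the neuron count, applied uniformly to
every layer including the output layer. This uniform reading is the one that
reproduces both headline factors on the 9216-4096-4096-1000 stack — exactly
1000× movement from DFA to SSDFA and ≈6379 ≈ 6.4·10³ from BP to SSDFA —
whereas excluding the output layer gives 7.2·10³. The MAC ratio
`2|W|/(|W|+|b|)` is bounded by 2 because the partial error at each forward
weight still costs `|W|` MACs under every rule. Word size is not modelled
(ratios are unitless); a `word_bytes` presentation factor can be applied by
the caller. Convolutional layers are supported only through caller-supplied
`LayerCounts`; the bundled derivation covers fully connected stacks.
Movement is monotone SDFA ≤ DFA ≤ BP whenever the class count does not
exceed the layer fan-in, which holds for every architecture studied.

## Synthetic tasks

The cluster task draws `n` samples (default 6000, split 5:1 train/test,
classes balanced within ±1) from isotropic Gaussians of scale `noise_scale`
(default 1) around 10 class means in 784 dimensions. `margin` (default 6) is
the distance from each mean to the nearest Bayes decision boundary: means sit
at `√2·margin` along mutually orthonormal random directions, hence pairwise
`2·margin` apart. At margin/noise = 6 the task is comfortably linearly
separable (a linear softmax exceeds 95% test accuracy) while still requiring
the pipeline to estimate means from finitely many samples in a
774-dimensional noise background. The teacher task labels uniform inputs on
[−1,1]^d by the argmax of a frozen randomly initialized network, retrying the
input draw (up to 20 times) if classes are missing and erroring if the argmax
is constant, guaranteeing a realizable boundary.

What the generators do not emulate: pixel correlations, manifold structure,
class imbalance, label noise. Passing the behavioral tests shows the credit
rules assign usable credit and that sparsity costs little *on separable
data*; it does not certify benchmark-level accuracy on natural images, for
which users can point the IDX reader at MNIST-format files.

## Experiment defaults and problem sizes

Training defaults — learning rate 0.1, no decay, batch 64, 5 epochs — were
chosen by a coarse sweep on the cluster task (the package's own
hyperparameter search; learning rate and decay are the swept knobs). Sweeps
default to 10 repeats per (rank, sparsity) cell; the test suite uses 3–5
seeds on a scaled-down task (64 features, 50 hidden units, n = 1200) so each
run takes a fraction of a second, with the full 784/400/6000 configuration
exercised in the acceptance suite. All randomness flows from a single root
seed through fixed derivation offsets (weights, feedback, shuffling, task),
so a config file is a complete provenance record; every CLI run writes its
resolved config next to its outputs.

## Numerical choices and edge cases

- Gradient checks use central differences at step 1e-6 (float64 makes 1e-6
  agreement attainable); activation derivative checks avoid the relu kink.
- Softmax is computed with max subtraction; cross-entropy adds the smallest
  positive float before the log.
- `measure_sparsity` counts exact zeros only — generated values are never
  thresholded, so sparsity is structural, not numerical.
- relu derivative at exactly 0 is 0.
- Divergence (non-finite loss) aborts training with the epoch index;
  non-finite gradients abort the SGD step with the layer index.
- Feedback triplet files store `repr(float)` values, so reload is bitwise.

## Known limitations

- No convolutional/pooling layers, biases (off by default, matching the
  bias-free formulation), momentum or adaptive optimizers.
- DFA/SDFA accuracy claims are only tested on synthetic separable tasks;
  known degradation of feedback alignment on deep convolutional stacks is
  out of scope.
- The cost model is analytic word counting, not cycle- or cache-accurate
  simulation, and reports no energy figures.
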