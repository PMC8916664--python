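# Methods

`gaitproto` implements an explainable open-set gait recognition pipeline for
multimodal insole data: unit-step extraction, a prototyping encoder–decoder
trained with a combined triplet + reconstruction loss, few-shot one-class-SVM
recognition, and attribution-map analysis evaluated by region perturbation.
This note records the model, its assumptions, the defaults that matter, and
the design choices made where the design was genuinely open.

## Signal model and unit-step extraction

A recording is an `N x 28` matrix sampled every 0.01 s: 16 pressure channels
(8 per foot, three discrete levels at acquisition), 6 accelerometer and
6 gyroscope axes.  Plantar pressure is zero while the foot is in the air, so
the summed pressure separates stance from swing.  Segmentation:

1. Gaussian-smooth the pressure channels (default `sigma = 3` samples,
   truncated at ±4σ, reflected boundaries).  Smoothing suppresses sporadic
   non-zero pressure readings during swing that would otherwise split a
   cycle.  The value 3 samples (30 ms) is well below the ~0.6 s stance
   duration of normal walking, so it cannot merge genuine cycles.
2. Threshold the summed smoothed pressure at `swing_threshold = 0.5` (half of
   one pressure level).  Rising edges are stance onsets.
3. A unit step spans one onset to the next — one full cycle, stance followed
   by swing, as the half-open interval `[onset_k, onset_k+1)`.  Leading and
   trailing incomplete cycles are discarded.
4. Each cycle is linearly resampled along time to `T = 100` rows (~1 s at
   100 Hz, a typical walking cycle).  Linear interpolation was chosen over
   spline resampling because downstream losses and attributions operate on
   coarse shape, not derivatives.

After segmentation, exactly-zero pressure entries are replaced by the floor
`delta = 0.01`.  This keeps live data distinguishable from *occluded* entries
(set to exactly 0) in the perturbation analysis.

The per-subject **prototype** is the element-wise mean of the subject's unit
steps, channel by channel.

## Synthetic data generator

The private nature of real insole studies makes a generator a first-class
component.  Each synthetic subject owns a smooth template over one cycle:

* pressure channels: clipped sums of 2–4 random-phase sinusoids over the
  stance window, scaled to unit peak, exactly zero during the swing window
  (default swing fraction 0.35, at the upper end of the physiological ~35–40 %
  swing share);
* acceleration/rotation channels: 4-harmonic random series scaled to unit
  amplitude.

A unit step is a draw around the template: a smooth monotone time warp with
peak displacement up to `jitter * T` rows (default jitter 0.05), additive
Gaussian noise on all channels (default `noise_sd = 0.1` relative to unit
signal amplitude), pressure clipped to ≥ 0, re-zeroed on the swing window and
floored at `delta`.  The defaults give a high but not trivial recognition
ceiling: within-subject steps cluster around their template while templates
differ across subjects.  The default study is 40 subjects x 158 steps = 6,320
unit steps.

What the generator does **not** emulate: ground-reaction-force biomechanics,
pressure-level quantization artefacts (3-level quantization is available but
off by default, since the pipeline treats values as continuous after
smoothing), left/right asymmetries, fatigue drift, or session effects.
Passing tests therefore demonstrate that the pipeline's machinery is correct
and that its statistical assumptions (separable subject signatures, swing
zeros) suffice — not that real-world accuracy at any particular level is
reproduced.

## Encoder–decoder

The encoder `f` maps `(T, 28)` to a unit-norm 128-vector: three parallel
sub-encoders — one per modality block (pressure 16, acceleration 6, rotation
6), parameters independent per block — of three 1-D convolutions with 32, 64
and 128 filters, flattened and concatenated into a dense 256 layer, a dense
128 layer, then explicit L2 normalization.  The decoder mirrors it: dense
256, per-modality dense heads, un-flatten, three transposed convolutions
(128, 64, 32 filters) with adjoint geometry, a 1x1 channel projection, and
per-modality-block L2 normalization.

Choices the architecture left open:

* **Convolution hyper-parameters**: kernel 5, ReLU activations, zero 'same'
  padding, no pooling.  Convolutions use **stride 2**: the flatten width then
  stays modest (13x128 per modality at T=100) and a full study runs on one
  CPU core in minutes; the transposed convolutions are exact adjoints of the
  encoder geometry, so the flatten/un-flatten symmetry is preserved without
  ad-hoc output padding.
* The dense 256 layer uses ReLU; the dense 128 output layer is linear (it
  feeds the normalization).
* The network stack is written directly on numpy with explicit
  forward/backward passes.  This is deliberate: the relevance-propagation
  stage needs per-layer weights, cached activations and the im2col view of
  each convolution, which a hand-rolled stack exposes naturally.

### Losses

* Triplet: `max(0, ||v_a − v_p||² − ||v_a − v_n||² + alpha)` with margin
  `alpha = 1.25`.  The hinge at zero follows the classical metric-learning
  formulation; an unclamped version is unbounded below.
* Prototyping: mean over the 28 channels of the squared distance between the
  per-channel unit-normalized reconstruction and the per-channel
  unit-normalized subject prototype (computed from the training split only).
  Bounded in [0, 4].
* Combined: `L = L_triplet + lambda * L_proto`, default `lambda = 1.0`.

Training: Adam at 1e-3, batches of 64 random valid triplets (positive = a
different step of the anchor's subject, negative = a random step of a random
other subject; no semi-hard mining), default 3 epochs over at most 1,024
anchors per epoch.  The synthetic subjects are separable enough that this
budget converges; both the budget and the learning curve are recorded in the
training log, and all sampling is driven by one seed, so runs are exactly
reproducible.

## Open-set recognition

Per repetition, subjects are partitioned 20/10/10 into training / known /
unknown groups.  For each known subject, `n = 10` shot steps are reserved;
their embeddings give the centroid `D_a` (plain mean, not re-normalized) and
a one-class SVM with RBF kernel `K(v,v') = exp(−gamma ||v−v'||²)`:

    min_a  1/2 sum_ii' a_i a_i' K(v_i, v_i')
    s.t.   0 <= a_i <= 1/(nu n),   sum_i a_i = 1

The offset is `delta_p = sum_i a_i K(v_i, v_h)` for a margin support vector
`h` (`0 < a_h < 1/(nu n)`); when no strictly interior multiplier exists
(possible at very small n), the offset falls back to the average of the
decision sums over all support vectors.  A query goes to the nearest centroid
(squared Euclidean distance, ties to the smallest subject id; no fall-through
to the second-nearest on rejection) and is accepted iff `h_p(v) >= tau`.
Defaults: `gamma = 2.2`, `nu = 0.06`, `tau = −0.1`.

Numerics: the dual is solved by libsvm (scikit-learn) with a tight tolerance,
rescaled from libsvm's multiplier convention (box 1, sum `nu·n`) to the one
above, then *polished* by an exact linear solve of the stationarity system on
the free set — KKT residuals land at ~1e-12, and every margin support vector
sits on the decision boundary to ~1e-15.  `n = 1` is handled in closed form
(`a_1 = 1`, `delta_p = 1`).

Scoring: a known-test step is a true positive only if accepted **and**
assigned to its true subject; misidentification and rejection both count as
false negatives.  An accepted unknown-test step is a false positive no matter
which subject it matched.  An empty unknown set yields TNR = NaN with a
warning rather than an error.

## Attribution

Both methods explain one embedding component `c` at a time and average the
128 per-component maps:

* **SA**: `|d f(s)_c / d s_ij|` by back-propagation, including through the
  final L2 normalization (its gradient is well defined).
* **LRP-eps**: relevance starts one-hot at component `c` with the
  component's *pre-normalization* output value — the normalization stage has
  no weighted connections, so the redistribution rule does not apply to it.
  At each dense or convolutional layer, relevance is redistributed in
  proportion to the contributions `x_i w_ij`, with the stabilizer
  `eps * sign(denominator)` (default `eps = 1e-7`, sign(0) := +1) added to the
  denominator.  Convolutions are handled through their im2col view — exactly
  their equivalent sparse dense connections.  Bias relevance is absorbed
  (biases enter the denominator but are not redistributed), the common
  convention; with bias-free layers and `eps = 0`, layer-wise conservation
  holds to machine precision.  ReLU layers pass relevance through unchanged.

The **common attribution map** is the grand mean of the component-averaged
maps over training steps, each step weighted equally.  In full-scale runs it
is computed over a per-subject subsample (default 5 steps per training
subject, i.e. 100 steps): computing a full Jacobian per step costs 128
backward passes, and the map stabilizes well before the full 3,160-step
average; the subsample size is configurable.

**Region perturbation**: all `T x 28` positions are ranked by relevance
magnitude (descending; ties broken row-major for reproducibility) and split
into quintiles O1..O5 — O5 absorbs any `L mod 5` remainder.  For each
quintile, every test step is occluded (entries set to exactly 0) at those
positions and the *fixed* pipeline (encoder, centroids, boundaries untouched;
shots are never occluded) is re-scored.  The random baseline occludes |O1|
uniformly random positions, drawn fresh per step from a seeded generator.
Signed LRP maps are ranked by magnitude because embedding components carry no
class semantics, so the sign of a relevance score has no fixed meaning.

## Degenerate inputs and tolerances

* All-zero signals are rejected by every normalization with an explicit
  `ZeroDivisionError`; zero pre-activations with `eps = 0` raise and point to
  a positive stabilizer.
* The encoder asserts unit output norm to 1e-6 (float32 forward pass);
  numerical oracles (gradient checks, LRP conservation, QP comparisons) run
  in float64 where 1e-6–1e-12 tolerances apply.
* `nu` outside (0, 1] makes the dual infeasible and is rejected up front;
  `gamma <= 0` likewise.

## Problem sizes used in the shipped analyses

The repeated-split study runs at full scale (40 x 158 steps, T = 100, ten
repetitions, retraining the encoder per repetition).  The perturbation
analysis reuses the first repetition's pipeline and a 100-step common-map
subsample.  Unit-level numerical checks use short steps (T = 8–16) so that
brute-force oracles (dense-matrix LRP, finite differences, loop-based means)
stay exact and fast.

## Known limitations

* The generator's statistical simplicity means recognition accuracy here is
  an upper bound on what identical settings achieve on real insole data.
* LRP is implemented for the encoder path only (the quantity the attribution
  stage explains); the decoder is explained indirectly through its role in
  training.
* Occlusion replaces entries with 0, which for pressure is outside the live
  data range by construction (floor `delta`); this is intentional and mirrors
  the evaluation design, but it means perturbation measures out-of-range
  sensitivity, not counterfactual plausibility.
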