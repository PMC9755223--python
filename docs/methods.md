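# Methods

This note documents the model choices, defaults, numerical details and
known limitations of the package. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Wake model

Networks are bias-free multilayer perceptrons: `weights[l]` of shape
`(n_{l+1}, n_l)`, rectifier hidden units, raw logits into a softmax
cross-entropy. Bias-freeness makes the network positively homogeneous
(scaling an input by c > 0 scales every pre-activation by c), which is what
lets the sleep conversion use pure per-layer scale factors with no offset
terms; it is enforced structurally (there is no bias parameter to disable).

Training is mini-batch SGD with classical momentum
(v ← μv + g, w ← w − ηv), inverted dropout on hidden activations only
(never on input or output, disabled at evaluation and during sleep), and
the loss evaluated on the presented samples only. Defaults for the
MNIST-class setting: η = 0.065, μ = 0.5, 10 epochs/task, batch 100, dropout
0.2, uniform init in ±0.02. A per-task learning-rate list can be emulated
by passing a different `TrainingConfig` per task through `run_protocol`'s
building blocks.

Evaluation is always single-head over all classes of the full protocol;
argmax ties are broken toward the lowest class index (NumPy argmax
semantics, documented and tested — an all-zero network on a balanced
4-class set scores exactly 0.25).

## Sleep phase

Conversion computes, per non-input layer,

    scale_l = max_act_l / max(max_weight_l, max_act_l),

where `max_act_l` is the layer's maximum wake activation over a reference
batch (one pass of the last task's training data) and `max_weight_l` the
layer's maximum positive weight. This is the data-based normalization
variant: the scaled propagated activity of the reference batch is bounded
by the layer's own maximum observed activation, with equality when the
activation term dominates. The max-weight term can be dropped
(`use_max_weight=False`). A layer with all-zero reference activation gets
scale 1 and a warning. Configured `scale_multipliers` stack on top. Scales
are applied at propagation time only; the stored weights are never
rescaled, so wake→sleep→wake with zero sleep steps is bit-exact.

Dynamics per step, layer by layer: `v_l += scale_l · W_l · s_{l-1}`, spike
where `v_l > θ_l` strictly, spiking voltages reset to exactly zero,
sub-threshold voltages persist. There is no leak, no refractory period and
no voltage floor. The input frame is redrawn every step as independent
Bernoulli events with p = the stored mean intensity per pixel (a one-step
Poisson event with rate ≤ 1 is the same Bernoulli draw; rates outside
[0, 1] are clipped with a warning). An alternative input mode drives every
pixel at a flat rate (default 0.5) for the replay analyses, so the noise
carries no information about past inputs.

Plasticity acts on the unscaled weights. The exact identity
ΔW = inc·C − dec·D, with C and D the per-synapse co-spike and post-only
counts, is asserted against the raw spike log in the tests — the update is
integer-weighted and exact in floating point at these magnitudes. Silent
post-neurons never have synapses modified; with dec = 0 no weight can
decrease, with inc = 0 none can increase. The output layer participates in
plasticity like any other layer.

### Hyperparameters and the shipped search

Thresholds, duration, inc and dec are protocol-level settings. No
universal values exist — the working point depends on the layer sizes,
weight scale and input statistics — so this package ships
`tune_sleep_hyperparameters`: a deterministic grid search that runs a
candidate sleep on a copy of the network and scores accuracy on the
*training* data of the tasks seen so far (never test data; ties go to the
earliest grid point). All desk-scale protocols re-run it before each sleep
phase. Default grids:

* toy model: θ ∈ {0.25, 0.5, 1, 2}, T_s ∈ {500, 2000},
  (inc, dec) ∈ {(.002, .002), (.002, .004), (.004, .002)};
* fixture networks: per-layer θ triples {(2, .5, .5), (2, 1, 1), (1, .5, .5),
  (3, .5, .5)}, (inc, dec) ∈ {(2e-4, 1e-4), (5e-4, 2.5e-4)}, T_s = 1500.

The per-layer structure matters: a high first-hidden threshold makes
layer-1 firing sparse and stimulus-selective, while lower deeper thresholds
keep the upper layers and the readout excitable; this combination is what
produces full recovery on the fixture.

## Toy binary-patch model

Four binary 10×10 images, two per task, each with 18 on-pixels; the paired
cross-task images (0↔2, 1↔3) share exactly `overlap` pixels and all other
on-pixel sets are disjoint, so interference is a single dial. The classifier
is a bare 100→4 softmax layer trained full-batch with learning rate 0.1, no
momentum, no dropout, to a loss plateau (|ΔL| < 1e-5, max 500 epochs). The
on-pixel count 18 was fixed so that the catastrophic-forgetting boundary
falls at 12 overlapping pixels (100% final accuracy below 12, 50% at 12 and
above, stable across seeds and across convergence tolerances 1e-3…1e-7);
with 20 on-pixels the same boundary sits at 13. Sleep input statistics are
the running mean of the four training images (0.5 for overlapping pixels,
0.25 for unique ones).

### How far sleep can go on the toy model — a budget argument

Sleep recovery on the toy model is complete exactly at the boundary overlap
(12) and does not extend deeper, for a structural reason. Only the
recent-task outputs spike under noise. Each spike applies dec to every
silent input pixel and inc to every active one, so the output's
*probability-weighted* input drive Σᵢ pᵢ wᵢ falls by a bounded amount per
spike; without a voltage floor the accumulated drift silences the output
permanently once its mean drive reaches zero. The total depression a
recent-task output can distribute is therefore capped by its initial mean
sleep drive (measured ≈ 1.15 at overlap 14), while the logit gap that must
be closed to re-classify an old-task image grows with overlap (≈ 2.4 at
overlap 14). Spike-conditioned selection makes matters worse: spikes
coincide with frames where the overlapping pixels are on, so inc
concentrates on exactly the weights that misclassify the old task. The
weight-level signature — task-1-unique → task-2-output weights driven
inhibitory, by about −2.4 — appears at every overlap (see
`weight_category_histograms`); the *accuracy* consequence is only decisive where
the gap is small, i.e. at the boundary. A 250-point random search over
(θ, T_s, inc, dec), a voltage-floor variant, flat input noise and
near-critical dec/inc ratios all respect this cap. The acceptance test for
this behaviour asserts strict recovery across the whole 12–16 range and is
therefore expected to fail beyond the boundary; it is kept as stated rather
than weakened, with this section as the analysis.

## Synthetic image fixture

`two_task_synthetic_spec` builds a four-class Bernoulli pixel model on a
10×10 grid: a 30-pixel block shared by all classes at p = 0.375 (the
analogue of shared stroke structure — the source of representational
overlap between tasks), a 15-pixel class signature at p = 0.9, background
at p = 0.05, plus a 2% pixel-flip noise; 250 training and 50 test samples
per class. The fixture protocol trains a 100-400-400-4 network for 30
epochs/task (the small input needs more passes than real image data to
reach the over-trained regime where forgetting is deep). Under these
conditions sequential training forgets task 1 (overall 0.50–0.65), and the
tuned sleep phase restores overall test accuracy to ≈ 1.0 on every seed
tested, while the mean between-class correlation of hidden activations
drops in both hidden layers (e.g. layer 1: 0.25 → 0.18, layer 2:
0.32 → −0.18 at seed 0).

What the fixture does *not* emulate: spatially correlated strokes,
within-class style variation, class imbalance, grey levels (samples are
binary), and any geometry in the pixel grid — the generator treats pixels
independently. Passing tests therefore demonstrate the mechanism
(noise-driven replay + local plasticity recovering a forgotten task on
networks with hidden layers), not performance on natural images; the
real-data path is `scripts/integration_real_data.py`.

The shared-block interference level deliberately sits below the point where
the sleep noise is dominated by class-independent structure: with a much
stronger shared block (p ≳ 0.45) the first hidden layer re-correlates
during sleep even though accuracy still recovers.

## Replay analysis

Task-specific neurons: each class's examples are encoded as Bernoulli
frames (p = pixel intensity, a fresh example per pass, cycling the test
pool) and presented to the sleep-mode network for 25 forward passes;
per-neuron spike counts are tallied for hidden layers only (the readout is
excluded), each neuron is assigned to its maximal class (ties to the lower
class index) and the top-100 by count are kept per class (count ties to the
lower neuron index; a smaller assigned pool is returned whole with a
warning).

Firing comparison: per-neuron mean rates from a uniform-noise sleep run,
pooled two-sample t-test (equal-variance, matching the reported degrees of
freedom convention) of a task's concatenated per-class sets against a
random subset of the same layer, one-sided by default with a Bonferroni
factor over the comparisons performed; the two-sided variant is available
for completeness. On the fixture the recent task's sets
fire far above a random subset in both hidden layers (t ≈ 6–12); the old
task's sets sit at or below random after forgetting — the recent-vs-old
contrast is the statistically decisive one.

Sparseness is reported two ways, since more than one reasonable
definition exists: the fraction of hidden units with activation
below 1e-6 per stimulus, and the Treves–Rolls population sparseness
(mean r)²/mean(r²).

Correlation matrices average the pairwise Pearson correlation of activation
vectors over all cross pairs of samples (distinct pairs on the diagonal);
zero-variance samples are excluded and an entry with no valid pair is NaN,
never silently 1.

## Protocol bookkeeping

Every run derives independent child seeds (weight init, batch order and
dropout, rehearsal sampling, sleep noise) from a single master seed, and
identical configuration + seed reproduces the accuracy table bit-for-bit.
Rehearsal buffers sample each finished task's classes uniformly without
replacement at the task boundary; mixed batches weight the two loss terms
1/N and 1 − 1/N with the gradient computed over the batch members of each
pool, and a batch without old samples contributes only the current-task
term. Problem sizes in the test suite (hidden widths 60–400, ≤ 1000
training images, sleep ≤ 2000 steps) were chosen as the smallest at which
the qualitative phenomena are stable across seeds.

## Known limitations

* No biologically detailed neuron model: no leak, adaptation, inhibitory
  populations or oscillations; sleep staging is out of scope.
* Toy-model sleep recovery is confined to the forgetting boundary (see the
  budget argument above).
* Convolutional backbones are not implemented; feature-vector CSVs from an
  external extractor are accepted instead.
* `identify_task_neurons` resets voltages between classes, making class
  blocks independent; a continuous presentation would mix carryover across
  classes and is not what the 25-pass analysis describes.
* The old-task neuron sets on the fixture do not exceed a random subset
  during uniform-noise sleep; only the recent task's do. The fixture's
  task-1 traces are weaker than in real image data after deep forgetting.
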