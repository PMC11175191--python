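# Methods

## Problem setting

Two-class classification of multichannel EEG trials (condition 0 = "truth",
1 = "lie"). A trial is a `(channels × samples)` matrix from a reduced 10–20
montage (default Fz, Cz, Pz, O1, O2) at 500 Hz. The pipeline is end-to-end:
no hand-crafted features — the classifier consumes min–max-scaled raw trials,
with each EEG channel a vertex of a functional-connectivity graph and the
trial's time series as that vertex's feature vector.

## Preprocessing

1. **Montage reduction** to the named channels (case-insensitive 10–20
   matching, rows reordered to the request).
2. **Notch filter** at 50 Hz (mains), IIR with quality factor Q = 30
   (config-exposed).
3. **Band-pass** 2nd-order Butterworth, 0.05–60 Hz.
4. **Epoching** into sliding windows (length/stride in samples; trailing
   partial windows dropped). Defaults use 1,000-sample (2 s) trials; the
   full-width 10,000-sample layout is available via configuration.
5. **Scaling** per trial and channel into [0, 1]:
   `x' = (x − min)/(max − min)`; a constant channel maps to all-zeros by
   convention.

All filters run forward–backward (`filtfilt`), so the effective magnitude
response is the squared single-pass response and symmetric deflections keep
their latency (argmax shift ≤ 1 sample — tested). Zero-phase filtering was
chosen over causal filtering because latency distortion is unacceptable in
ERP-like analyses; attenuation tests account for the squared response.

**Noise injection** for robustness sweeps adds zero-mean Gaussian noise per
trial with variance `P_signal / 10^(SNR_dB/10)`, where `P_signal` is that
trial's mean square. Noisy copies are re-scaled exactly like clean trials
before entering the model. Injection happens at evaluation time on test data
only; training data are never perturbed by the sweep.

## Channel graph

Edge weights are absolute Pearson correlations between channels, pooled by
concatenating the **training** trials along time (per-trial averaging is
available as a config alternative). Absolute rather than signed correlation
is used because bipolar EEG derivations make edge signs montage-dependent;
coupling strength is what matters for the graph. Weights below a threshold
`tau` (default 0.3, config `graph.threshold`) are zeroed. Test and
validation trials never touch the graph estimate; the pipeline asserts this.

From the adjacency `W`: degree `D_ii = Σ_j W_ij`, combinatorial Laplacian
`L = D − W` (the unnormalized form; the symmetric-normalized variant is
deliberately not used), eigendecomposition `L = U Λ Uᵀ` with ascending
eigenvalues, and the affine rescaling `L̃ = 2L/λ_max − I` that maps the
spectrum into [−1, 1] for Chebyshev filtering. Disconnected graphs (multiple
zero eigenvalues) are permitted but logged as a warning — the default
synthetic benchmark intentionally plants two components.

## Classifier

Input dropout (rate 0.1), then six blocks of

    Chebyshev graph convolution → batch normalization → TF-2 activation

then flatten (`n_nodes × last_width`), a 2-unit dense head and softmax.
A config flag swaps activation and batch norm. The convolution computes

    Y = Σ_{s=0}^{S−1} T_s(L̃) · X · Θ_s + b,
    T_0 = I,  T_1 = L̃,  T_s = 2 L̃ T_{s−1} − T_{s−2},

with weight tensor `Θ` of shape `(S, in, out)`; `S` counts Chebyshev *terms*,
so `S = 1` is a per-vertex linear map (the reference configuration) and
`S ≥ 2` mixes graph neighborhoods. Per-layer learnable-scalar accounting is
`S·in·out + out`; at full width (10,000 → 10,000 → 5,000 → 2,500 → 1,250 →
625 → 312, S = 1) the six layers hold 100,010,000 / 50,005,000 / 12,502,500 /
3,126,250 / 781,875 / 195,312 parameters — verified by model introspection in
the acceptance suite. The dense head consumes `n_nodes × 312 = 1,560`
features in that configuration. Weight init is scaled-uniform fan-in
(`U(±1/√fan_in)`), biases zero, all seeded.

ReLU and Leaky-ReLU are drop-in activation alternatives for ablation runs;
the whole training harness is identical under a single config change.

## TF-2 activation

Each activation layer carries one learnable triple `γ = [α, P, N]`:

    f(σ) = P σ k(σ; α)      σ > 0
    f(σ) = N σ k(−σ; α)     σ ≤ 0
    k(s; α) = ½ [ 1/(α + (1−α)s) + (1−α)/(1 − αs) ],  s ∈ [0, 1]

`k(1; α) = 1` for every α, hence `f(1) = P` and `f(−1) = −N`; with the
defaults α = 0.5, P = 1, N = 0.1 the unit starts Leaky-ReLU-like. As α → 1
the kernel flattens to ½ (a purely linear regime). The kernel argument is
clamped at |σ| = 1 and the function continues exactly linearly beyond (slope
P resp. N): this avoids the kernel's pole at `s = 1/α` for unbounded
pre-activations, and since `∂k/∂α` carries a factor `(1 − s)` the parameter
gradient vanishes smoothly at the clamp boundary. Batch normalization
upstream keeps most pre-activations inside the curved region.

All four partials (`∂f/∂σ, ∂f/∂α, ∂f/∂P, ∂f/∂N`) are implemented
analytically; layer gradients sum over all elements of the batch. They are
validated against central finite differences (h = 1e−5, rtol 1e−4, 1,000
random draws) — this gradient-check is the correctness anchor for the unit.
The triple follows its own momentum rule

    Δγ ← ρ Δγ + ξ ∂L/∂γ,   γ ← γ − Δγ   (ρ = 0.9, ξ = 0.01 default),

independent of the weight optimizer; a config flag routes γ through the main
optimizer instead. α is re-clamped into [1e−3, 1 − 1e−3] after each step.

## Training protocol

Stratified (by class) random 70/20/10 train/validation/test split, rounding
residue to train; a subject-wise split mode exists for leakage-sensitive
analyses (the default random split can place trials of one subject in
several partitions — appropriate for the within-subject design emulated
here, but it does overestimate cross-subject generalization). Cross-entropy
loss, Adadelta (ρ = 0.95, ε = 1e−6) with decoupled weight decay 4e−6, batch
16, up to 200 epochs, best-validation-accuracy checkpoint restored at the
end. Non-finite loss aborts with a diagnostic.

Desk-scale runs (the tested configuration) use feature widths
1000 → 64 → 48 → 32 → 24 → 16 → 8, Adadelta multiplier 1.0 (the canonical
parameter-free Adadelta step; the full-scale default keeps the reference
0.001) and 80 epochs — sizes chosen so a complete train/evaluate cycle takes
roughly ten seconds on one CPU while still exercising all six layers.

Training batches are augmented with **random circular time-shifts**: each
trial is rolled by an independent uniform offset. For the (quasi-)stationary
oscillatory signals involved, class information (band power, coupling) is
invariant to circular shifts, while trial identity is not — this is the main
defense against memorizing individual trials at small sample sizes, and it
is what lifts held-out accuracy from ~0.75 to >0.95 on the benchmark. It is
on by default and config-exposed.

## GAN augmentation

One GAN per class (class-conditional augmentation is the only way generated
trials can carry labels). The generator maps a 100-dim uniform latent vector
through dense widths 512/1024/2048/4096 to the output length (7,500 at
reference scale), batch-normalized Leaky-ReLU hidden layers, sigmoid output
in [0, 1]; the discriminator is five dense layers ending in a sigmoid. The
printed "layer diameters" of the reference design only parse as dense
widths, so dense stacks are used throughout. Training alternates one
discriminator ascent step on `V` and one generator step (minimax by default,
non-saturating available), plain SGD, batch 10, 200 iterations.
Multichannel trials are generated channel-concatenated as single vectors.

Desk-scale GANs (output length 256, widths 16/32/64/128/256) keep the
200-iteration budget but use SGD lr 0.1 and the non-saturating loss — at toy
scale the reference lr 1e−4 leaves both networks at initialization. The
sanity criterion is spectral: the mean normalized power spectrum of
generated trials must be closer (L2) to the real class mean spectrum than
draws from an untrained generator.

Augmented trials carry provenance `"gan"`; the splitter/pipeline refuse them
in validation or test partitions.

## Synthetic benchmark

Each channel is a unit-variance mixture of AR(2) resonators at
delta/theta/alpha/beta centers (2/6/10/20 Hz), 1/f background (amplitude
0.3) and white sensor noise (0.2), scaled to ~20 µV with mild per-subject
gain jitter (SD 5%). Class contrast lives in two places:

* **Band power** — truth: alpha-dominant (amplitude 1.2 vs beta 0.4); lie:
  beta-dominant (1.1 vs alpha 0.4); alpha is weighted toward posterior
  channels, beta toward frontal ones.
* **Coupling** — shared broadband sources injected into channel pairs with
  per-class strengths: (Pz,O1) 0.8/0.3, (Fz,Cz) 0.3/0.8, (O1,O2) 0.7/0.7.
  A coupling `c` maps to mixing weight `λ = c/√(1−c²)`, giving a
  single-pair channel an expected inter-channel correlation of exactly `c²`.

`effect_size` scales every class difference linearly; 0 makes the classes
distributionally identical (the null control trains to chance). The pooled
planted couplings produce |r| ≈ 0.4–0.5 on coupled pairs and ≈ 0 elsewhere,
so the default threshold 0.3 recovers exactly the planted edge set.

What the generator does **not** emulate: ERP morphology (no P300
templates), artifacts (blinks, EMG), volume conduction / reference effects,
non-stationarity across a session, and realistic inter-subject variability.
Passing tests therefore demonstrate that the machinery — filters, graph
estimation, spectral convolutions, TF-2 learning, the GAN and the harness —
works as specified on signals with EEG-like second-order structure; they do
not certify performance on real recordings.

Named fixtures: `tiny` (2 ch × 256 × 40 trials, unit tests), `default`
(5 ch × 1,000 × 400, integration and acceptance), `paper_scale` (5 ch ×
10,000 × 40, construction/smoke only). Each returns a manifest of its
assertable properties.

## Numerical choices and degenerate inputs

* Float64 throughout by default; the full-width architecture is built in
  float32 to halve its ~1.3 GB footprint (construction only).
* Exact symmetrization of correlation matrices (corrcoef is symmetric only
  to the last ulp).
* Zero-variance channels abort graph construction with the channel named;
  an empty thresholded graph (λ_max = 0) aborts with advice to lower tau.
* Metric ratios with zero denominators report NaN with a warning, never a
  silent 0. κ is Cohen's standard two-rater chance-corrected agreement.
* ROC points come from the standard threshold sweep (scikit-learn), area by
  trapezoid; the rank-statistic equivalence is tested.
* ε-clamping (1e−7) inside all GAN logs.
* Seeds: every stochastic component (simulation, splits, init, dropout,
  shift augmentation, noise injection, GAN) takes an explicit integer seed;
  no global RNG state is used or mutated.

## Known limitations

* The reference trial-length bookkeeping is internally inconsistent
  (30 s × 500 Hz = 15,000 samples per trial, a 7,500-sample generator
  output, a 10,000-feature network input); trial length is therefore pure
  configuration here, and "augmentation from 7,500 to 10,000" is read as
  trial counts, not sample lengths.
* The flatten-stage accounting of the reference architecture (624 features)
  cannot be reconciled with 5 vertices × 312 features = 1,560; the head uses
  the latter.
* With S = 1 (the reference setting) graph structure enters only through
  batch statistics, not through neighbor mixing; S ≥ 2 configurations are
  first-class and tested, but the benchmark's headline numbers use S = 1.
* Dense (not convolutional) GAN networks; no WGAN/spectral-norm variants;
  generation quality is assessed only by the spectral sanity metric.
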