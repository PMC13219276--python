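# Methods

## Problem setting

K clients each hold a local labeled image set D_i and collaborate on one
classifier θ by exchanging parameters, never images. The server's job each
round is to choose the convex weights w (Σ w_i = 1, w_i ≥ w_min) with which
client updates are averaged. Under label skew — clients seeing different
disease mixes — the data-proportional FedAvg choice ignores that some
clients are reliable precisely on the classes the global model currently
gets wrong. AdaClass (see the README for the seven steps) reallocates a
bounded fraction of the weight mass toward such clients.

Design points worth stating explicitly:

* **Warm-up.** Early per-class F1 estimates are noise; the first
  `r_warmup = 3` rounds use FedAvg weights unchanged, and the momentum
  buffer stays empty through warm-up, so the first adaptive round applies
  no smoothing and the second onward does.
* **Percentile rule.** The τ-percentile threshold uses linear interpolation
  between order statistics. When every class has identical F̄ the ≤ rule
  would flag all classes; we return the empty set instead — nothing is
  struggling if nothing is behind.
* **Availability.** A client is scored only on classes it holds samples
  for (local count > 0); clients without samples in any flagged class are
  scored on overall F1 alone, so farms are not penalized for diseases they
  have never seen. `f_low` and `f_overall` are unweighted means over the
  relevant classes.
* **Floor.** Clamp-then-normalize is a single pass; renormalization can
  leave a floored entry marginally below `w_min` (e.g. (0.01, 0.99) with
  floor 0.05 → (0.048, 0.952)). This is accepted; no iterative projection.
* **Reduction.** With α = 1, β = 0, w_min = 0 the rule is exactly FedAvg,
  which the tests assert bitwise round by round.

FedDyn follows the cited dynamic-regularization formulation: the client
objective adds `−⟨h_i, θ⟩ + (α_dyn/2)‖θ−θ_g‖²`, the client state updates as
`h_i ← h_i − α_dyn(θ_i − θ_g)`, and the server applies
`θ ← mean(θ_i) − h/α_dyn` with its own running `h`; at `α_dyn = 0` the whole
scheme collapses to FedAvg (the correction is skipped rather than divided
by zero). Buffers (normalization running statistics) are plainly averaged
under every strategy; the FedDyn correction touches trainable parameters
only.

## Training protocol

Local training uses AdamW (lr 0.001, weight decay 0.01), minibatch 32
(evaluation batches 64), class-weighted cross-entropy with weights
`w_c = N/(C·n_c)` from the *global* training distribution, gradient-norm
clipping at 1.0, and a warm-up + step-decay schedule: linear warm-up over
the first 10% of round-epochs, then ×0.5 at 75% and 90% of the run. The
milestones are this package's choice; placing the decays near the end keeps
the mid-run learning rate at its base value, which federated averaging
needs — client updates partially cancel, so the effective global step is
smaller than the local one. Optimizer state is local to a round (clients
are stateless between rounds). The FedProx/FedDyn penalties enter through
their exact parameter-space gradients rather than autodiff, which is
algebraically identical and cheaper.

Per-class F1 for the aggregation rule is measured on a stratified local
validation split (`val_fraction = 0.1`, at least one sample per present
class), computed with scikit-learn's `f1_score(zero_division=0)`. Whether
round F1 should come from local train or held-out data is genuinely
underdetermined; a held-out split avoids rewarding memorization at the cost
of noisier estimates on small clients.

The 10-client default runs 18 rounds × 2 local epochs with Dirichlet
α = 1.0; a 3-client preset (30 rounds × 1 epoch, α = 0.3) mirrors the
low-heterogeneity configuration. All clients participate every round; the
final-round global model is the deliverable (no early stopping). Every RNG
stream — partition, model init, batch order, augmentation, dropout — is
derived from the single run seed, and the partition depends on the seed
only, so all strategies compare on byte-identical client data.

## Partitioning and diagnostics

Per class, one Dirichlet(α·1_K) proportion vector is drawn, converted to
integer quotas by largest-remainder rounding (ties to the lower client id),
and the class's shuffled samples are dealt out; empty clients are legal.
The heterogeneity report gives per-client sample counts, dominant class
share, number of classes present, and Jensen–Shannon divergence in base-2
logs (so JS ∈ [0,1]) — measured against the **global training label
distribution**, not the uniform one: the published per-client values are
small exactly for clients whose mix resembles the global mix. Summary
dispersion uses the population standard deviation (÷K), the convention that
reproduces the published client-table summaries.

## Imaging

Deterministic preprocessing (train *and* inference): CLAHE → gamma → denoise.
CLAHE is implemented in-package with clip-limit semantics — per-tile
histograms (8×8 grid, clamped so tiles span ≥ 8 px), excess above
`clip·area/256` redistributed uniformly, midpoint-CDF lookup tables,
bilinear interpolation between tiles. Clipped equalization preserves
mid-range constant images exactly but biases extreme constants toward
mid-gray by a gray level or two; tests pin the mid-range fixed point.
Gamma uses `v → 255·(v/255)^(1/γ)` with γ = 1.2, i.e. brightening, matching
its stated purpose of revealing symptoms in dim imagery. Denoising is
bilateral (default) or Gaussian.

Stochastic train-only augmentation applies, each with probability 0.5 in a
fixed order: horizontal flip, vertical flip, rotation ±15°, affine
(translate/scale within ±10%), color jitter (±20% brightness / contrast /
saturation), unsharp-mask sharpening (strength 1.5). Magnitudes beyond the
rotation bound and probability are package choices. The draw order is part
of the contract so seeded runs reproduce exactly.

## Model

Backbone → 1×1 head convolution into the attention width → MobileViT-style
block → CBAM → ESA → global average pool → dropout 0.2 → affine classifier.
The bundled `tiny` backbone is three stride-2 conv/norm/SiLU stages
(overall stride 8, 32 output channels); the ImageNet backbones plug into
the same slot via `register_backbone` when an implementation is present.
The MobileViT block unfolds the feature map into `patch_size = 2` pixel
groups and runs 4-head self-attention across patch positions with an
internal width equal to the attention channels, single transformer layer.
CBAM uses reduction 16 with a bias-free bottleneck (channel gate of a
1280-wide map: 2·1280·80 = 204,800 parameters) and a 7×7 spatial gate; ESA
concatenates channel-wise average/max maps, passes them through dilated
3×3 convolutions at rates {1, 2, 3}, and fuses with a 1×1 convolution into
a sigmoid gate. Spatial gates use edge-replicate padding so a constant
input yields a spatially constant gate. Three architecture rows are pinned
by closed form regardless of backbone internals: stem conv+norm 928, head
conv+norm 412,160, classifier 8,967 (for 7 classes). Input resolution 224
is the published configuration; desk-scale runs use 32–64 px.

The layers run on `adaclassfl.nn`, a compact reverse-mode autodiff engine
over numpy (fused im2col convolution, attention, batch/layer norm, AdamW);
every primitive is verified against central finite differences in the test
suite. Arrays are float64 in memory; size accounting reports the 32-bit
deployment footprint.

## Synthetic data

The generator renders a shaded elliptical leaf with a midrib on a soil
background and stamps one motif per class: (0) clean leaf, (1) circular
brown spots, (2) one large irregular dark patch, (3) parallel yellow
streaks, (4) concentric orange rings, (5) marginal necrosis, (6) pale
mottling — the visual vocabulary of field-captured maize disease imagery,
which caps the class count at 7. Default class priors follow the published
maize imbalance (4.2%–20.6%). The `difficulty` scalar linearly interpolates
lesion color toward the leaf color, so contrast → 0 as difficulty → 0;
a mean-color nearest-centroid probe scores ≈ 0.95 at difficulty 1.0 and
degrades monotonically, which the tests assert. Gaussian pixel noise
(σ = 3) and small per-image color jitter (±4) keep the task non-trivial
without breaking separability.

What it does *not* emulate: photographic texture, lighting and background
variation, intra-class disease-stage progression, inter-class visual
overlap, or label noise. Passing tests therefore demonstrate the
*mechanics* of the pipeline — partitioning, weighting, optimization,
metrics — not field performance on real crops.

The F1-fixture generator produces aggregation inputs without any training:
per client, a sample count uniform on [50, 500], a Bernoulli class-
availability mask (at least one class forced present), and per-class F1
drawn from Beta distributions centered on the requested means (an infinite
concentration collapses to the means exactly).

## Desk-scale experiment sizing

The reference experiment (`desk_scale_experiment`) uses 1,400 images at
32 px: 10 clients then hold ≈ 100 training images each, giving enough local
steps per round for federated averaging to converge within the fixed
18-round budget; one run takes roughly three minutes on a single CPU core
and a majority of seeds exceeds 0.9 final test accuracy. Dispersion across
seeds in strategy comparisons is reported as the sample standard deviation
(n−1); effect sizes are paired Cohen's d (sample std of differences) and
the matched-pairs rank-biserial correlation (zero differences dropped,
average ranks for ties).

## Evaluation conventions

Precision/recall/F1 define 0/0 as 0. Accuracy is ΣTP/N — the one-vs-rest
counts summed over classes would double-count the denominator (C·N), so
the standard form is used; weighted recall then equals accuracy as an
algebraic identity, which the property tests exploit. Micro-averaged ROC
pools all (sample, class) one-vs-rest decisions into a single curve; its
trapezoidal AUC equals the pairwise-comparison (Mann–Whitney) probability,
asserted on random small instances. Latency profiling uses warm-up runs
followed by timed runs (defaults 20/200) with nearest-rank percentiles.

## Known limitations

* Synthetic imagery only, with the gaps listed above; no claim transfers to
  real crop photographs without retraining and re-validation.
* Full participation, no stragglers, no communication constraints, no
  privacy mechanism (aggregate class counts are shared for the loss
  weights).
* The bundled backbone is deliberately small; published-scale backbones
  require an external implementation to be registered.
* Wall-clock latency numbers are hardware-dependent and are never treated
  as correctness targets; the protocol is the deliverable.
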