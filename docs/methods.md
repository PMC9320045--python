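# Methods

## Scope and model of the system

The package simulates the privacy surface of cross-silo federated
learning for binary chest-image classification.  Three mechanisms
interact:

1. **Federated averaging.**  In round t the server sends global
   parameters θ_t to the selected clients; client k runs one local epoch
   of minibatch SGD on binary cross-entropy and returns θ_t − η∇ (its
   updated parameters).  The server aggregates with weights proportional
   to the clients' training-set sizes.  The threat surface is the signed
   difference Δ_k = θ_t − θ_k,after, recorded for every (round, client).
2. **Gradient inversion.**  An honest-but-curious server treats Δ_k as a
   gradient proxy (exactly η·∇ℓ for a one-step update; the matching loss
   is scale-invariant so η never needs to be known) and optimizes a dummy
   batch so its gradient matches Δ_k in cosine similarity, with an
   anisotropic total-variation prior.  Optimization is Adam applied to
   the sign of the loss gradient, step size 0.1 decayed 10× at 3/8, 5/8
   and 7/8 of the iteration budget, three trials from standard-normal
   initializations, best trial chosen by final loss (never by PSNR, which
   uses ground truth and is evaluation-only).
3. **DP-SGD defense.**  Per-sample gradients are clipped to ℓ2 bound C,
   averaged, and noised with N(0, σ²C²)/B.  The accountant tracks Rényi
   divergences of the subsampled Gaussian mechanism on the order grid
   [1.1, 10.9] step 0.1 and [12, 63] step 1, composes additively over
   steps, and converts to (ε, δ) by minimizing RDP(α) + log(1/δ)/(α−1)
   over the grid.

## Synthetic data: what it emulates and what it does not

Real adult and pediatric X-ray collections are replaced by a generator
producing 32×32 (configurable ≥ 8; 224 mirrors the full-scale setting)
grayscale images:

* **Population structure** — adults get sinusoidal-plus-gradient
  backgrounds, pediatric images radial patterns; both are rescaled to
  [0.05, 0.78] so the background uses most of the dynamic range (making
  PSNR discriminative: a structureless guess scores ≈ 12–14 dB) while
  staying strictly darker than the encoded features.
* **Label** — a Gaussian "lesion" blob (blended toward intensity 0.95,
  σ = 0.10·res) in the lower image half when the finding label is 1.
  Prevalence is a knob (default 0.5, drawn independently per image; no
  per-client label distribution is enforced).
* **Demographics** — age is encoded as the radius of a soft disc at a
  fixed upper-central position (radius linear in age over 0–100 years);
  sex as the laterality of a bright corner square, mimicking a
  radiographic side marker.  The package's own decoder recovers sex
  exactly and age to a few years (observed worst case ≈ 9 years at
  32×32) on clean images, which makes attribute leakage measurable
  without training an auxiliary network.

The default federation reproduces the study partition: 5 large adult
clients (size configurable, default 200 — large enough that federated
averaging stays dominated by them, preserving the imbalance the analysis
is about) plus 31 small clients with sizes 2×{500, 200, 100, 30, 10, 2,
1} (pediatric) and 2×30, 5×10, 5×2, 5×1 (adult).  Splits follow the
cascade: n < 10 all to training; 10 ≤ n < 50 equal thirds with the
remainder to training (forced by the 10 → 4/3/3 row); n ≥ 50 as
⌊0.7n⌋/⌊0.15n⌋/rest.

What passing tests do **not** show about real data: the generator has no
radiographic texture, no anatomy, no label noise, and its demographic
encoding is deliberately legible.  Results here demonstrate the
*mechanisms* (attack works on informative updates, DP calibrated to a
budget destroys them) rather than clinical-scale effect sizes.

## Models

`toy_cnn` is three conv(3×3)/batch-norm/ReLU blocks (8, 16, 16 channels,
strides 1/2/2) and a single-logit linear head over the flattened final
feature map.  Two properties drove the design: a spatial (rather than
pooled) head keeps lesion location visible, making the synthetic task
learnable from random initialization within ~10 federated rounds at
learning rate 0.01; and with ≈ 4.7k trainable parameters against 1024
unknown pixels the gradient-matching problem is overdetermined, so a
20k-iteration attack on one 32×32 image finishes in minutes on one CPU.
Inputs are standardized with the grayscale constants μ = 0.449,
σ = 0.226 (channel means of the usual RGB normalization).

DenseNet121 and ResNet50 are enumerated layer by layer (shapes, names,
batch-norm buffers); the enumerations reproduce the published totals
(7 978 856 and 25 557 032 parameters for RGB/1000-class variants) and
support the one-channel first-layer adaptation (verbatim sum over the
input-channel axis — no rescaling, preserving responses to
channel-constant inputs) and all freezing modes, but have no forward
pass: training and attacking full-size networks is out of scope.

Freezing modes: `none` (everything trains; batch-norm running statistics
keep updating and are aggregated with the same weights as parameters —
a documented assumption), `batch_norm` (affine parameters frozen,
running statistics locked), `all_but_last` (only the head trains).
Private training requires locked batch-norm statistics: with batch
statistics active the loss is not a per-sample sum and per-sample
gradients are undefined.

## Numerical choices

* The autodiff engine builds backward passes from the same primitive
  set, so gradients are themselves differentiable (double backprop); this
  is what lets the attack differentiate the cosine loss through the
  model's gradient.  Convolution is im2col via gather/scatter with a
  zero mask for padding.  float64 throughout.
* Total variation is averaged (not summed) over neighbor differences so
  the prior's scale is resolution-independent and the default weight
  0.01 balances the unit-scale cosine term.
* Attack dummy pixels are unconstrained during optimization; images are
  min-max rescaled to [0, 1] only for PSNR and export.  Infinite PSNR
  (identical images) is serialized as 99 dB.
* Greedy PSNR matching takes the globally largest remaining cell each
  step; ties break on (row, column) order.  This is the reported
  procedure, not the PSNR-optimal assignment, and is not claimed to be.
* The accountant uses the standard sampled-Gaussian series: the binomial
  closed form at integer α, the two-sided erfc-weighted expansion around
  the crossover point at fractional α; q = 1 reduces to α/(2σ²) exactly.
  Noise calibration is binary search for the smallest σ meeting the
  target ε after all planned steps (tolerance 10⁻³).  Poisson sampling
  with q = batch/n is assumed in the analysis while local training uses
  plain shuffled minibatches — a standard approximation mismatch.
* σ is calibrated per client (each has its own q, δ and step count) for
  the full planned private rounds; clients stopping early under-spend.
* δ = min(0.9/n, 10⁻²) exactly, including the 10⁻² cap for one- and
  two-image clients (a known weakness of such budgets, kept
  deliberately).
* The clipping bound is the median unclipped per-sample gradient norm
  over the first three epochs of non-private training on an auxiliary
  dataset disjoint from every client (global mode), or per-layer medians
  (layer-wise mode).  A zero median is rejected with guidance rather
  than silently producing a degenerate mechanism.
* Scheduling: strict improvement (>, no minimum delta) defines plateaus;
  learning rate × 0.1 after 3 flat rounds, early stop after 5, best
  global model by mean validation AUC with earliest-round tie-break.
  Clients without validation data (or with a single-class validation
  split) are excluded from the selection criterion but still train and
  aggregate.  Client subsampling rounds half-up (0.3 × 36 → 11).
* Round aggregation is computed *from the recorded deltas* (global minus
  weighted deltas, buffers averaged separately), so replaying a round
  record through `federated_average` reproduces the stored global model
  bit for bit.
* The update difference is read as the signed before − after; an
  elementwise absolute value would destroy gradient direction.  The
  printed-denominator variant of the matching loss (‖∇θ′ − ∇θ‖ as
  normalizer) is available behind a flag for comparison; cosine
  normalization is the default reading.  Attack labels are supplied as
  an unordered multiset (analytic label recovery is assumed solved
  elsewhere); ordering ambiguity is resolved by the greedy matcher.

## Problem sizes used by the test and acceptance runs

Chosen so the whole suite runs comfortably on one CPU: federations of
six 60–100-image clients for utility checks (ten rounds reach mean
validation AUC ≳ 0.95 non-privately), the full 36-client roster for
layout/partition checks, 5000-iteration three-trial attacks for the
success-vs-collapse contrast, 1200-iteration single-trial attacks over
sixteen one-image clients for the leakage probes, and ten private rounds
for the ε sweep.  The `full` preset restores the complete study sizes.

## Known limitations

* Only the toy CNN trains; conclusions about DenseNet121 vs ResNet50 are
  limited to architecture-level parameter analyses.
* The RDP accountant covers the subsampled Gaussian mechanism only (no
  Gaussian-DP or zCDP variants).
* The attack implements the cosine/TV sign-Adam variant; no analytic
  label recovery, no batch-norm-statistics matching, no membership or
  property inference.
* Reconstruction PSNR on min-max-rescaled outputs is a coarse proxy for
  recognizability; no perceptual metrics are provided.
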