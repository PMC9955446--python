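# Methods

## The DropWeak scheme

DropWeak combines three masking mechanisms in every stochastic pass over
a weight tensor `W`:

1. **Node dropout** — each output unit (dense) or output channel (conv)
   is dropped with probability `node_drop_prob`, exactly as in classic
   DropOut.
2. **Per-weight dropping** — each weight is dropped independently with
   probability `rho` (`weight_drop_prob`), as in DropConnect. `rho` may
   be a scalar or a per-weight array; a magnitude-inverse schedule
   (`magnitude_inverse_rho`) is provided that assigns the weakest weight
   `rho_max` and the strongest 0 via rank percentiles of `-|w|`.
3. **Weak-weight zeroing** — weights of low magnitude are zeroed
   deterministically for the pass. Two rules: `absolute(tau)` zeroes
   `|w| < tau` (strict, so `tau = 0` is a no-op), and `quantile(q)`
   zeroes the `floor(q·n)` entries of smallest magnitude, ties broken by
   flat index ascending so the mask is a total-order-deterministic
   function of the weights. Default: `quantile(0.10)` — scale-free and
   robust to weight-norm drift during training, where an absolute
   threshold would need retuning.

All three act on a per-pass *view* of the master weights; the master
tensor is never modified, so dropped or zeroed entries automatically
"reactivate" on the next pass without bookkeeping. During training the
masks are treated as constants in the backward pass: gradients reach the
master weights through surviving entries only.

**Scaling.** With `scale_mode='inverted'` (default) surviving
Bernoulli-masked weights are rescaled by `1/(1-rho)` and kept nodes by
`1/(1-node_drop_prob)`, making the masked pass unbiased for the dense
pass. The weak mask is deliberately *not* compensated: it is a
deterministic zeroing, not a thinning, so compensation would change what
the mechanism means. `scale_mode='none'` is kept for the exact reduction
checks below.

**Stream contract.** Masks are decided by one uniform draw per entry
(`keep iff u >= p`), weight mask drawn before node mask, and an inactive
mechanism (scalar `rho = 0`, or `node_drop_prob = 0`) consumes no draws.
Consequences, verified in tests: with `rho = 0` and no weak rule the
scheme is stream-for-stream identical to plain DropOut; with
`node_drop_prob = 0` it is identical to plain DropConnect; with
everything off the pass is bit-identical to the dense computation.

## The classifier

A deliberately small two-stage residual network, written directly on
NumPy (im2col convolutions with hand-derived gradients, edge-replicate
padding — on standardized inputs a zero pad is a strong artificial
border feature that both hurts the fit and plants spurious attention
peaks along the image edge):

    stem conv 3x3 stride 2 → ReLU
    Block 1: residual block(s), DropWeak on both convolutions
    transition conv 3x3 stride 2 → ReLU
    Block 2: residual block(s), no weight masking
    elementwise DropOut → global average pool → dense head (DropWeak)
    SoftMax

Defaults: 64x64 grayscale input, channel widths (8, 16), one residual
block per stage, ~7k parameters. Block 1 carries the DropWeak masks and
Block 2 only plain DropOut — the asymmetric two-block topology the
method prescribes. The full-scale regime this family of models is
reported under (256x256 inputs, Adam 1e-5 with plateau factor 0.2, batch
16, 750 epochs, 80/10/10 split) is reachable through configuration; the
desk defaults are 64x64, Adam 1e-3, batch 16, ~20 epochs, which trains
in one to two minutes on one CPU core. The acceptance harness trains its
primary model for 24 epochs at 1.5e-3: faster schedules (3e-3, 16
epochs) reach the same accuracy but yield less spatially grounded
attention maps, while the gentler schedule gives both. Training standardizes with the training split's
mean/SD only, decays the learning rate by `lr_factor` (0.2) after
`lr_patience` (10) epochs without validation improvement, and restores
the best-validation checkpoint. All randomness (init, shuffling, masks,
splits, MC passes) flows from one root seed through named substreams, so
runs are bit-reproducible.

## Uncertainty estimators

T stochastic passes with independent masks are treated as draws from an
approximate weight posterior. Per sample, with per-pass distributions
`p_t` and mean `p̄`:

* predictive entropy `H[p̄]` (total), bounded by `ln C`;
* aleatoric term `mean_t H[p_t]` (expected per-pass entropy);
* epistemic term `MI = H[p̄] − mean_t H[p_t]`, the mutual information
  between prediction and mask configuration; zero iff all passes agree,
  non-negative by Jensen. Tiny negative values from floating point are
  clipped to 0 with the raw value retained.

Entropies are in nats (a bits toggle exists). The PH value
("probability of hit") is `max_c p̄_c`, used for sorting and abstention.

**Jackknife correction.** The plug-in entropy of a finite-T average is
biased (downward for one-hot-like passes). For a statistic `S` on all T
passes and `S_(-j)` on the T−1 passes excluding pass j, the corrected
value is `T·S − (T−1)·mean_j S_(-j)`. It is applied to both terms of the
MI; for the aleatoric term (a plain mean, hence linear) the correction
is exactly the identity, so the corrected MI differs from the raw MI
only through the predictive-entropy term. On 2,000 replicates of T=25
one-hot draws from Bernoulli(0.3) the corrected entropy's mean absolute
bias is roughly an order of magnitude below the plug-in's (both
recomputed by `scripts/acceptance.py`).

T defaults to 25, the middle of the reference sample counts {10, 25,
50}; run-to-run variance of the predictive mean shrinks monotonically
across those counts (checked in the acceptance suite).

## Grad-CAM

Grad-CAM with one deliberate twist: the score that is differentiated is
the pre-SoftMax **logit margin** of the target class, `z_c − mean_{c'≠c}
z_{c'}`, not the raw logit. SoftMax probabilities are invariant to
common-mode logit shifts, so features that raise every class score
equally carry no class evidence — yet they dominate raw-logit maps and
were observed to drag the peak off the nodule onto background texture.
Channel weights are the spatial mean of `∂ margin / ∂ A_k` for a conv
feature map `A`, the map is `ReLU(Σ_k w_k A_k)`, bilinearly upsampled to
input size and max-normalized (an all-nonpositive raw map returns
identically 0). The MC variant averages the *pre-normalization* maps of
T stochastic passes before normalizing, preserving relative magnitudes
across passes.

**Default target layer.** The default capture point is the stem's
feature map (32x32 at 64x64 input). The design was genuinely open (any
conv stage is selectable) and was settled by cross-seed verification of
the localization property: Block 2's 16x16 map localizes the nodule peak
poorly at this input scale, and per-layer rates vary considerably across
training seeds (Block 1 ranged 0.70–1.00 peak-inside-nodule over five
training seeds on correctly-classified malignant phantoms), while the
stem map — the highest-spatial-fidelity stage in a network this shallow
— was consistently ≥ 0.90. At the 256x256 full scale, with a deeper
backbone, a later layer would likely be preferable.

## Synthetic phantom generator

The generator defines the study conditions for every end-to-end check.
Each 64x64 image holds one nodule analog on a textured background:

* benign: smooth disc, diameter 3–9 px; malignant: disc deformed by
  low-order radial harmonics (orders 2–5, relative amplitude 0.25 — a
  spiculation analog), diameter 12–30 px. The stored ground-truth
  nodule mask is the nodule's *rendered support* — every pixel where it
  contributes at least 2% of its contrast, soft edge included — i.e.
  the nodule as it actually appears in the image, which is the right
  reference for attention-map checks (rim attention on the spiculated
  boundary is genuine nodule attention). The mapping is 1 mm ≙ 1 px, so
  the ranges sit inside the clinically reported 3–30 mm nodule span with
  benign small and malignant large; the ranges are disjoint because a
  desk-scale 7k-parameter network must be able to learn the task to
  ≥90% accuracy for the downstream uncertainty checks to be meaningful.
* background: correlated Gaussian texture (3 px correlation length, SD
  0.08), radial vignette (strength 0.25), additive pixel noise (SD
  0.04); nodule contrast +0.35 with a soft edge.
* aleatoric source: labels flipped independently at rate 0.05 (the
  clean label and the nodule mask are retained as ground truth), plus
  the pixel noise. At 5% flip rate, accuracy against observed labels
  saturates near 95%.
* epistemic source: `generate_ood` regenerates the *same* nodules and
  labels over shifted background statistics. The default shift doubles
  the texture SD only. A stronger combined shift (doubling plus
  vignette inversion) was found to push the trained network into
  confidently-wrong saturation on some MC streams, collapsing the
  epistemic MI instead of raising it — a real and known failure mode of
  MC-mask uncertainty under large shifts, but the default probe is meant
  to demonstrate the ordinary regime.

What the phantoms do **not** emulate: anatomy, Hounsfield calibration,
slice geometry, scanner artifacts, inter-reader label structure. Passing
tests therefore demonstrate the estimators' mathematical behaviour and
the pipeline's mechanics under controlled conditions, not clinical
performance.

## Evaluation

Malignant is the positive class. Sensitivity, precision, accuracy,
specificity and F1 are reported in percent; a zero-denominator ratio is
NaN, never 0. Report rows round half-up to 2 decimals (raw values kept
in JSON). ROC is a threshold sweep over unique scores with ties included
simultaneously; AUC is trapezoidal. Cross-validation uses stratified
folds with per-fold retraining; the aggregate row is the half-up
column-wise mean. On the worked nine-fold table used in the examples,
the sensitivity / accuracy / specificity columns average to 91.32 /
90.44 / 89.59; the precision and F1 columns compute to 87.39 / 87.88–89
(87.39 and 87.89 under half-up rounding).

Abstention analysis retains samples with entropy ≤ u (entropy mode,
default) or PH ≥ u (ph mode), default thresholds {0.3, 0.5}, reporting
the retained fraction and the accuracy among retained (NaN if empty).

## Problem sizes and numerical choices

* Desk-scale study: n = 2,000 phantoms, 80/10/10 split, 16 training
  epochs (3-fold cross-validation uses 12 per fold, k=3 in the
  harness; the library default is k=9), T = 25 MC passes.
* Network arithmetic in float32; uncertainty estimators in float64.
  Simplex membership is validated at 1e-6; the decomposition identity
  holds to 1e-12 against a brute-force reimplementation.
* Degenerate inputs: `rho = 1` drops everything and skips the
  uncompensatable rescale; quantile ties break by flat index; an
  all-zero Grad-CAM map stays all-zero after normalization; empty
  abstention sets report NaN accuracy.
* Divergent training (non-finite loss or weights) raises an error
  carrying the last finite checkpoint.

## Known limitations

* The approximate posterior is mask-sampling only; no variational or
  MCMC weight inference, so epistemic MI is a lower-bound-flavoured
  diagnostic, not a calibrated posterior quantity.
* Under strong covariate shift the epistemic signal can collapse
  (confidently-wrong saturation); see the OOD note above.
* The NumPy network is CPU-bound and desk-scale; it is not a framework
  for large models, and the optional Naive-Bayes fusion head is one
  defensible reading of an underspecified design, off by default.
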