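# Methods

This note documents the models, parameters and design choices behind
`ipgseg`: what each stage computes, what the synthetic scenes do and do not
emulate, and where the genuinely open decisions were made.

## Pipeline model

The framework addresses pixel-wise classification of a hyperspectral cube
`M ∈ R^{H×W×C}` when only a few pixels per category are labeled. Its core
assumption is that a category-agnostic promptable segmenter carries strong
*structural* prior knowledge — it can turn a handful of point prompts into a
spatially coherent mask — while the *spectral* evidence lives in the cube's
many bands. The stages combine the two:

**Band groups.** Every three adjacent bands `(j, j+1, j+2)` form one
three-channel image, giving `C − 2` groups; adjacent groups share two bands.
Each group is rescaled per channel to the segmenter's display range
`[0, 255]` by min–max scaling (a percentile stretch is available as a config
option; a constant channel maps to zero). The raw cube is never modified —
rescaling happens on the way into the segmenter only.

**One-vs-rest prompting.** For category `i`, its labeled pixels are
foreground prompts and all other categories' labeled pixels are background
prompts. Background prompts stay frozen at the seed configuration for the
whole run; only foreground prompts grow as pseudo labels accumulate. The
alternative — also feeding background-thresholded pixels (`y = −1`) back as
background prompts — is not implemented: growing backgrounds couples the
categories' prompt sets and nothing in the gating machinery requires it.

**Spectral voting.** Each pixel receives `C − 2` binary predictions per
category. `T(a, i)` counts the positive ones; the fused label is
`argmax_i T(a, i)`. Ties break toward the smallest category index
(deterministic), and a pixel whose best tally falls below `min_votes`
(default 1, i.e. any vote assigns) stays unassigned rather than being forced
into a category no group voted for. The per-pixel top-1 minus top-2 margin
is recorded alongside the label.

**Confidence, uncertainty, gate.** With `f_a` the embedding of pixel `a` and
`F_i` the embeddings of category `i`'s current foreground prompts — both
passed through the trainable projection — the confidence `p_a^(i)` is the
mean cosine similarity to the `n` prompt features and the uncertainty
`u(p_a^(i))` is the population variance of those `n` similarities (so a
single prompt gives `u = 0`). A candidate (a voted pixel not already
prompted) is admitted only when `p ≥ τ_h` **and** `u ≤ κ_h`; independently,
`p ≥ τ_h` / `p ≤ τ_l` classify pixels as foreground/background with an
abstention band in between. Defaults: `τ_h = 0.8`, `τ_l = 0.5`,
`κ_h = 0.2`. Admission is implemented as hard-label selection — the pixel
enters training with weight 1 — rather than overwriting its stored
confidence with 1, which would corrupt both the consistency loss and the
audit trail; every ledger entry records the `p` and `u` it was admitted
with, so the gate can be re-checked after the fact.

**Consistency loss and projection training.** The loss for category `i`
over its gated pixels is the negated one-vs-rest log-likelihood
`L_i = −Σ_a g_a [log p_a^(i) + Σ_{j≠i} log(1 − p_a^(j))]`. Cosine means can
be negative while the logarithms need `(0, 1)`, so confidences are clipped
to `[ε, 1−ε]` with `ε = 10⁻⁷` before the logs; the clip saturates the
gradient (zero outside the open interval) rather than producing
infinities. The only trainable parameter is a `D × D` linear projection
applied to every embedding before similarity scoring — the rest of the
backend is frozen. Its gradient is computed analytically (chain rule through
the normalized dot products) and verified against central finite differences
in the test suite; one plain gradient step per iteration is taken with
learning rate 0.01 (the classifier's SGD settings do not transfer to this
much smaller, better-conditioned problem; 0.01 keeps the projected feature
geometry stable between iterations). A non-finite gradient skips the step
with a warning.

**Iteration schedule.** Per iteration: segment all groups per category →
vote → score candidates → gate → admit the top `selections_per_class`
(default 1) gated candidates per category by confidence, ties broken in
row-major pixel order → one projection step. Because voting assigns each
pixel at most one category, per-category candidate sets are disjoint by
construction; a defensive higher-confidence-wins rule guards the
one-category-per-pixel ledger invariant anyway. The loop runs a fixed 50
iterations (no early stopping), selection happens before the projection
step within an iteration, and the feature field is recomputed each
iteration with the current projection (features drift as the projection
trains). Candidate features are read from the middle band group's embedding
field — one canonical field keeps confidence comparable across iterations.

**Classifier.** Every training pixel (seed or pseudo label; on conflict the
seed's ground-truth label wins and the conflict is logged) contributes one
`9 × 9 × C` window centered on it, reflect-padded at scene borders to avoid
zero-padding artifacts. Patches are standardized per band with statistics
from the training patches. The network is deliberately small — two 3×3
convolution blocks (widths 32/64, ReLU, 2×2 max pooling), global average
pooling, a linear softmax head — trained with SGD (learning rate 0.05,
momentum 0.7, weight decay 1e-4; biases exempt from decay), 100 epochs,
batch 64, all config-overridable. It is implemented directly on numpy with
explicit backpropagation (im2col convolutions); the analytic gradients are
finite-difference-checked in the tests, and a fixed seed reproduces the
parameter trajectory exactly. Evaluation uses OA, AA and Cohen's kappa
`(OA − P_e)/(1 − P_e)` with `P_e = Σ_i Total_i (TP_i + FP_i) / (Σ_i
Total_i)²`; metrics live in `[0, 1]` internally and print as percentages.
`kappa` is reported as undefined (not 0) in the degenerate `P_e = 1` case.

## Segmenter backends

The loop sees a backend only through `segment(image, prompts)` and
`embed(image)`.

**Oracle backend.** Masks come from the known class regions of a synthetic
scene: the prompted category is read off the ground truth under the
foreground prompts (majority, ties to the smallest category), and the true
region is corrupted by (a) independent per-pixel flips at rate `ρ` inside an
eligibility band of half-width `b` pixels around the region boundary —
boundary indecision, the dominant failure mode of prompt-driven
segmentation — and (b) optional whole-mask dilation (over-segmentation).
Flips are a deterministic function of (backend seed, image bytes,
category), so each band group fails independently while repeated calls are
bit-identical and prompt-order-invariant. Embeddings are the per-class
spectral signatures plus i.i.d. Gaussian noise (`feature_noise_sd`), again
deterministic per image. Two simplifications relative to a real foundation
segmenter: masks do not sharpen as prompts accumulate (iteration dynamics
live entirely in the confidence/gating/prompt growth), and embeddings are
class-pure up to isotropic noise rather than spatially textured. Passing
tests therefore demonstrate the correctness and interplay of the voting,
gating and training machinery — not the behavior of any particular
pretrained segmenter on real radiance data.

**Foundation backend** (`ipgseg.sam_adapter`, optional extra): wraps a
Segment Anything checkpoint behind the same contract, binarizing mask
logits at 0 (score 0.5) and bilinearly resampling encoder activations to
the pixel grid for `embed`. It needs external weights and prefers a GPU;
the core test suite never imports it.

## Synthetic scenes

`generate_scene` emulates what makes benchmark land-cover scenes amenable
to this method: a few spatially contiguous class regions and smooth
per-class spectral curves. Regions are either Voronoi cells of random sites
(default; convex-ish, guaranteed minimum size via rejection) or round-robin
randomized flood fills ("grown-blobs": irregular outlines, 4-connected,
near-balanced). Signatures are a 0.05 baseline plus 3 Gaussian bumps over
the band index (amplitudes 0.5–1, widths ≈1–`C`/10 bands), drawn by
rejection with global restarts until all pairwise angles reach `θ_min`
(default 45°); smoothness makes adjacent band groups look alike, which is
the redundancy spectral voting exploits. Pixel spectra are the class
signature plus i.i.d. `N(0, noise_sd²)` (default 0.05). Not emulated:
radiative-transfer effects, spatially correlated noise, mixed pixels,
class-dependent texture.

The default desk-scale spec is 64 × 64 pixels, 24 bands (22 groups), 4
classes — every stage runs in seconds at this size.

**Corruption calibration.** The "moderate" oracle level used by the noisy
studies is `ρ = 0.3`, boundary band 3, `feature_noise_sd = 0.08`, chosen so
that a single band group misassigns roughly 10–20% of pixels on the default
scene — enough noise that voting and gating have real work to do, little
enough that the task stays solvable.

**Few-label regime.** The classifier-benefit study uses a harder scene:
eight grown-blob classes with `θ_min = 15°` and `noise_sd = 0.5`. The
default four-Voronoi-class scene is too easy to measure augmentation — a
9 × 9 patch averages away i.i.d. noise, so even 5 labels/class trains a
near-ceiling classifier. With fragmented regions and spectrally similar
classes, five labels per class leave the baseline at roughly 85–91% OA,
which is the regime (limited labels, confusable spectra) the framework is
designed for; the measured quantities are the paired OA with and without
pseudo labels on identical held-out pixels.

## Numerical and reproducibility choices

- Mask scores binarize at 0.5; the mask/score consistency is a type
  invariant.
- Cosine similarities are clipped to `[−1, 1]` against rounding; zero-norm
  feature vectors are rejected rather than patched.
- Seed-label sampling visits categories in ascending order with one
  generator and sorts candidate pixels row-major first, so draws are
  independent of array-traversal details.
- One global seed fans out to per-stage seeds by stable hashing of the
  stage name (`derive_seed`), keeping every stage below 2³¹ and
  individually reproducible.
- The whole oracle pipeline is pure numpy: two runs with one seed produce
  byte-identical ledgers, rasters and logs (asserted in the tests).
- Degenerate inputs: constant channels normalize to zero; an all-zero vote
  tally stays unassigned; a category with no gated candidates simply adds
  nothing that iteration; `K = 1` is rejected (one-vs-rest needs an
  opposing class).

## Known limitations

- The oracle's static masks cannot exhibit the prompt-driven mask
  refinement of the real system; conclusions about that feedback effect
  require the foundation backend and real scenes.
- The confidence gate inherits the segmenter's feature geometry: when class
  embeddings are nearly collinear (angles well below ~35°, cosine above
  `τ_h`), the gate stops discriminating between classes and pseudo-label
  precision rests on voting alone.
- The spatial-consistency objective trains only the `D × D` projection;
  with the oracle's class-pure embeddings this is sufficient, but it is a
  deliberately minimal stand-in for fine-tuning a real prompt encoder.
- Patch extraction reflects at borders; for scenes much smaller than the
  patch size the reflected context dominates.
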