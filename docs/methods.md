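# Methods

## Overview

`l2l` chains two generative models over single-leaf images acquired on a
dark background with in-image reflectance probes. A residual
variational autoencoder (VAE) learns the distribution of binary
companion skeletons — the blade's outer contour plus its vein tree —
and a Pix2pix-style conditional GAN translates a skeleton into a
colorized RGB or R/G/NIR leaf. Generation draws a latent vector,
decodes a skeleton, optionally refines it, and colorizes it. Quality is
quantified by an anomaly-detection autoencoder trained as the identity
operator on real images only.

## Preprocessing chain

1. **Hot-pixel removal.** A pixel is replaced by the mean of its 8
   neighbours when its value exceeds *every* neighbour by more than 10%
   of the channel midrange (min+max)/2. One pass; all decisions are
   made against the input image, never partially updated values. Border
   pixels lack a full neighbourhood and are left unchanged (the
   protocol does not specify border handling; skipping is the least
   invasive choice). The midrange is computed per channel over the
   whole image.
2. **Probe normalization.** With m the minimum inside the 2%
   reflectance probe and M the maximum inside the 99% probe, every
   pixel maps as p ← (p − m)/(M − m), clipped to [0, 1]. Probes at m
   and M map exactly to 0 and 1.
3. **Companion skeleton.** Derived from the NIR channel, where leaf
   tissue is bright and background dark. Otsu's threshold (histogram
   with 256 bins; exact per-class statistics accumulated from true
   pixel values, so maximizing between-class variance is exactly
   minimizing intraclass variance; ties resolve to the lowest
   threshold) binarizes the channel; the largest 8-connected component
   with holes filled is the blade. Its outer boundary is traced with
   the Moore-Neighbor algorithm (clockwise 8-neighbourhood walk; the
   walk is followed until its first repeated (pixel, backtrack) state,
   which reduces to Jacob's stopping criterion whenever that state is
   the initial one — the generalization also terminates on
   configurations where the initial state never recurs). Boundary
   tracing yields contours only, and no explicit vein operator is part
   of the protocol, so vein detection inside the blade is this
   package's documented substitute: pixels darker than a masked boxcar
   local mean (window side/8, offset 0.05) within the twice-eroded
   blade, morphologically thinned to ≤2 px strokes. On procedural
   fixtures with known vein trees the extracted skeleton stays within
   2 px Hausdorff distance of the ground truth.
4. **Crop and resize.** One subpixel affine warp centres the blade
   centroid in a square window (10% margin around the blade bounding
   box) and resamples to the target side — bilinear for intensity
   channels, nearest for the skeleton, which is re-binarized at 0.5.

**Augmentation** triples a dataset (80 → 240): each sample contributes
itself plus two variants with independent horizontal/vertical flips, a
rotation uniform in [−π/4, π/4] and a zoom uniform in ±20%; image and
skeleton share the exact geometric transform (bilinear vs nearest) and
the expansion factor is fixed at 3 to match the printed dataset sizes.

## Skeleton VAE

Loss: L = ‖x − x̂‖₂² + β·KL[N(μ_x, σ_x) ‖ N(0,1)], with the
reconstruction summed (not averaged) over pixels and the KL in closed
form Σ½(μ² + σ² − 1 − ln σ²). The σ head emits log-variance;
σ = exp(½ logvar) keeps positivity without constraints.

Architecture (exact layer tables are an open design choice; everything
is configurable): a 4-stage stride-2 convolution encoder doubling
channels from a base width of 8; dense heads for μ and logvar (latent
dimension 32); a mirrored nearest-upsample + convolution decoder; two
residual blocks appended to the decoder; additive skip connections from
encoder stages 1–3 into the matching decoder stages.

Skips and generation: a decoder trained only with skips cannot decode a
raw latent (no encoder features exist). Each training batch therefore
zeroes the skip inputs with probability 0.5 (`skip_dropout`), so the
decoder learns both the skip-assisted reconstruction path and the
pure-latent generation path. At generation time skip inputs are zero
grids.

Defaults: β = 1.0 (no published value exists for this weighting; 1.0 is
the neutral choice), Adam with lr 2·10⁻⁴, batch 8, binarization
threshold 0.5 for turning the continuous decode into a skeleton. The
latent prior for sampling is N(0, I); an empirical mode (diagonal
Gaussian fitted to the training posterior means) is available behind a
flag, since at desk scale the aggregate posterior can sit far from the
standard normal.

## Pix2pix translator

Objective: min_G max_D L_cGAN(D,G) + λ·L_L1(G), with
L_L1 = ‖target − G(z|y)‖₁ (reported per pixel). The generator
optimizes the non-saturating form −E[log D(G(z|y))] instead of the
literal log(1 − D): identical fixed points, live gradients early in
training. D's loss is −E[log D(real)] − E[log(1 − D(fake))], patch
probabilities clamped at ε = 10⁻⁷.

Generator: U-net — 4-stage stride-2 encoder on the 1-channel skeleton,
nearest-upsample decoder with *concatenated* skips, dropout (p = 0.5)
after the first two decoder stages. Dropout is the realization of the
noise source z (standard Pix2pix practice) and can stay active at
inference for stochastic translation. Discriminator: three stride-2
convolutions on the concatenated (skeleton, candidate) channels plus a
stride-1 head → a (side/8)² grid of per-patch probabilities.

Defaults: λ = 100 (the conventional Pix2pix weighting; no published
value to follow), Adam lr 2·10⁻⁴ for both nets, alternating one D and
one G update per batch. RGNIR mode swaps the target bands to R/G/NIR
and changes nothing else; the skeleton model need not be retrained.

## Generation and refinement

Generation: z ~ N(0, I) (length 32) → decode → binarize at 0.5 →
optional refinement → translate. Degenerate latents may decode to an
empty skeleton; batches carry such samples through (counted, not
crashed).

Refinement deletes off-blade artifacts: the leaf is the largest
8-connected foreground component; its outer contour is filled
(`binary_fill_holes`), and every other component that does not
intersect the filled region is removed. Components inside enclosed
holes intersect the filled region and survive; kept pixels are
bit-identical to the input, so refinement never adds pixels and is
idempotent. Internal background holes are deliberately preserved —
overlapping lobes, herbivory and disease produce real holes. The same
operator can be applied to a translated image's foreground mask.

## Quality evaluation

The anomaly AE reuses the VAE encoder/decoder layout with a plain dense
bottleneck (latent 64), *no* variational head and *no* skip connections
— skips would make identity reconstruction trivial and the score
uninformative. Score: s_x = mean squared pixel error between the image
and its reconstruction (mean absolute error behind a flag; the score
definition is this package's choice, as only the concept is fixed).
ROC: fake = positive class; a score ≥ threshold is positive; thresholds
sweep the union of observed scores plus a +∞ sentinel, so the curve
runs from (0,0) to (1,1); AUC by the trapezoidal rule, which equals the
pairwise Mann-Whitney statistic P(fake > real) + ½P(tie).

At full scale this evaluation, applied to generated grapevine leaves,
is reported to reach AUC = 0.25 (synthetics mistaken for real 75% of
the time); that number requires the real dataset and full-scale trained
models. The desk-scale harness asserts the structural properties
instead: corrupted fixtures must score above their clean counterparts
and clean-vs-corrupted AUC must exceed 0.5.

## Synthetic fixtures

The fixture generator emulates the statistical structure the pipeline
assumes, not botany: a star-convex lobed blade (polar radius
R(1 + 0.15 cos(nθ + φ) + two small random harmonics)), a recursive
midrib-plus-branches vein tree (1–2 px strokes clipped to the eroded
blade), a smooth multiplicative colour field over the blade (base green
hue), a brighter and flatter NIR channel with veins darkened to 55%,
three constant corner probes at reflectances 0.02/0.50/0.99, and a dark
background (level 0.03) strictly below every blade intensity. Hot
pixels can be injected as an exact inverse of the removal rule. All
randomness flows through one seeded generator per sample; a dataset's
per-sample seeds are master_seed + index.

What fixtures do **not** model: real venation topology, specular
highlights, shadows, out-of-focus blur, sensor noise beyond hot pixels,
petioles, or damaged/overlapping leaves. Tests passing on fixtures
therefore demonstrate algorithmic correctness and trainability, not
image realism on real crops.

## Problem sizes and numerical choices

The packaged study runs at side 64 with 64 training leaves, 30 epochs
per model and a base channel width of 8 — sizes chosen so the complete
suite and the acceptance script run on a single CPU in minutes while
still showing monotone learning; every size scales up through the
configs (256×256 is the default architecture contract). Networks
compute in float32; training is bit-reproducible for a fixed seed and
software stack, since all randomness (init, shuffling, reparameterization
noise, dropout) flows from one seeded generator. Histories record
per-epoch means; `fit(epochs=0)` returns the untrained initialization
with an empty history. Checkpoints are single-file `.npz` archives with
the config and history embedded as JSON.

## Known limitations

- At desk scale the prior-sampled skeletons are sparse (few foreground
  pixels): with β = 1 against a pixel-summed reconstruction loss the
  KL pressure is weak, the aggregate posterior drifts from N(0, I),
  and random latents decode close to the background class. The
  empirical sampling mode and larger β/width/epochs mitigate this;
  the contracts (binary output, valid range, reproducibility) hold
  regardless.
- The GAN uses no normalization layers; at much larger widths or sides
  instance/batch normalization would likely be needed for stability.
- Vein extraction is a documented substitute (see above), tuned for
  dark-vein NIR imagery; light-vein species would need the offset sign
  flipped.
- Moore tracing returns the outer contour of the largest component
  only; multi-leaf scenes are out of scope.
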