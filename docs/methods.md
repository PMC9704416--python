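# Methods

This note records the modelling assumptions, parameter choices and known
limitations behind `ischemap`. It is written for a reader who wants to know
*why* the pipeline is built the way it is, not just what it computes.

## Speckle contrast model

Speckle contrast is K = σ/⟨I⟩ over a local window, with the population
(ddof = 0) standard deviation: the estimator over a fixed window is the
convention in speckle imaging and keeps the statistic deterministic.
Borders are handled by mirror padding so edges do not acquire spurious
contrast. Wherever the window mean falls below `eps` (default 1e-8) K is
defined as 0 — a dark background must not masquerade as flow. The flow
index is 1/max(K², eps): the proportionality constant linking 1/K² to
absolute velocity depends on exposure time, polarization and optics and is
not recoverable from the data, so the index is relative and unitless
throughout. The pipeline default is a 5×5 spatial window; temporal and
spatio-temporal contrast are provided for completeness.

## Synthetic phantom

The generator emulates the features of dual-modality bowel imaging that
the pipeline actually relies on, at configurable scale:

* **Anatomy.** An elliptical tissue blob on a towel-colored background; a
  primary vessel tree drawn by seeded biased random walks with branching,
  each tree aimed across the organ (not at the centroid, so vasculature
  spreads rather than forming a hub); a fine capillary network of short
  thin walks. The same tree drives both modalities, but with different
  footprints: the flow map uses a tight rendering (the lumen), the RGB
  darkening a broader one (wall plus shadow) — vessels look wider than the
  flow they carry, as they do in real serosa.
* **Flow.** Parenchyma baseline 1.0 (arbitrary units), +2.5 along main
  vessels, +0.5 along capillaries, 0 off-tissue. The vessel/parenchyma
  ratio of the LSCI flow index is then ≈3, in the physiological ballpark
  rather than the order-of-magnitude separation a naive parameterization
  gives; this also matters for lesion realism (below).
* **Ischemia.** A disk-shaped core multiplies flow by (1 − severity); a
  smoothstep ramp of configurable width blends the attenuation to zero, so
  flow is monotone nondecreasing along any ray out of the core. The RGB
  channel is deliberately unaffected: early ischemia is assumed invisible
  to color inspection, which is precisely the premise the anomaly detector
  tests. Because attenuation is multiplicative, vessels crossing the core
  retain a few-fold more flow than core parenchyma — the lesion is a
  low-flow *region*, not a uniform intensity level.
* **Speckle.** Per pixel, intensities are gamma variates with shape
  k = 1 + c·flow (c = 5), so the expected contrast is K = 1/√(1 + c·flow)
  and zero flow yields fully developed speckle (K = 1). This reproduces
  the σ/μ statistic without simulating coherent optics — the phantom
  validates the *statistics* pipeline, not diffraction. Frames are
  globally modulated by a three-sinusoid factor bounded by ±10%, emulating
  respiration/pulsation/peristalsis-induced intensity fluctuation.
* **Misalignment.** A random thin-plate-spline warp (4×4 control grid,
  offsets ≤ `warp_magnitude`) displaces the LSCI channel. The speckle is
  re-synthesized from the warped flow map rather than resampled, so its
  contrast statistics stay exact. The stored truth is the *alignment*
  field (the exact inverse displacement, computed by fixed-point
  iteration), i.e. the field a perfect registration network should output.
  Landmarks (7–9 per scene: tissue-outline, vessel-interior, background)
  are transported through the same inverse map.

What the phantom does **not** model: coherent diffraction and speckle
grain size, depth-dependent scattering, specular highlights, organ-scale
deformation between frames, camera noise floors and color response.
Passing the phantom suite therefore demonstrates that the algorithms are
implemented correctly and behave as designed under controlled conditions;
it does not certify in-vivo performance.

## Preprocessing

Images entering any network are affinely mapped onto [−1, 1] (the stored
original range makes the map invertible to 1e-12). Histogram equalization
is global and acts on luminance only (YCbCr), because hue carries the
serosa-color cues the method must not distort; adaptive equalization
(CLAHE) is deliberately not used, matching the simple global scheme the
pipeline assumes. Downsampling is block averaging (anti-aliased), not
striding. Tissue/background separation is Otsu's threshold on each pixel's
RGB distance to the border-estimated background color, keeping the largest
connected component.

## Networks

The autodiff engine (`ischemap.nn`) is a ~700-line reverse-mode
implementation over NumPy: strided/transposed convolutions via im2col and
its adjoint, batch normalization, bilinear warping differentiable in both
image and field, float32 by default (float64 for gradient checking).
Every primitive is verified against central-difference gradients.

Reference architectures (256×256):

* **Generators G1/G2**: 8-level U-Net, kernel 4, stride 2, channels
  64→128→256→512 then 512 at the deeper levels (the printed shorthand
  3→64→128→256→512→1024→512→256→128→3 lists the concatenated bottleneck
  width); leaky-ReLU encoder, ReLU decoder, Tanh head, skip connections,
  batch norm on interior blocks, 50% dropout in G1's three innermost
  decoder blocks.
* **Discriminators D1/D2**: 70×70-receptive-field PatchGAN on 6-channel
  conditioned input, channels 64→128→256→512→1, returning a patch score
  grid.
* **Registration R1**: kernel-3 encoder 6→32→64→128, a 6-block residual
  trunk at 128 (the standard residual-generator depth), a
  resize-convolution decoder (nearest-upsample + conv, avoiding
  checkerboard artifacts) with one refinement residual block per level,
  and a 2-channel head. The head's full-resolution output is
  average-pooled onto a coarse control grid (default 8×8), bounded by
  Tanh × `max_disp` (default 16 px), and densified by exact thin-plate
  spline interpolation; since control and evaluation points are fixed the
  densification is a precomputed linear map, differentiable for free.

Parameter accounting: with biases everywhere and *affine* batch norm, the
discriminator counts 2,769,601 parameters; without the affine terms,
2,767,809 — the two published D budgets. The same convention separates the
two generator budgets (54,419,459 affine vs 54,409,603 non-affine), so the
anomaly family (G1/D1) is built with affine batch norm and the
registration family (G2/D2/R1) without. At batch size 1, training-mode
batch normalization behaves like instance normalization; inference uses
frozen running statistics.

Desk-scale training (the test and phantom conditions) uses the same
builders with reduced channel lists (generator [8, 16] or [16, 32, 64, 64,
64], discriminator [8, 16], registration [8, 16, 32] with a 2-block trunk,
4×4 control grid, `max_disp` 12) at 64×64. A deliberately *lean*
translator matters for more than speed: with only a couple of dozen
training pairs, a high-capacity translator memorizes each scene's
misalignment and bypasses the registration branch entirely — the same
degeneracy the anti-identity loss targets, but at small data scale the
λ_A = −2 weighting cannot counter λ_R = 150 on its own, and restricting
the translator's capacity and receptive field is the effective control.

## Registration objective

L_total = L_cGAN + λ_R·L_recon + λ_S·L_smooth + λ_A·L_anti with the
published weights λ_R = 150, λ_S = 130, λ_A = −2.0 and Adam (lr 0.001,
β₁ = 0.9, batch 1) for all three networks.

* L_recon compares both composition orders — translate-after-warp
  G2(warp(LSCI)) and warp-after-translate warp(G2(LSCI)) — against the
  RGB image in L1. The warp-after-translate term routes its gradient to
  the registration branch only (the translator's output is detached
  there): this enforces the orthogonality of the two branches and costs
  the translator nothing, since it still learns from the other order.
* L_smooth is the bilateral-weighted sum of 3×3-neighbour field
  differences, averaged over pixels. Displacements are measured in
  normalized grid coordinates (pixels × 2/H): the published weight was
  tuned for a spatial-transformer field on the [−1, 1] grid, and measuring
  in raw pixels would make λ_S resolution-dependent (≈30× too strong at
  64×64, freezing the field entirely). Bilateral weights come from the
  grayscale RGB — the fixed modality — with σ_s = 2 px and σ_r = 0.1 on
  [−1, 1] intensities (neither is published; both are config-exposed).
* L_anti measures how close each branch alone comes to the identity and
  enters negatively, penalizing the collapse where the translator absorbs
  the warp and the field stays zero.
* The adversarial term uses the log form with the patch grid averaged and
  the non-saturating generator update; the two fake terms are weighted
  equally (unspecified; equal assumed).

Training supports a translator warm-up (`warmup_epochs`: the registration
branch is frozen while the translator bootstraps, so early field updates
are not driven by a random translator) and early stopping on mean landmark
error when landmarks exist (else on the reconstruction-loss plateau),
restoring the best-validation weights; `min_epochs` prevents stopping
before the translator is useful. Registration runs in one direction only
(LSCI warped onto RGB): the reverse direction is structurally weaker
because speckle images lack the morphological detail needed to predict an
RGB-frame deformation.

Landmark transport: the field follows the warp convention (ϕ sampled at
target coordinates, added to them when sampling the source), so image
content at LSCI position p lands at the registered position solving
x + ϕ(x) = p; landmark error inverts the field by fixed-point iteration
rather than adding ϕ(p), which would be the inverse field to first order
only.

## Anomaly detection

The healthy model is a pix2pix-style conditional GAN: G1 maps RGB to the
expected healthy LSCI, D1 judges (RGB, LSCI) pairs, objective
L_cGAN + λ·L1 with λ = 100, Adam lr 2·10⁻⁴, β₁ = 0.9, batch 1, up to 40
epochs (convergence at phantom scale is well inside that). Dropout (50%)
is active only in training; inference is deterministic.

The residual r = |y − ŷ| is converted to a probability-like score by
dividing by the *fixed* dynamic range (2 for [−1, 1] images), not a
per-image maximum: the reconstruction acts as a per-sample baseline
precisely so that scores are comparable across samples, and per-image
normalization would destroy that. Post-processing masks to tissue,
applies grayscale morphological closing (disk radius 3 at 256×256, 2 at
64×64 — fills the pepper holes speckle grain leaves inside lesions),
re-masks, and thresholds at 10% for the binary map. Masking precedes
closing so background zeros cannot bleed into tissue; the output
background is exactly zero.

## Evaluation

Confusion counts are taken inside an evaluation window (default 80×100,
clipped/configured to fit smaller images) with buffer-labelled pixels
excluded entirely — inside the gradual transition zone both labels are
defensible, so neither is scored. Metrics follow the standard
confusion-matrix formulas; division-by-zero cases return 0.0 with a
warning rather than raising. AUC is a trapezoidal sweep over the unique
score values (verified against rank-statistic and scikit-learn oracles).

Transition-zone ground truth: the ROI is median-filtered (3×3, to keep
thin bright vessel traces from masquerading as a dominant level), split by
Otsu's threshold into the dominant low/high populations, and the two
contour levels are interpolated between the class medians
(¾m₁+¼m₂ and ¼m₁+¾m₂). A 3-class multi-level Otsu was tried first and
rejected: on near-bimodal ROIs with a heavy vascular tail its split is
unstable (identical distributions flip between bracketing the transition
and splitting a single mode). The three annotation repeats are emulated by
bootstrap-resampling the ROI pixels and averaging the levels. The
perfusion-oriented input is expected bright-is-perfused; the log flow
index −2·log K is the recommended display, since it symmetrizes the
lesion/parenchyma/vessel populations.

## Problem sizes

Phantom work runs at 64×64 with 32–128 speckle frames per scene: 20 pairs
for registration studies (≤8 px warps, 4×4-control-grid truth), 30 healthy
scenes for detector training (40 epochs), reduced channel lists as above.
These sizes keep full training runs in the minutes range on one CPU while
preserving every structural property the full-scale system relies on.

## Known limitations

* The phantom's translation task (LSCI→RGB) is far easier than real
  cross-modality appearance transfer; registration results on phantoms
  bound the optimization behaviour, not clinical accuracy.
* Unsupervised registration at desk scale recovers large smooth warps
  partially (the landmark-error floor is set by the photometric noise and
  the lean translator's fidelity); it is not a general-purpose registrar.
* Absolute perfusion is out of reach by design: all flow quantities are
  relative indices, and no claim is made about necrosis prediction.
* Batch-size-1 batch normalization makes inference statistics sensitive to
  the running-average horizon; bundles freeze them at save time.
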