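# Methods

## Model

A single-channel image `I` with effective bit depth `n` is mapped to a
*descriptor image* `D`: for every pixel `x`, the `l × l` neighbourhood
`N_{x,l}` (odd `l`, mirror-reflected at the image border) is summarized by the
uncertainty of its intensity distribution,

    D[x] = M_k( p(N_{x,l}) ),      M_k(p) = Σ_i f_k(p_i),

where `p` is the (optionally weighted, optionally Parzen-smoothed) histogram
of the patch over `bins` intensity bins and `f_k` is one of four strictly
concave core functions (Shannon `−x log x`; logarithmic fuzzy
`−[x log x + (1−x) log(1−x)]`; exponential fuzzy `x e^(1−x) + (1−x) e^x − 1`;
rational `x/(1+x) − x/2`). All logarithms are natural: the gap
`Δ(r) = (r−1) log(r/(r−1))` between the fuzzy and Shannon bounds converges to
1 only in nats, and the plateau values of the bounded kinds (≈2.706, ≈0.496
at `r = 256`) are then reproduced directly. The conventions `0·log 0 := 0`
and `(1−x) log(1−x) := 0` at `x = 1` are applied element-wise.

Strict concavity gives the two extremal facts the descriptors rely on: a
point-mass histogram scores 0 and the uniform histogram attains the
closed-form bound `B_k(r)`, where `r = min(l², 2^n, bins)` is the variety
degree — the number of distinguishable levels a patch can exhibit. The bounds
are implemented from their closed forms; agreement with the measure at the
uniform distribution is a test, not the implementation.

Because `M_k` depends only on the histogram, any bijective grey-level remap
whose bins align with the remapped levels leaves `D` unchanged. That is the
mechanism that turns contrast-reversed modality pairs into comparable images:
similarity is the mean absolute difference (MAD, L1) of the two descriptor
images, with an RMS (L2) option. Mutual information and raw-intensity MAD are
kept as baselines.

## Estimation choices

* **Binning**: intensity `v` maps to bin `⌊v · bins / 2^n⌋`. Default
  `bins = min(l², 2^n, 256)`; experiments that need the full variety degree
  (bit-depth studies) pass `bins = min(l², 2^n)` explicitly.
* **Weighting**: uniform; Gaussian `∝ exp(−‖d‖²/2σ²)` with default
  `σ = l/4` (keeps ±2σ inside the patch); or "modified" — a convex
  combination `(1−α)·Gaussian + α·point-mass-at-centre` with default
  `α = 0.5`. The modified form is this package's concrete choice for a
  centre-dominant weighting: one interpretable parameter, and the centre
  pixel always outweighs its Gaussian weight. Note a point-symmetric map
  cannot distinguish a patch from its pure mirror; what weighting does
  distinguish is arrangements that place different values at and near the
  centre.
* **Parzen estimation**: the weighted histogram convolved along the bin axis
  with a discrete Gaussian of standard deviation `bandwidth` bins (default 1),
  reflected at the bin edges, then renormalized. Smoothing happens after
  binning. A Parzen-smoothed descriptor may exceed the `min(l², ·)` bound
  because mass spreads over more bins than the patch has samples, so its
  variety degree is taken as `bins`.
* **Validation**: probability vectors must sum to 1 within 1e-9; they are
  never silently renormalized (an off-mass histogram is an upstream bug).
  Images must respect their declared bit depth; sides are capped at 4096 px.
* **Borders**: mirror (symmetric) padding, which introduces no intensity
  values absent from the image and keeps `D` the same size as `I`.

## Engine

The per-pixel computation is vectorized per intensity bin: the indicator
image of each bin is box-summed (uniform weighting — exact integer
integral-image arithmetic plus a lookup table of `f_k(c/l²)`) or correlated
with the separable weight kernel (Gaussian/modified — two 1-D passes). This
is algebraically identical to the per-patch accumulation and is tested
against a naive per-pixel loop to 1e-12 for all weightings, estimators and
kinds. Cost is `O(H·W·bins)`; bins are processed in chunks of 64 to bound
memory, except under Parzen smoothing where the full bin stack is needed.

## Rigid search and similarity curves

Similarity curves transform the moving image first (bilinear, rotation about
the centre and/or integer-step translation) and recompute its descriptor on
the transformed frame, so the descriptor sees the same resampling the
intensities do. Similarity is evaluated only on the valid-overlap mask, and
for descriptor methods the mask is additionally eroded by the patch radius so
no patch straddles fill values. Argmin ties break toward the lowest
parameter.

Curve steepness is summarized by the **normalized convergence rate**: orient
the curve so lower = better, min-max normalize to [0, 1], and average the
interpolated values at `extremum ± radius`. The default experiment radius is
5° of a ±15°…±25° sweep: near the extremum the rise of the curve reflects
how sharply the similarity locks onto the alignment, whereas values at the
sweep edge only measure tail saturation (both measures' tails flatten
together). A flat curve scores 0 by convention.

Multi-pair studies average *raw* curves over five independently seeded
phantom pairs before normalization, emulating the standard practice of
pooling similarity curves over many aligned layer pairs.

## Slice matching and deformation selection

Slice matching takes index identity as ground truth, picks the search slice
optimizing the method's criterion (ties toward the lowest index), and
classifies the signed index error: zero deflection (exact), left/right
deflection (±1 slice), failure (|error| > 1). Reported as counts (RDN, LDN,
ZDN, SUM = RDN+LDN+ZDN) and percentages (ZDP, SUM probability). The
deflection-study descriptor configuration is `l = 15`, 16 bins, modified
weighting, Parzen estimation.

Deformation selection scores a pool of candidate warps (one generated from
the ground-truth smooth field plus 50 random fields of the same amplitude
class) by similarity to the fixed image and charges the residual
`τ = mean_x ‖d_sel(x) − d_truth(x)‖` in pixels. Ten seeded repetitions are
averaged.

## Synthetic phantoms

The generator produces what the descriptors need from multimodal data and
nothing more: a smooth blob-shaped tissue label field (nested radial
structure plus thresholded smoothed noise, 5 tissues, each ≥1% of pixels)
rendered per modality as `clip(round(lut[label] · bias + ε))` with a smooth
multiplicative bias field of ±20% amplitude (intensity nonuniformity) and
Gaussian noise of 3% of the 13-bit range. The canonical pair uses ascending
tissue means for one modality and the reversed ordering for the other, so raw
intensities anti-correlate while structure is shared. Stacks evolve the label
field gradually across slices (adjacent slices differ in 0.5–50% of labels).
All generators are pure functions of their seed.

What the phantoms do **not** emulate: anatomical geometry, modality-specific
noise statistics (Rician noise, partial-volume effects), resolution
anisotropy, or acquisition artefacts. Passing synthetic studies therefore
demonstrates the *mechanism* — histogram-based descriptors survive contrast
reversal, steeper curves for the wider-range measure, deflection and residual
orderings — not clinical-grade accuracy figures, which depend on real data.

## Problem sizes used in the studies

* Rotation-vs-patch-size: 128×128 pairs, `l ∈ {3, 7, 11}`, angles −25…25°
  step 1°, five pairs averaged.
* Bit-depth study: 128×128 pairs compressed 13 → 7 bits
  (`⌊v/2^{13−n}⌋`), `l = 33`, `bins = min(l², 2^n)`, angles −20…20° step 5°,
  five pairs averaged. The patch is kept near a quarter of the frame; patches
  spanning half the frame leave rotated overlap regions too thin after
  patch-radius erosion and the curves degenerate. As in any finite-patch
  configuration, `r` is capped by `l²` at the top depths.
* Slice matching: 30-slice bimodal 64×64 stack.
* Deformation selection: 64×64 pairs, 51 candidates, amplitude 3 px at
  correlation scale 32 px (Jacobian-positive, hence invertible), 10 seeds.

## Numerical conventions and tie-breaks

* Probability sum tolerance 1e-9; local z-score guard ε = 1e-8; descriptor
  values stored at full float64 precision, 8-bit quantization only for
  preview export.
* All argmin/argmax ties break toward the lowest index for determinism.
* Transformed intensities are rounded back to the integer grid of the
  declared bit depth (exact for lattice-preserving transforms such as ±90°
  rotations and integer shifts).

## Known limitations

* Strictly 2-D. Collapsing a 3-D patch's richness to one number discards even
  more spatial arrangement, and no 3-D weighting is provided to compensate;
  the method is not expected to be robust for volumetric registration.
* The descriptor discards spatial arrangement within the patch up to what the
  centre-weighted histogram retains; structures with identical weighted
  histograms remain indistinguishable.
* Only discrete search over pre-generated transforms/deformations is
  provided; there is no continuous deformable-registration optimizer.
* The modified weighting is point-symmetric; it boosts the centre but cannot
  break pure mirror symmetry.
* At high variety degree the fuzzy measure's surplus over Shannon entropy is
  `Σ −(1−p_i) log(1−p_i) ≈ 1 − ½·Σ p_i²`, i.e. one nat minus half the
  histogram's collision probability. On phantoms whose high-bit intensities
  are dominated by independent Gaussian noise, patch histograms have almost
  no collisions, the surplus is nearly constant, and the measured convergence
  rates of M1 and M2 become statistically indistinguishable (M2 can sit ~1%
  below M1 in the bit-depth study, while it is consistently steeper at small
  patch sizes, where bins are well occupied). Demonstrating an M2 advantage
  at high `r` appears to require the intensity clustering of real tissue
  texture, which the i.i.d.-noise phantom deliberately does not model.
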