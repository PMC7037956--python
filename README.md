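# patchent

Patch-entropy structural descriptors for multimodal image similarity and
registration.

Images of the same anatomy acquired with different modalities (MRI T1/T2/PD,
CT, …) share structure but not grey values — tissue contrast may even be
reversed — so intensity criteria like the mean absolute difference (MAD)
cannot compare them directly. `patchent` maps each modality into a shared
*structure descriptor set*: every pixel is replaced by the uncertainty of the
intensity distribution of its local `l × l` patch. Uncertainty depends on
local intensity *richness*, not on the particular grey levels, so both
modalities land in the same representation and a plain mono-modal MAD becomes
a valid multimodal similarity measure.

## The measures

For a patch histogram `p = (p_1, …, p_r)` over `r` bins, the descriptor is
`M_k(p) = Σ_i f_k(p_i)` for one of four strictly concave core functions
(natural logarithm throughout):

| tag | core function `f(x)` | upper bound `B(r)` at uniform `p` | `B(r → ∞)` |
|-----|----------------------|-----------------------------------|------------|
| m1  | `−x log x` (Shannon) | `log r` | ∞ |
| m2  | `−[x log x + (1−x) log(1−x)]` (logarithmic fuzzy) | `log r + Δ(r)` | ∞ |
| m3  | `x e^(1−x) + (1−x) e^x − 1` (exponential fuzzy) | `e^((r−1)/r) + (r−1) e^(1/r) − r` | `e` |
| m4  | `x/(1+x) − x/2` (rational concave) | `r/(r+1) − 1/2` | `1/2` |

Every measure is 0 for a monochrome patch and maximal for a uniform
histogram. The working measure is **m2**: its bound exceeds the Shannon bound
by `Δ(r) = (r−1) log(r/(r−1))`, which grows to 1 nat — an ~18% wider
quantification range at 256 grey levels — and the wider range yields steeper
similarity curves around the correct alignment. `r = min(l², 2^n, bins)` is
the *variety degree* of an `l × l` patch at bit depth `n`. The bounded
measures m3/m4 plateau (near 2.706 and 0.496 by `r = 256`), which is why they
stop resolving richness at high bit depths.

Patches can be spatially weighted (uniform, Gaussian, or a centre-boosted
"modified" Gaussian) so that patches with equal histograms but different
centre content get different descriptors, and the binned histogram can be
Parzen-smoothed along the bin axis before the measure is applied.

## Worked example

```python
from patchent import (PatchSpec, bound_gap, similarity_curve,
                      mad_similarity, standard_pair, upper_bound)

for r in (9, 49, 256, 4096):
    print(f"r={r:5d}  B1={upper_bound('m1', r):.4f}  "
          f"B2={upper_bound('m2', r):.4f}  gap={bound_gap(r):.4f}")

fixed, moving = standard_pair(seed=1, size=128)   # aligned T1-like / T2-like pair
curve = similarity_curve(fixed, moving, "m2", PatchSpec(l=7), range(-10, 11, 5))
for angle, value in zip(curve.parameters, curve.values):
    print(f"angle {angle:+6.1f} deg   MAD(D_fixed, D_moving) = {value:.4f}")
print("raw-intensity MAD at 0 deg:", f"{mad_similarity(fixed, moving):.1f}")
```

prints

```
r=    9  B1=2.1972  B2=3.1395  gap=0.9423
r=   49  B1=3.8918  B2=4.8815  gap=0.9897
r=  256  B1=5.5452  B2=6.5432  gap=0.9980
r= 4096  B1=8.3178  B2=9.3176  gap=0.9999
angle  -10.0 deg   MAD(D_fixed, D_moving) = 0.4457
angle   -5.0 deg   MAD(D_fixed, D_moving) = 0.3517
angle   +0.0 deg   MAD(D_fixed, D_moving) = 0.1280
angle   +5.0 deg   MAD(D_fixed, D_moving) = 0.3349
angle  +10.0 deg   MAD(D_fixed, D_moving) = 0.4338
raw-intensity MAD at 0 deg: 4061.0
```

The fuzzy-entropy bound `B2` tracks `log r + Δ(r)` with `Δ(r) → 1`. The
descriptor MAD between the contrast-reversed pair bottoms out at the true 0°
alignment (0.128, against ≥ 0.33 a few degrees away), while the raw
intensities of the same pair differ by ~4061 of 8191 grey levels — raw MAD is
useless across modalities, descriptor MAD is not.

## Command line

```sh
patchent bounds --r-min 2 --r-max 1024 --out bounds.csv
patchent descriptor --in slice.png --kind m2 --l 7 --out slice_desc.tiff
patchent curve --method m2 --mode rotation --range -25 25 --step 1 --out curve.csv
patchent match --method m2 --l 15 --bins 16 --weighting modified --estimator parzen --out match.csv
patchent warp-select --method m2 --seed 1 --out warp.csv
patchent synth --kind pair --seed 1 --out phantom/
patchent run experiment.cfg        # flat key=value config file
```

Every run logs its resolved configuration and seed; rerunning the same config
produces byte-identical CSVs.

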