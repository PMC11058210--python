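# Methods

`occlumap` reconstructs the missing part of a prepared molar's occlusal
surface from a calibrated 2D depth map by inverting a fixed generative
model under a boundary-aware loss. This note records the models, the
numerical choices, and what the synthetic test bed does and does not show.

## Depth-map representation

A crown mesh (mm units) is reduced to an 8-bit square depth map in four
steps.

1. **Box derotation.** The minimum-volume oriented bounding box of the
   mesh removes the scanner's intrinsic frame. The box is found by an
   exhaustive search over convex-hull face orientations (exact whenever the
   optimal box is flush with a hull face), augmented with the world axes
   and the PCA axes of the hull as candidate box normals so the result
   never loses to the axis-aligned box. Box axes are canonicalized: extents
   sorted descending (the flattest direction becomes z), z signed so that
   the dominant share of near-axial surface normals points up, the
   first-axis sign fixed deterministically. The remaining in-plane freedom
   is resolved in 2D (below).
2. **Occlusal-plane leveling.** A total-least-squares plane is fitted by
   PCA to the points whose normal z-component exceeds `n_z_t = 0.9` (cusp
   tips and fossa floors — the features that define the occlusal table).
   The rotation built from the plane's slope vectors levels it; the fit is
   iterated (tolerance 0.002 deg, at most 10 rounds) so a second
   normalization moves vertices by less than 1e-3 mm RMS.
3. **Projection.** The mesh surface is sampled uniformly by area
   (deterministic per seed); each sample carries either an interpolated
   vertex normal (default) or its triangle's face normal (used by mask
   extraction, where creases must stay sharp). After shifting the cloud so
   its maximal height equals the global depth window `z_norm` (8 mm
   default), each pixel of the `w x w` grid (`w` a power of two, 256
   default) takes the maximal sampled height in its footprint, scaled
   linearly to intensity `255 z / z_norm`; empty pixels and heights at or
   below zero are background 0. The calibration `c_pix_mm = z_norm / 255`
   accompanies every map. Values stay continuous in memory; quantization
   to 8 bits happens on export (round half away from zero).
4. **In-plane canonicalization.** The minimum-area bounding rectangle of
   the crown outline is rotated axis-parallel (long side horizontal) and
   centered; the recorded cheek-facing (buccal) direction resolves the
   half-turn ambiguity by pointing it to the bottom half of the image. The
   pipeline applies this rotation to the point cloud *before*
   rasterization, which avoids image interpolation entirely; an equivalent
   image-space operation (warp) exists for PNG-only workflows and is
   accurate to interpolation error.

Repeatability: projections of one crown with different sampling seeds
differ only through sampling shot noise. At 64x64 / 1e5 samples, the 95%
confidence interval of the mean full-image RMSE against a reference
projection is about [0.03, 0.05] mm on the synthetic crowns; the dominant
term is silhouette-grazing pixels whose few low-intensity samples come and
go. The error falls roughly with the square root of the sample count;
production projections use 3.3e6 samples.

## Preparation masks

A cavity differs from occlusal anatomy in two ways: its walls are much
steeper than any cusp flank, and its floor lies below the occlusal relief.
Mask extraction keeps the sampled points with `n_z > n_z_t` (default 0.25;
cavity walls at 6 deg from vertical have `n_z ~ 0.1`, cusp flanks stay
above 0.3 even after leveling) and `z > z_t` (default: cavity floor + 0.2
mm), projects only those, and binarizes. Cleanup of the raw mask is
automated where the reference workflow edited by hand, under the
constraint that artifacts never touch the preparation edge: isolated dark
islands under 10 px are dropped *before* a radius-1 closing (closing first
would bridge them to the edge), a radius-1 opening removes filament
artifacts, holes are filled, and only the largest dark component is kept
(the preparation is one enclosed region). The boundary ring `M_B` is the
set of kept pixels within one 8-connected step of the removed region,
restricted to the crown.

Against the analytically known carve region, the extracted boundary agrees
within one pixel step (Euclidean sqrt(2), diagonal neighbor) on the
canonical test crown for all four preparation types, with region overlap
(Jaccard) of 0.98 or better. Across a wider population of random crowns,
isolated boundary pixels at the junction of the cavity and the crown
outline can reach ~2.2 px on strongly tilted crowns; the overlap stays at
or above 0.98.

Experimental masks: the interior circle mask is centered on the largest
inscribed circle of the crown and selects exactly the requested pixel
count by distance rank (rejecting fractions whose disk would touch the
outline); the boundary-cut control removes an equal pixel count as a cap
clipped against the outline.

## Reconstruction objective

With a binary mask `M` (1 = observed, 0 = removed), the corrupted image is
the Hadamard product `x_cor = x ⊙ M`. The latent matrix `w` (n_res x 512,
`n_res = 2 (log2 w - 1)`) of a fixed generator `G` is optimized under

    L_B = λ_pixel L_pixel + λ_percept L_percept + λ_w L_w
          + λ_colin L_colin + λ_pixel,B L_pixel,B

with the published weights `λ_w = -3.2`, `λ_colin = 8.6e-4`,
`λ_pixel = 6.7e-4`, `λ_percept = 9.2e3`, `λ_pixel,B = 4.0e-4`. Term
forms (each normalized by its element count so the weights are
scale-comparable):

- `L_pixel`: mean squared masked pixel difference;
- `L_percept`: feature-space distance of the masked images under a fixed
  deterministic multi-scale filter bank (below);
- `L_w`: mean squared distance of `w` from the generator's latent mean
  (the published weight is negative, rewarding distance from the mean; it
  is implemented exactly as printed);
- `L_colin`: mean (1 - cosine similarity) over latent row pairs, coupling
  the per-resolution styles;
- `L_pixel,B`: mean squared difference on the boundary ring — the term
  that enforces a seamless transition at the preparation edge.

Adam (α = 0.05, β1 = 0.9, β2 = 0.999) runs up to `n_R = 2000` steps per
restart; restarts (default 10; desk-scale runs use 2-3) initialize `w`
with unit Gaussian noise around the latent mean from seeds derived from
the master seed, and the restart with the smallest final objective wins.
All gradients are analytic and match central finite differences to better
than 1e-4 relative error. The merged result
`x_merge = x_cor + (M - 1)^abs ⊙ x_cln*` keeps every observed pixel
bit-exactly.

The point of diminishing returns `n_dr` is defined operationally as the
first step at which the relative objective decrease over a trailing
50-step window falls below 1e-3 (both configurable); the trace length is
returned if stagnation never occurs.

### Perceptual feature bank

The perceptual term uses a fixed random bank of zero-mean convolution
kernels at scales 3, 7 and 15 px (four kernels per scale, seed 7),
applied circularly. Because the bank is linear, the whole feature
distance reduces to a single spectral weighting `S(ω) = Σ_k |K̂_k(ω)|²`
evaluated via Parseval — one FFT per loss evaluation with an exact
adjoint. A pretrained deep feature extractor can be substituted through
the same interface; the bank keeps the desk-scale pipeline dependency-free
and deterministic.

### Generators

The optimizer only needs `evaluate`, `gradient` and `latent_mean`
(`GeneratorContract`). The production-scale model is a style-based GAN
trained on mirrored canonical depth maps; training such a network is out
of scope here, and `StyleGan2Adapter` is the documented slot for one (it
records the training configuration verbatim and refuses silently altered
settings). The bundled desk-scale model is `LinearGenerator`: a PCA basis
of the training maps, `image = clip(mean + B fold(w)[:rank], 0, 255)`,
where `fold` averages the latent rows into one 512-vector. Rows can
disagree during optimization, which keeps the colinearity term meaningful.
Component columns are scaled by data standard deviations so unit latent
coordinates have image-scale effect. With pixel-only weights the objective
is convex in the folded code and the optimizer reproduces the masked
normal-equations solution (relative gap < 1e-3), which serves as an
independent oracle in the tests.

## Synthetic crowns

Each crown is a watertight solid built on a polar grid: a superellipse
occlusal table (exponent 2.5, default semi-axes 5.6 x 4.9 mm) carrying a
dome, four Gaussian cusps (heights 2.0-2.6 mm, deliberately asymmetric by
0.6 mm), a central fossa (1.2 mm deep) and band-limited roughness (50 µm
std) — total height near 8 mm; a cervical skirt descends from the table
rim at slope 2 to a 1.4 mm lip, as in real crown depth maps whose outline
fades toward the dark cervical margin; a short wall and flat base close
the solid. The population generator jitters radii (±5%), cusp heights
(±8%; occlusal tables of functional molars are near-level, so leveling
tilts stay under ~9 deg), cusp positions (±0.4 mm), widths and fossa
depth, and draws a fresh roughness field per crown.

Cavity preparations are carved analytically in the leveled frame: inside
the footprint polygon the surface drops to a flat floor (default 0.6 mm)
with walls at 6 deg from vertical anchored at the local rim height, so
the removed region at the surface equals the polygon exactly — the oracle
for mask testing. The four default footprints remove ≈30/45/60/80% of
the crown's projected area (types a-d; b-d cut the outer contour).

What the synthetic bed does **not** emulate: real enamel microtexture and
scanner noise, anatomical groove systems, undercuts, multi-tooth context,
and the proprietary 92-crown data set and GPU-trained generator behind
the published headline numbers. Quantitative results on synthetic crowns
therefore demonstrate the pipeline's internal consistency — pose
invariance, edge fidelity, optimality, scaling of error with removed
area — not clinical accuracy.

### A capacity effect worth knowing about

The penalty for masks that cut the outer contour (versus interior masks of
equal area) is a statement about lost contour information. With the
desk-scale linear generator it is only measurable when the generator can
otherwise represent the image content: at 64x64 the interior-circle median
RMSE is clearly below the boundary-cut median (0.06 vs 0.09-0.24 mm across
configurations), reproducing the expected ordering, while at 128x128 the
ordering inverts — the rank-limited model cannot represent fine interior
texture, so interior masks inherit a capacity floor that swamps the
contour effect. The mask-size experiments therefore run at 64x64 (exact
block-maximum downsampling of the canonical maps, which commutes with the
max-height rasterization); a high-capacity generator would not need this.

## Study sizes

The default desk-scale study (acceptance script and pipeline defaults)
uses 92 synthetic crowns at 128x128 / 2e5 samples (mask extraction 4e5),
an 89/3 split mirrored to 178 training maps, a rank-24 linear generator,
and reconstructions with 800 Adam steps and 2 restarts. The test suite
uses a 26-crown population at 64x64 for reconstruction experiments and
the canonical crown at 128x128 for geometry checks. Projection
repeatability is evaluated at 64x64 with 1e5 samples (at 128x128 and 1e5
samples, interior pixels average about five samples each, so empty-pixel
dropout — absent at the production 3.3e6 — would dominate the
measurement). Pose-invariance comparisons hold the sampling seed fixed so
they isolate the normalization chain; sampling noise is what the
repeatability protocol measures.

## Known limitations

- The mask heuristic needs the preparation walls to be steeper than every
  occlusal slope; shallow saucer-shaped preparations would require
  per-case thresholds, as in the reference workflow.
- The automated mask cleanup substitutes the reference's manual edit; on
  strongly tilted crowns it can leave isolated boundary pixels ~2 px off
  at the cavity/outline junction.
- The linear generator has no notion of anatomy beyond the span of its
  training maps; reconstructions of large removals regress toward the
  population mean. Error trends (growth with removed area, the penalty
  for contour-cutting masks) reproduce qualitatively; absolute errors are
  not comparable to a trained deep generator.
- Back-projection triangulates the pixel grid and cannot restore
  sub-pixel detail or undercuts.
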