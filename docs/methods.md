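# Methods

## The operators

All seven operators share one scheme.  The input image `f` (8- or 16-bit
grayscale, at most 2048×2048) is edge-padded onto a square workspace whose
side is the smallest integer that keeps every original pixel inside the
canvas under rotation about the canvas center (no-clip guarantee, checked
geometrically against the padded corners).  For each plan angle θ_i =
(180/N)·i, i = 0..N−1, the workspace is rotated by θ_i with bilinear
interpolation, the classic flat operation (erosion/dilation composition
with the fixed structuring element) is applied to the real-valued samples,
and the result is rotated back and cropped to the original frame.  The N
per-angle images are fused pixelwise: maximum for the opening family,
minimum for the closing family.  Derived operators (top-hats, smoothing,
the two contrast enhancers) are built from the *float* fuses; quantization
to the input bit depth (round half away from zero, then clip) happens
exactly once, at output.

Angles live in [0°, 180°) rather than [0°, 360°): all three probe shapes
are point-symmetric, so θ and θ+180° define the same operation.  For a line
probe, N = 36 therefore means 5° orientation steps.

Classic morphology is computed with `scipy.ndimage.grey_erosion` /
`grey_dilation` over the probe's boolean footprint; rotation with
`scipy.ndimage.rotate(order=1, reshape=False)`.

## Numerical conventions

- **Lattice angles.**  θ ≡ 0 (mod 360°) is an exact identity, and exact
  multiples of 90° are performed with `np.rot90` *in the original frame*
  (no workspace).  This is not only faster and bit-exact; it also keeps the
  border policy consistent.  Composing erosion and dilation inside the
  padded workspace lets the dilation see eroded *pad* values, which differ
  from classic edge replication at the true image border — with the
  lattice-angle bypass, N = 1 (and every 90° term of larger plans) matches
  classic morphology exactly, including borders.
- **Border policy** defaults to edge replication (no spurious top-hat rim
  responses); `reflect` and `constant` are available.
- **Duality** ϕ_R(f) = M − γ_R(M − f) (M = 2^depth − 1) holds to ~1e−13 in
  float because bilinear interpolation is linear and min/max swap under
  complement; tests assert 1e−6.
- **Interpolation slack.**  Bilinear resampling is a low-pass operation.
  Rotate-then-unrotate recovers smooth images (Gaussian σ=3) to within ~4
  gray levels, but white noise is *not* recoverable (errors up to half the
  dynamic range).  Likewise strict anti-extensivity γ_R(f) ≤ f holds
  exactly at N = 1 but only within ~4 gray levels (measured on smooth
  images; tolerance frozen at 4) for N > 1.  Quantitative claims about the
  rotational operators are therefore made on structured images, not on
  per-pixel noise.
- **Smoothing order.**  Morphological smoothing is open-then-close
  (`ϕ_R∘γ_R`) by default; close-then-open and the average of both are
  configurable (`smoothing_order` = `oc` | `co` | `average`).
- **Enhancement definitions.**  MCE1_R is the extraction image
  f − MS_R(f) (a signed difference, normally routed through histogram
  modification); MCE2_R is the simultaneous emphasis f + WTH_R − BTH_R.
- **Histogram modification** of a signed output: shift so the minimum is 0,
  scale down only if the range exceeds 2^depth − 1, round to integer
  levels, CDF-based equalization over all 2^depth bins with first-nonzero
  normalization (darkest occupied level → 0), then a linear stretch to the
  full range.  A constant input maps to constant 0.
- **Thresholds.**  Otsu: exhaustive between-class-variance scan, smallest
  maximizer on ties, foreground strictly above the threshold.  Tsai: solve
  the moment-preserving equations for the two representative levels and the
  below-fraction p0, threshold at the smallest level whose cumulative
  frequency reaches p0.  Constant images are flagged degenerate and
  binarize to all zeros.
- **Structuring elements.**  Disk membership is inclusive: a cell belongs
  to a size-s disk iff its center lies within s/2 of the anchor, which
  gives the anchor row exactly s foreground cells.  Even sizes are promoted
  to the next odd integer (recorded on the element).  The line element is
  built horizontal; orientations come from rotating the image, never from
  resampling the element.  Sizes are capped at 99 and images at 2048 pixels
  per side as a policy limit (CLI `--no-limits` lifts the image cap).

## Evaluation phantoms

Two seeded generators provide ground-truthed test images.  Their defaults
are the package's study conditions; they were fixed once, so that each
phantom genuinely probes the angular-sampling behavior its pipeline is
designed around, and are frozen in the recipe attached to every phantom.

**Mesh phantom** (`make_mesh_phantom`, 128×128, 8-bit): two orthogonal
families of bright bars (intensity 200 on background 30, width 6.6 px,
pitch 24 px) at a per-seed global orientation uniform in [0°, 90°), with a
gentle sinusoidal undulation (amplitude 4 px, period 64 px) that spreads
the local bar orientation around the global angle; 12 circular distractors
(radius 1.5–2.5 px, mesh intensity) in the background; additive Gaussian
noise σ = 20.  Ground truth is the noiseless mesh mask.  The bar width sits
just under the effective span of the size-7 disk probe, so the probe fits a
bar only when some rotation aligns it well: a single orientation shreds the
oblique bars (mean Jaccard 0.77 over ten seeds), N = 8 restores them
(0.98), and the curve is flat beyond — the pipeline's similarity saturates
at N = 8.  Thresholding the raw phantom instead keeps every circular
distractor; the rotational opening removes them all.

**Aggregated-spots phantom** (`make_spots_phantom`, 128×128, 8-bit): 24
bright spots (radius 2 px, intensity 220) in chains of three with a 2-px
gap between spot edges, each chain at a per-seed orientation uniform in
[0°, 180°), over a slowly varying background (30 plus a smoothed random
illumination field of amplitude 20, noise σ = 5).  The gap carries a bright
ridge (intensity 175, full within 0.5 px of the chain axis, linear falloff
over 0.4 px) emulating the partial overlap of aggregated granular objects.
A line probe swept to within a couple of degrees of the chain axis reads
the ridge as a connected bright segment, reconstructs it into the opening,
and the top-hat splits the chain into its spots; a misaligned or isotropic
probe leaves the ridge in the top-hat and the spots merge.  Because the
alignment tolerance is a fraction of a pixel over the probe's 3.5-px
half-length, the white-top-hat pipeline keeps improving down to 5° steps:
its similarity saturates at N = 36, and the size-7 disk probe (N = 8)
merges every chain.

What the phantoms do *not* model: real point-spread functions, Poisson
noise, intensity-dependent shading, out-of-focus light, or the anatomical
textures of the real mammography/fluorescence applications.  Passing the
phantom suite shows the operators have the claimed geometric and angular
behavior, not that any particular biological segmentation task is solved.

## Evaluation metrics and the rotation sweep

Binary overlap is measured with the Jaccard index |A∩B|/|A∪B| (Dice is
also provided; the tests cross-check J = D/(2−D)).  The sweep
(`optimum_rotation_sweep`) runs a fixed pipeline — rotational opening +
Otsu for the mesh, rotational white top-hat + Otsu for the spots — over ten
seeded phantoms per rotation count, averages the Jaccard, and reports the
smallest N within 1% of the grid maximum (the saturation count).  Spot
separation is additionally checked by 8-connected component counts; because
individual seeds occasionally digitize one bridge so that a pair merges or
splits, the component-count comparison uses the median over ten seeds,
while the disk probe merges chains on every seed.

Problem sizes throughout (128×128 phantoms, ten seeds, the given N grids)
are the package's standard evaluation conditions; they complete in a few
seconds to a few minutes on one CPU.

## Known limitations

- Stacks are processed slice-wise; there is no 3-D (volumetric) morphology.
- Only flat (binary) probes; no grayscale-weighted or user-drawn elements.
- Bilinear interpolation softens single-pixel detail; operators on
  pixel-scale noise are well-defined but not quantitatively meaningful
  (see interpolation slack above).
- No decomposition-based fast paths (van Herk etc.); complexity is
  O(N · image · probe) via scipy's grey filters, which is ample at the
  supported sizes.
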