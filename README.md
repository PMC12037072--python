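# rotmorph

Rotational morphological processing for grayscale biomedical images.

Classic flat (binary-probe) morphology filters an image through a small
structuring element *B*: erosion is a moving minimum over the support of
*B*, dilation a moving maximum, and their compositions — opening γ, closing
ϕ, the top-hats — remove, fill or extract structure smaller than the probe.
Because *B* lives on the pixel lattice, it is not rotation invariant: a
discretized disk is subtly anisotropic, and a line probe only acts along
its own orientation.  When the objects of interest are fine, curved or
arbitrarily oriented (mammary filaments, organelle meshes, aggregated
fluorescent spots), a single probe orientation distorts or destroys them.

`rotmorph` implements the rotational variant of these operators: rotate the
image through *N* uniformly spaced angles θ_i = (180/N)·i (bilinear
interpolation on an edge-padded, no-clip canvas), apply the classic
operation with the *same* probe after each rotation, rotate back, and fuse
the per-angle results pixelwise —

- γ_R(f) = max_i R_{−θ_i}[ γ_B( R_{θ_i} f ) ]   (rotational opening)
- ϕ_R(f) = min_i R_{−θ_i}[ ϕ_B( R_{θ_i} f ) ]   (rotational closing)
- WTH_R = f − γ_R(f),  BTH_R = ϕ_R(f) − f       (top-hats)
- MS_R = ϕ_R(γ_R(f))                            (smoothing)
- MCE1_R = f − MS_R(f)                          (contrast enhancement 1)
- MCE2_R = f + WTH_R(f) − BTH_R(f)              (contrast enhancement 2)

With N = 1 every operator reduces bit-exactly to its classic counterpart.
Three probe shapes are provided (disk, line, square; size = diameter, line
length, or side), along with the histogram-modification post-stage
(shift → equalize → stretch) for the signed enhancement outputs, Otsu and
Tsai moment-preserving thresholding, 8-/16-bit TIFF single-image and stack
I/O, and seeded synthetic phantoms with ground truth for quantitative
evaluation.

Intended users: microscopists and image-analysis researchers who need
orientation-robust denoising, fine-structure enhancement, or separation of
aggregated granular objects as a preprocessing step for quantitative
morphology.

## Worked example

Extract an undulating mesh from a noisy synthetic phantom with a size-7
disk probe:

```python
import rotmorph as rm

ph = rm.make_mesh_phantom(seed=1)            # 128x128, 8-bit, with ground truth
req = rm.RMPRequest("opening", rm.make_se("disk", 7), rm.plan_angles(8))
out = rm.run_rmp(ph.image, req)              # rotational opening, N = 8
res = rm.otsu_threshold(out)
print(res.threshold)                          # 93
print(rm.jaccard(res.binary, ph.ground_truth))  # 0.9816
```

The Jaccard index 0.982 says the binarized extraction overlaps the true
mesh almost perfectly.  The same pipeline without rotation (`plan_angles(1)`,
i.e. a traditional opening) scores only 0.793: the single lattice-aligned
disk fails wherever the bars run oblique to the grid.

The same operations are available from the shell:

```sh
rotmorph run --op opening --se disk --se-size 7 --rotations 8 in.tif out.tif
rotmorph run --op wth --se line --se-size 7 in.tif out.tif   # N defaults to 36 for line
rotmorph threshold --method tsai out.tif binary.tif
rotmorph sweep sweep.csv --phantom mesh --se disk            # rotation-count sweep
```

Multi-page TIFFs are processed slice by slice; `--stack 2-5` or
`--stack 1,3,7` selects slices (1-based, inclusive).

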