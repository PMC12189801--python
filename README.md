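# accca

Nuclei segmentation for H&E-stained histology images by **a**ctive
**c**ontours + **c**onnected **c**omponent **a**nalysis: Macenko stain
separation isolates the hematoxylin (nuclear) signal, classical
morphology and the Euclidean distance transform extract per-nucleus
markers, connected-component analysis turns them into seeds, and a
geodesic active-contour level set grows each seed to the nucleus
boundary.  The package is aimed at computational-pathology work where
overlapping nuclei defeat plain thresholding and where a single active
contour would fuse touching objects into one.

## Method

**Stain separation (Macenko).**  Stains obey the Beer–Lambert law, so in
optical density `OD = −log10(I)` a pixel is a nonnegative mixture
`OD ≈ M c` of two unit color vectors (hematoxylin, eosin).  Pixels with
`OD > β = 0.15` in some channel enter an SVD; projection angles onto the
dominant plane are summarized by their robust `α = 1` / `99` percentile
extremes, which are mapped back to 3-D as the stain vectors.  Per-pixel
least-squares concentrations then render the normalized H&E, H-only and
E-only images; the pipeline proceeds on the H-only image, where nuclei
are dark.

**Markers and seeds.**  Otsu thresholding (dark = foreground), a 3×3
opening, and border clearing produce a clean mask; the Euclidean
distance transform `D` yields the sure foreground `D > ½·max(D)`
(maximum taken per connected component), the dilated-mask complement is
sure background, and the ring in between is unknown.  Each connected
component contributes one seed per disjoint sure-foreground blob, and a
blob spanning several nuclei is split among the local maxima of `D` —
this is how deeply overlapping nuclei each get their own seed.

**Geodesic active contours.**  All seeds initialize one signed-distance
field `u` (negative inside) evolved by

    du/dt = g(I)(κ + v)|∇u| + ∇g·∇u,
    g(I) = 1 / (1 + |∇ I₁|^p),  I₁ = Gaussian blur of I,

with curvature `κ = div(∇u/|∇u|)`, a balloon constant `v` (negative =
inflate, the default, since seeds start inside nuclei), and an
edge-stopping function `g` that is ≈1 in flat regions and small on
edges; `∇g·∇u` pulls the contour onto an edge and pushes it back on
overshoot.  The solver is an explicit upwind scheme with periodic
signed-distance reinitialization; fronts grown from different seeds may
meet but never fuse, so two nuclei overlapping across a shared edge stay
two objects while a single front remains free to split.

**Synthetic scenes.**  Because the method is unsupervised, a seeded
generator renders elliptical, hematoxylin-dominant nuclei through
`I = 10^(−M c)` with partial overlaps (stain adds in OD, so overlaps are
darker), an eosin-textured background, and Gaussian intensity noise —
with exact instance ground truth for every stage.

## Worked example

```python
import accca

scene = accca.generate_scene(160, 160, n_nuclei=10, overlap_fraction=0.3,
                             noise_sd=0.01, seed=7)
result = accca.run(scene.image, truth=scene.truth)

m = result.metrics
print(f"nuclei in truth:      {m.n_truth}")
print(f"nuclei segmented:     {m.n_pred}")
print(f"foreground Dice:      {m.dice:.3f}")
print(f"mean per-object Dice: {m.mean_object_dice:.3f}")
print(f"object count error:   {m.count_error}")
```

prints

```
nuclei in truth:      10
nuclei segmented:     10
foreground Dice:      0.985
mean per-object Dice: 0.980
object count error:   0
```

i.e. on this scene all ten nuclei — including the three deliberately
overlapping ones — are recovered as separate objects whose pixels agree
with the ground truth to a Dice coefficient of 0.985 (foreground) and
0.980 (averaged over matched objects).

The same run is available from the shell:

```
accca synth --n-scenes 1 --n-nuclei 10 --overlap 0.3 --noise 0.01 --seed 7 --out scenes/
accca run scenes/scene_000.png --truth scenes/scene_000_truth.tif --out out/
```

Other subcommands (`normalize`, `enhance`, `segment`, `augment`,
`evaluate`) expose the individual stages; composing them is equivalent
to the single `run` invocation.

## Layout

```
src/accca/stain_norm.py   Macenko estimation and stain separation
src/accca/enhance.py      threshold, morphology, distance transform, markers
src/accca/components.py   connected components, LoG blobs, seed generation
src/accca/gac.py          geodesic active-contour level set
src/accca/synth.py        synthetic H&E scenes + evaluation metrics
src/accca/pipeline.py     end-to-end orchestration, augmentation, split
src/accca/cli.py          accca command-line interface
docs/methods.md           model, parameters, numerics, limitations
```
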