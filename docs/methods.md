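# Methods

## Model

The pipeline treats an H&E image as a Beer–Lambert mixture of two
absorbing stains.  With intensities normalized to [0, 1] and optical
density `OD = −log10(max(I, ε))`, a pixel satisfies `OD ≈ M c` where
`M ∈ R^{3×2}` holds the unit OD color vectors of hematoxylin and eosin
and `c ≥ 0` the stain concentrations.  Segmentation then operates on
the hematoxylin channel alone: nuclei are hematoxylin-dominant, so the
H-only image shows them dark on a light background, and everything
downstream (thresholding, markers, contours) assumes that polarity.

### Stain-vector estimation

Macenko estimation as implemented here:

1. keep pixels with `OD > β` in at least one channel (β = 0.15;
   near-transparent background carries no stain information);
2. SVD of the tissue OD tuples; the two leading right singular vectors
   span the stain plane.  Each basis vector is sign-flipped so its
   entry sum is ≥ 0 (the SVD sign is otherwise arbitrary);
3. project tuples into the plane and take the angles of the projections;
   the α and 100−α percentiles (α = 1, linear interpolation between
   order statistics) are the robust extreme directions;
4. map the two extremes back to 3-D, clip negatives, normalize to unit
   length; the min-angle vector is provisionally hematoxylin and the
   columns are swapped if eosin ends up with the larger blue-channel
   absorbance (hematoxylin absorbs more blue; the min/max-angle
   assignment alone depends on the plane orientation);
5. concentrations are the per-pixel least-squares solution clipped at
   zero; per-stain robust maxima are 99th percentiles, used to rescale
   against a stored reference when one is supplied.

A tissue cloud of rank < 2 (single stain, empty slide) raises a
degenerate-stain error rather than returning meaningless vectors.

### Marker extraction

Otsu's threshold (256-bin histogram) with dark-is-foreground polarity,
a 3×3 opening with 2 iterations, and removal of frame-touching
components give the working mask.  On the exact Euclidean distance
transform `D`, sure foreground is `D > fg_fraction · max(D)` with the
maximum taken **per 8-connected component** (fg_fraction = 0.5).  The
per-component reference is deliberate: a global maximum silently erases
every nucleus whose inradius is below half the largest one, which is
the common case with nuclei radii spanning 6–14 px.  Sure background
is the complement of a 3-iteration dilation of the mask; the remainder
is the unknown ring.

Each mask component contributes one seed per disjoint sure-foreground
blob.  Two nuclei overlapping deeply enough share a single blob (the
neck of their merged distance field stays above the threshold), but
each keeps a local maximum of `D` at its own core with a saddle
between; blobs containing two or more distance peaks at least
`peak_min_distance = 8` px apart are therefore partitioned among the
peaks by nearest-peak assignment.  A component with no sure-foreground
pixels at all falls back to its distance peak as a one-pixel seed.

### Level-set evolution

All seeds initialize a single signed distance field `u` (negative
inside), evolved explicitly by

    u_{t+dt} = u_t + dt · [ g κ |∇u|_c + v g |∇u|_± + ∇g·∇u_± ]

where `|∇u|_c` is the central-difference magnitude, `|∇u|_±` the
Godunov upwind magnitude w.r.t. the sign of `v g`, and the advection
term upwinds each component against the sign of the corresponding
component of `∇g`.  Curvature is `div(∇u/|∇u|)` with the gradient
magnitude floored at 1e−8 and the result clamped to ±1 per grid unit.

The stopping field is `g = 1/(1 + (λ|∇I₁|)^p)` on the
Gaussian-smoothed image `I₁`.  Two choices here matter and are easy to
get wrong on unit-range images:

- **gradient gain λ (default 60).**  A nuclear edge smoothed at σ = 1
  has gradient magnitude of only a few percent per pixel; without a
  gain, `g` stays ≈ 0.99 at edges and the balloon walks straight
  through.  λ = 60 maps such edges to g ≈ 0.1 while noise-level
  gradients (intensity noise sd 0.01) stay at g ≈ 0.95.
- **smoothing σ (default 1 px).**  The lens between two nuclei
  overlapping by 20 % of a radius is ~2 px wide; σ = 2 smoothing erases
  it entirely (no internal edge survives), σ = 1 preserves it while
  still suppressing pixel noise.

The balloon force is gated twice: it acts only where `g > 0.1`
(otherwise its residual speed `|v| g` creeps through broad low-g
"all-edge" basins such as the overlap lens) and only within
`|u| ≤ 2` of the zero level (otherwise it slowly flattens the thin
positive barrier between two fronts that have stopped on opposite
sides of a shared edge; since reinitialization keeps `u` a signed
distance, the gate leaves the contour's own speed untouched).

**Seed identity.**  The evolution tracks which seed each interior
pixel belongs to.  A pixel may only turn interior if its labeled
8-neighbors agree on the seed; a pixel claimed by two different fronts
is refused and remains a one-pixel wall.  This is the same exclusion
rule as in marker-controlled watershed and topology-preserving level
sets: each seed is one nucleus, so cross-seed merging is never the
desired outcome, while a single front remains free to split or vanish.
Near the tips of an overlap lens the two nuclear edge arcs approach
within a pixel and share one blurred g-valley, so without the rule the
fronts fuse there no matter how strong the stopping function is.
Final labels are read directly off this identity map (equivalently:
every final component is assigned to the seed with which it shares the
most area); interior pixels no front ever reached become fresh labels.

**Maintenance.**  Every `reinit_every = 20` steps, `u` is rebuilt as
the signed distance to its own zero level, extracted with subpixel
precision by marching squares and resampled at 0.05-px spacing (the
zero level moves by well under half a pixel).  Negative components of
at most 2 px nowhere deeper than 0.5 are dissolved at that point:
such features are below grid resolution, and the central-difference
curvature scheme stagnates on an isolated grid minimum instead of
extinguishing it (a collapsing circle would otherwise leave a
one-pixel remnant forever).

**Stability.**  Before each step two CFL-style bounds are checked
(ConfigError on violation): `dt · max(g|v| + |g_r| + |g_c|) ≤ 0.5`
for the hyperbolic terms and `dt · max(g) ≤ 0.5` for the clamped
curvature term.  Defaults: `dt = 0.4`, `v = −0.3`, `p = 2`,
`max_iters = 500`, convergence when the mean |Δu| inside the |u| < 3
band drops below `tol = 1e−4`.

## Tunable parameters

| name | default | unit | meaning |
| --- | --- | --- | --- |
| α | 1 | percent | robust percentile of projection angles |
| β | 0.15 | OD | transparency threshold for tissue pixels |
| ε | 1e−6 | intensity | floor before the logarithm |
| se_size / open_iterations | 3 / 2 | px / – | opening footprint and repeats |
| fg_fraction | 0.5 | – | sure-fg fraction of per-component max distance |
| min_area | 20 | px | components below this are dropped |
| peak_min_distance | 8 | px | separation of distance peaks when splitting seeds |
| v | −0.3 | px/time | balloon speed (negative inflates) |
| smooth_sigma | 1.0 | px | Gaussian sd before the stopping gradient |
| gradient_gain | 60 | – | gain on the smoothed gradient inside g |
| balloon_threshold / balloon_band | 0.1 / 2.0 | – / px | balloon gates (see above) |
| dt / max_iters / reinit_every / tol | 0.4 / 500 / 20 / 1e−4 | | solver controls |
| train_fraction | 0.75 | – | split with floor on the training side |

The augmentation stage is a deterministic grid (rotations × shifts ×
scales, bilinear, reflection padding, about the image center), not
random sampling, so its output count is exactly the product of the
three lists and every run is reproducible.

## Synthetic scenes

`generate_scene` emulates the statistical structure the pipeline
assumes: elliptical nuclei with semi-axes U[6, 14] px, hematoxylin
concentration U[0.7, 1.2] and eosin co-concentration U[0, 0.1]; a
requested fraction of nuclei placed at center distance
U[0.75, 0.95]·(sum of mean radii) from a partner to force partial
overlap; concentrations composited additively in OD (overlap regions
are darker, which is what creates the internal edge the contours stop
at); a smooth background eosin field spanning concentrations
[0.1, 0.3] — the dense end emulates eosin-stained stroma and keeps the
two-stain estimation well posed, the faint end lies below the β
threshold like near-transparent glass; Gaussian noise added in
intensity space and clipped.  Ground truth assigns overlap pixels to
the nucleus with the higher hematoxylin concentration.  One seeded
generator drives all sampling, so scenes are bit-reproducible.

What the generator does **not** emulate: chromatin texture inside
nuclei, out-of-focus blur, stain-batch and scanner variation, clusters
of more than two mutually overlapping nuclei, and non-elliptical
shapes.  Passing tests therefore demonstrate correctness of the
algorithms under the stated geometric/optical model, not performance
parity on scanned tissue; on real slides the stopping-function gain,
smoothing and marker parameters are the knobs that need re-tuning.

Default problem sizes — 160×160 scenes with 10 nuclei, 20 scenes per
experiment — were chosen so a nucleus spans the same ~10–30 px it does
at typical 20× crops while a full experiment stays comfortably
CPU-friendly.

## Evaluation

`evaluate` reports foreground Dice `2|A∩B|/(|A|+|B|)` and IoU, the
absolute object-count error, and the mean per-object Dice over pairs
matched greedily by descending IoU (ties broken by label order;
unmatched objects simply do not contribute).  Two empty maps score
Dice 1 by convention.

## Known limitations

- The marker stage assumes at most pairwise overlap; chains of three or
  more mutually overlapping nuclei can still yield merged seeds.
- The seed-identity rule makes cross-seed merging impossible by
  construction; if the seed stage over-segments (two seeds in one
  nucleus), the evolution preserves that mistake rather than repairing
  it.
- Level-set features below one pixel are not representable; contours of
  nuclei smaller than ~3 px radius are unreliable.
- The augmentation grid reproduces counts multiplicatively; it does not
  attempt to reproduce any particular external dataset size.
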