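# Methods

This note records the model behind `pelletgran`, the choices made where
the design was genuinely open, and what the synthetic experiments do and
do not demonstrate.

## The measurement model

A dish of piled feed pellets is imaged at a known isotropic scale
(default 0.072 mm per pixel) under diffuse, near-shadowless lighting, so
pellets are bright on a darker background.  No segmentation is
attempted.  Instead, flat grayscale openings with disks of increasing
radius act as a sieve: the opening with radius *r* removes bright
structure that cannot contain a disk of radius *r*.  Writing A(·) for
the total pixel sum, the opening intensity curve r ↦ A(γ_r f) drops
where the disk size passes the pellets' projected half-width, the
pattern spectrum PS(r) = (A(γ_r f) − A(γ_{r+1} f))/A(f) estimates the
size distribution, and the curve's scalar summaries (mean, median, APM)
are size indices tracked over batch time.  Because lying pellets project
their diameter as the capsule width regardless of orientation, a disk
probe makes the readout rotation-independent; the index responds to
diameter and length jointly, i.e. to projected area.

Assumptions: 8-bit-scale intensities; pellets brighter than background;
isotropic calibration; and a radius grid that extends past the largest
pellet half-width (otherwise the spectrum is truncated and the indices
saturate).

## Structuring-element families

**Exact disks** contain pixel (i, j) iff i² + j² ≤ r².  Their footprints
nest, but digital disk families are *not* sieving families: a digital
disk of radius R is generally not a union of translates of a smaller
digital disk (opening disk(3) by disk(1) strips its four (±2, ±2)
pixels).  Consequently opening curves under exact disks can ripple by a
few tenths of a percent, and the spectrum can carry small spurious
(even negative) bins.  This is intrinsic to digitisation, not an
implementation artifact — it is also why derivative curves from
approximated disks show re-occurring spikes at fixed radii, and why
results are best indexed by the **effective radius** sqrt(area/π).

**Decomposable disks** (the default) are convex digital octagons built
as Minkowski sums of `a` unit diamonds and `b` unit 3×3 squares.  Per
radius, (a, b) minimises |area − πr²| subject to the octagon half-width
staying within one pixel of r, with (a, b) componentwise non-decreasing
along the family.  Design notes:

* A plain greedy rule ("largest octagon inside the Euclidean disk")
  degenerates to pure diamonds, whose area falls ~34 % short of πr²;
  area-matching keeps the deviation ≤ 15 % for r ≥ 3 (≤ 4 % for r ≥ 5)
  and the footprint within 12 % symmetric difference of the exact disk
  at r = 8.  Radii 1 and 2 coincide with the exact disks.
* Because (a, b) is monotone, every element is a Minkowski factor of
  all larger ones.  This yields the sieving property exactly — openings
  compose, curves are provably non-increasing, spectra non-negative
  with an exactly telescoping sum — which footprint nesting alone would
  *not* guarantee.  It also gives the speed-up: erosion by the chain of
  a + b unit elements costs O(a + b) small passes instead of O(r²) per
  pixel.

Comparison shapes (flat octagon, diamond, and a non-flat "ball" with a
quantised spherical-cap height profile of height r) are provided for
the element-comparison experiment; all footprints are 180°-symmetric so
openings stay rotation-independent.

Border handling: erosion pads with +∞ and dilation with −∞, making a
constant image a fixed point of every flat operation and keeping
border-touching pellets un-eroded.  Intensities accumulate in float64
(a full 8-bit frame sums to ~1.2×10⁸, far inside exact integer range).

## Indices and series

* Mean and median of the curve; quantiles use the linear-interpolation
  rule (so the IQR of [0, 1, 2, 3, 4] is exactly 2).
* **APM** is the opening intensity at the pattern-spectrum maximum,
  ties broken toward the smaller radius; a flat spectrum is flagged
  degenerate and falls back to the smallest radius.  As a *per-image*
  operation APM uses that image's own spectrum.  As a *batch series*,
  the position is anchored at the argmax of the batch-averaged
  spectrum: a per-sample argmax necessarily jumps between adjacent
  radii whose intensities differ by the largest spectrum bin, burying
  the drift signal under a sawtooth whenever the pellet size crosses a
  radius boundary (intensities at any fixed radius rise smoothly with
  size; the per-sample-argmax series does not).  The anchored series is
  what makes APM interchangeable with mean/median as a monitor, which
  is precisely its observed behaviour on production batches.
* Trend lines are least squares in t (linear) or ln(1 + t)
  (logarithmic, the default — extruder drift decelerates).  Series
  comparison reports Pearson correlation and RMSE; RMSE is quoted on a
  millimetre scale after normalising the index series to the reference
  mean by a single multiplicative factor (which leaves correlations
  untouched).  Zero-variance series yield NaN correlation rather than
  an error.
* The opening radius converts to object diameter as 2·r·mm_per_pixel.

## Synthetic scenes

The generator emulates the production imaging conditions: capsules
(rectangle plus semicircular caps) of sampled diameter/length at
uniform random position and orientation, a configurable standing
fraction (default 0.20) rendered as discs of the diameter, z-order
compositing so later pellets occlude earlier ones, per-pellet albedo
jitter, ~1 px soft edges, additive sensor noise — and a thin darker rim
per pellet so stacked pellets keep a visible seam instead of merging
into one large bright blob (real clusters keep the structure of their
constituent pellets; this is also what makes a moist aggregate *not*
read as one large pellet).  There are no cast shadows, matching an
integrating-sphere rig.  Everything is a pure function of the seed.

Batch presets reproduce the reference sampling plans (1.1 mm product:
11 samples 5 min apart; 3.0 mm product: 27 samples over 45 min).  The
size drift is logarithmic, start + growth·ln(1 + t), with the start at
the nominal product size and the *relative* drift taken from the
image-measured opening diameters of such batches (×8/7 for the 1.1 mm
run, ×25/21 for the 3.0 mm run); relative size spread (~4.3–4.5 %)
follows hand-calliper spreads.  Pellet length is set to 1.5× the
diameter — a typical extruded-feed aspect ratio; length data are rarely
reported.  Default pellet counts give dish-like coverage (~0.7) at the
default 600×800 frame; the test suite uses 192×256 frames with 250
pellets, the same optics at a smaller field of view.

What the generator does *not* model: 3-D stacking geometry (tilted
pellets, perspective), inter-pellet shadows, specularities, moisture
gradients, dish rims, or real sensor nonuniformity.  Passing tests
therefore demonstrate the method's internal consistency and its
behaviour under controlled drift, spread, occlusion and noise — not its
accuracy on any particular physical rig, which requires the calliper
comparison workflow on real images.

## Numerical and degenerate-input choices

* CLAHE defaults: 8×8 tiles, clip limit 0.01, output 0–255 (contrast
  should simply be as high as possible; the exact values are
  conventional and configurable).  Images smaller than the tile grid
  are rejected.
* Blank (zero-intensity) images: the curve is all-zero, the spectrum is
  undefined; the pipeline flags the result degenerate, reports the
  smallest radius as peak, and still emits all indices.
* The baseline isolated-pellet measurement thresholds with Otsu's
  method (manual override available), labels 8-connected components and
  reports principal-axis *extents* (max − min span + 1 along the
  second-moment eigendirections).  Extents, unlike moment-ellipse axis
  lengths, return ~20 px for a 20-px rectangle, matching what one
  means by "length and width in pixels"; border-touching components are
  measured and flagged.
* 16-bit inputs are rescaled by max-value division (×255/65535); RGB
  collapses by channel mean.
* Disc placement in the binary oracle fixture keeps Chebyshev gaps of
  ~2 r between footprints so every opening treats the discs
  independently; placement failure after bounded retries is an error.

## Known limitations

* Exact-disk opening curves are not strictly monotone (see above); the
  acceptance check that a digital disc's opening intensity equals its
  full pixel mass at *every* smaller radius fails by up to ~4 % at some
  radii — a theorem about digital disks, not a tunable defect.  The
  spectrum peak and the beyond-the-radius zero are exact.
* The pattern spectrum is a projected-size distribution of the visible
  pile surface, not a per-pellet distribution; heavy occlusion shifts
  mass to smaller radii.
* APM needs at least two samples to anchor its batch position; single
  images fall back to the per-image peak.
* The opening reads the inscribed disk of the (soft-edged) capsules, so
  peak diameters sit one radius bin below the nominal diameter; on
  real rigs this offset is absorbed by the millimetre normalisation
  against reference measurements.
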