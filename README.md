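# pelletgran

Segmentation-free monitoring of feed-pellet size in grayscale images by
grayscale granulometry.

Extruded aquaculture feed pellets drift in size during a production
batch: the die plate clogs, pressure and temperature rise, and the
output diameter and length creep upward.  Fish growth depends on pellet
size, so production needs an automatic readout of that drift.  Images of
the product show piled, disordered, overlapping pellets — hopeless for
per-object segmentation, and exactly the situation granulometry was made
for.

**Who it is for:** image-analysis engineers and process-control people
who need a scalar "how big are the pellets right now" signal from a
camera over a dish or conveyor, plus anyone who wants a clean, tested
implementation of grayscale opening granulometry and the pattern
spectrum.

## Method

For an image *f* and a structuring element *B*, the flat erosion,
dilation and opening are

    (f ⊖ B)(x) = min{ f(x + b) : b ∈ B }
    (f ⊕ B)(x) = max{ f(x − b) : b ∈ B }
    γ_B(f)     = (f ⊖ B) ⊕ B

The opening removes every bright structure the element cannot fit
inside.  With a family of disks *nB* of increasing radius (disks make
the probe rotation-independent, which piled pellets require) the total
surviving intensity A(γ_n f) is the **opening intensity (granulometric)
curve**, and its normalised successive differences form the **pattern
spectrum**

    PS(n) = ( A(γ_n f) − A(γ_{n+1} f) ) / A(f),

read as an estimated particle-size distribution.  Scalar **size
indices** summarise each curve — its mean, its median, or the intensity
at the pattern-spectrum maximum (APM) — and the interquartile range of
the curve measures size spread.  Tracked over batch time, the indices
follow the (logarithmic) size drift; the spectrum-peak radius converts
to millimetres as `2 · r · mm_per_pixel` (0.072 mm/px on the reference
rig, so an 800 px frame spans 57.6 mm).

Two disk families are provided: exact digital Euclidean disks, and a
fast **decomposable** octagonal approximation built as a Minkowski chain
of unit diamonds and squares.  The decomposable family is the default:
it opens images in O(chain length) small erosions instead of O(r²) per
pixel, and — because every element is a Minkowski factor of the larger
ones — it is an exact sieving family, so its opening curves are provably
monotone.  Effective radii `sqrt(area/π)` correct for the approximation
when reporting millimetres.

A seeded synthetic-scene generator (capsule-shaped pellets piled with
occlusion, near-shadowless shading, drifting batch series with ground
truth) makes every stage testable without production data.

## Worked example

`python examples/size_distribution_from_pile.py` renders a dish of 250
pellets of 1.1 mm nominal diameter and estimates their size without
segmenting anything:

```
scene: 250 pellets rendered, true mean projected width 1.101 mm
pattern-spectrum peak: radius 6 px -> opening diameter 0.864 mm
spectrum (radius: fraction of image intensity lost):
  r= 5  0.054 ##########
  r= 6  0.160 ################################
  r= 7  0.072 ##############
```

The spectrum peaks at radius 6: disks of radius 7 no longer fit inside
the pellets, so most pellet intensity vanishes between those openings.
Twice the radius, calibrated, gives the dominant projected size
(0.86 mm here — the opening reads the *inscribed* width of the soft-edged
capsules, a bin below their nominal diameter).

`python examples/monitor_batch_drift.py` simulates an 11-sample batch
with logarithmic size drift and prints, per index, the fitted trend:

```
  mean: slope +2.598e+05 per ln-minute (+4.6% of the index level)
median: slope +3.143e+05 per ln-minute (+5.7% of the index level)
   apm: slope +3.435e+05 per ln-minute (+5.8% of the index level)
mean/median agreement: r = 0.980
```

Positive slopes on all three indices flag the upward size drift.  See
also `examples/exact_vs_decomposable_disks.py` (the two families'
curves correlate at 0.999 while the decomposable one runs ~3× faster
already at radius 12) and `examples/baseline_isolated_pellets.py`.

## Command line

```bash
pelletgran simulate --preset batch-c --seed 42 --out scenes/
pelletgran analyze --input 'scenes/*.png' --mm-per-pixel 0.072 \
    --max-radius 30 --element disk-approx --out results/
pelletgran monitor --manifest scenes/manifest.csv --index median \
    --trend log --out results/
```

`analyze` writes a per-image long-format CSV (radius, effective radius,
intensity, derivative, spectrum value) plus a JSON summary; `monitor`
writes the index series, trend fits and — given a calliper CSV with
`time,length,diameter` columns — correlation and RMSE against the
reference measurements.

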