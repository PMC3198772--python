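"""Exact Euclidean disks vs fast decomposable (octagonal) disks.

The decomposable disk family opens an image as a short chain of unit
diamond/square erosions instead of probing the full O(r^2) footprint,
which is what makes on-line monitoring affordable.  This script shows
that the two families produce near-identical opening curves while the
decomposable one runs much faster at large radii.
"""

import time

import numpy as np

import pelletgran as pg

pop = pg.PelletPopulation(1.1, 0.047, 1.65, 0.071, count=250, seed=8)
image, _ = pg.render_pile(pop, (192, 256), 0.072, overlap=0.95)

curves = {}
for kind in ("disk_exact", "disk_decomposable"):
    family = pg.disk_family(12, kind)
    t0 = time.perf_counter()
    curves[kind] = pg.opening_curve(image, family)
    elapsed = time.perf_counter() - t0
    print(f"{kind:18s}: {elapsed:5.2f} s for radii 1..12, "
          f"effective radii {np.round([se.effective_radius for se in family[-3:]], 2)} (last three)")

corr = np.corrcoef(
    curves["disk_exact"].intensities, curves["disk_decomposable"].intensities
)[0, 1]
print(f"opening-curve correlation exact vs decomposable: {corr:.4f}")
print("The approximation changes the curve only marginally (r > 0.99), so "
      "the fast family is the default for production monitoring; effective "
      "radii sqrt(area/pi) correct for its area deviation when reporting "
      "sizes in millimetres.")
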