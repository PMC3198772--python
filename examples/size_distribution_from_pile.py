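"""Estimate a pellet size distribution from one image of a piled dish.

Renders a synthetic dish of 1.1 mm-class pellets, runs the granulometry
pipeline (CLAHE, opening curve, pattern spectrum) and prints the
estimated dominant size.  No pellet is ever segmented: the pattern
spectrum is read directly off the opening intensity curve.
"""

import numpy as np

import pelletgran as pg
from pelletgran.pipeline import AnalysisConfig, analyze_image

pop = pg.PelletPopulation(
    diameter_mean=1.1, diameter_sd=0.047,
    length_mean=1.65, length_sd=0.071,
    count=250, seed=42,
)
image, truth = pg.render_pile(pop, (192, 256), mm_per_pixel=0.072, overlap=0.95)
result = analyze_image(image, AnalysisConfig(max_radius=14))

print(f"scene: {len(truth)} pellets rendered, "
      f"true mean projected width {truth.mean_projected_width_px * 0.072:.3f} mm")
print(f"pattern-spectrum peak: radius {result.peak_radius} px "
      f"-> opening diameter {result.peak_diameter_mm:.3f} mm")
print("spectrum (radius: fraction of image intensity lost):")
for r, v in zip(result.spectrum.radii, np.round(result.spectrum.values, 3)):
    print(f"  r={r:2d}  {v:.3f} {'#' * int(200 * v)}")
print("The peak marks the disk radius at which the opening starts removing "
      "the pellets themselves; twice that radius, calibrated, is the "
      "dominant projected pellet size.")
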