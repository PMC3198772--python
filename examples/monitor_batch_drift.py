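"""Track pellet-size drift over a simulated production batch.

Simulates an 11-sample batch of 1.1 mm product whose size drifts
logarithmically (as extruder batches do), computes the mean/median/APM
size indices per sample and fits a logarithmic trend line to each.
Positive slopes flag the upward size drift an operator would react to.
"""

import pelletgran as pg
from pelletgran.pipeline import AnalysisConfig, analyze_image, monitor_series

config = AnalysisConfig(max_radius=14)
family = config.family()
drift = pg.batch_c_drift(seed=3, count=250)
scenes = pg.render_batch(drift, (192, 256), 0.072, overlap=0.95)

times, results = [], []
for t, image, _ in scenes:
    times.append(t)
    results.append(analyze_image(image, config, family))

mon = monitor_series(times, results, trend_form="logarithmic")
print("time (min) vs median size index (intensity units):")
for t, v in zip(times, mon.series["median"].values):
    print(f"  t={t:4.0f}  {v:12.0f}")
for method in ("mean", "median", "apm"):
    tl = mon.trends[method]
    rel = tl.slope / mon.series[method].values.mean()
    print(f"{method:>6s}: slope {tl.slope:+.3e} per ln-minute "
          f"({rel:+.1%} of the index level)")
corr, _ = pg.compare_series(mon.series["mean"], mon.series["median"])
print(f"mean/median agreement: r = {corr:.3f}")
print("All three indices rise with batch time: the pellets are growing, "
      "and each index is a usable drift monitor.")
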