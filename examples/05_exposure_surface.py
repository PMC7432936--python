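"""Predict an exposure surface from a fitted model.

The model is evaluated at every cell center of a raster covering the city.
Predictors are clamped to their training ranges (standard LUR practice) and
negative predictions floored at zero; both interventions are flagged.
"""

import numpy as np

import airlur as al

result = al.run_study(seed=1)
model = result.models[("NO2", "annual")]
print(f"NO2 annual model: {model.predictor_names}, R2 {model.fit.r2:.2f}")

grid = al.rasterize(model, result.scene, cell_size=1000.0, quad_segs=64)
arr = grid.to_array()
print(f"surface: {arr.shape[0]} x {arr.shape[1]} cells of 1 km")
print(f"concentration range {arr.min():.1f} - {arr.max():.1f} ug/m3, "
      f"mean {arr.mean():.1f}")
print(f"cells truncated to training range: {grid.truncated.sum()} "
      f"({100 * grid.truncated.mean():.0f}%)")

split_row = int(result.scene.region_split_y // 1000)
print(f"south mean {arr[:split_row].mean():.1f} vs north mean "
      f"{arr[split_row:].mean():.1f} ug/m3")
# the south (industry + harbor + heavy traffic) carries the higher burden
# for the industrial gases; a coarse text rendering of the surface:
for row in arr[::-4][:, ::2]:
    print("".join(" .:-=+*#@"[min(int(v / arr.max() * 8), 8)] for v in row))
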