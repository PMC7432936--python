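"""Generate the synthetic two-region coastal city and look at its layers.

The city emulates a harbor metropolis: an industrial south with refineries
and a harbor against the coast, a residential north, and an open-space band
between them. Elevation rises inland from the coastline.
"""

import airlur as al

scene = al.generate_city(al.SceneConfig(), seed=1)

print(f"bounds (m): {scene.bounds}")
print(f"roads: {len(scene.roads)} "
      f"({len(scene.roads_of_class('major'))} major, "
      f"{len(scene.roads_of_class('minor'))} minor)")
for cls in ("industrial", "urban", "open_space", "harbor"):
    zones = scene.landuse_of_class(cls)
    area_km2 = sum(z.geometry.area for z in zones) / 1e6
    print(f"land use {cls:>10}: {len(zones):2d} polygons, {area_km2:6.1f} km^2")
print(f"industrial point sources: {[i.name for i in scene.industries]}")

x0, y0, x1, y1 = scene.bounds
print(f"elevation near coast: {scene.elevation.sample(x1 - 500, 15_000):.1f} m; "
      f"inland: {scene.elevation.sample(x0 + 500, 15_000):.1f} m")
# elevation grows with distance to the coastline, as in a coastal escarpment

south = scene.wind["south"]
print(f"south-region wind: {len(south.direction_deg)} hourly observations, "
      f"mean speed {south.speed_ms.mean():.1f} m/s")
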