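"""Generate a synthetic proglacial world and look at its ground truth.

Builds a small world (6 glacier forelands, 4 buried loggers each, one year of
hourly records), prints the generating coefficients on both scales and the
shape of the monthly truth table.
"""

from proglacial import WorldConfig, generate_logger_traces, generate_world

config = WorldConfig(
    n_glaciers=6, stations_per_glacier=4, n_months=12, dem_size=24, seed=7
)
world = generate_world(config)

print(f"DEM: {world.terrain.elevation.shape} cells at {config.cell_size} m")
print(f"glaciers: {len(world.glaciers)} in regions {sorted(world.stations['region'].unique())}")
print(f"stations: {len(world.stations)}, monthly truth rows: {len(world.truth.monthly)}")
print("\nGenerating coefficients (natural scale):")
print(world.truth.natural_coefficients.round(4).to_string())
print("\nSame coefficients on the standardized scale actually fitted:")
print(world.truth.standardized_coefficients.round(3).to_string())

traces = generate_logger_traces(world)
tr = traces[0]
print(f"\nFirst logger: {tr.station_id}, {len(tr.records)} hourly records, "
      f"depth {tr.depth_cm} cm, elevation {tr.elevation:.0f} m")
# The standardized vector is what a mixed-model fit on this world should
# recover; the natural vector is what physically generated the temperatures.
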