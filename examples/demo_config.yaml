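# Demo configuration: a small synthetic proglacial world that runs the whole
# pipeline (simulate -> snow -> fit -> loo -> validate -> project -> buffering)
# in a few minutes on one CPU.
world:
  seed: 42
  n_glaciers: 6
  stations_per_glacier: 4
  n_months: 12
  dem_size: 24
  residual_sd: 1.0
  glacier_intercept_sd: 1.0
  trend: 0.5            # °C per decade of macroclimate warming
  cloud_missing_prob: 0.2

projection:
  # distance bands scaled to the toy domain (each glacier patch is 720 m wide;
  # the study-scale defaults of the sampling design span 0-3100 m)
  distance_classes: [[0, 70], [90, 160], [180, 250], [270, 340], [360, 430]]
  buffer_radius: 250.0
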