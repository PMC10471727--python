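# proglacial

Soil microclimate reconstruction and buffering analysis for glacier forelands.

Landscapes left behind by retreating glaciers warm faster than the regional
average, yet the temperature that soil organisms actually experience a few
centimeters below the surface is shaped by topography, snow cover, solar
radiation and the nearby ice — not by coarse climate grids. `proglacial`
implements a hybrid correlative pipeline for this problem: it reconstructs
monthly near-subsurface soil temperature from macroclimate and terrain-derived
covariates, validates the model's spatial transferability with a bespoke
weighting scheme, and quantifies how much of the recent warming could be
buffered by fine-scale microclimate heterogeneity.

It is aimed at microclimate ecologists and environmental modellers who want a
tested, fully synthetic-data-backed implementation of this workflow that runs
on a laptop — every stage can be exercised end-to-end against a generated
"proglacial world" with known ground truth, without downloading any data.

## The model

Monthly mean soil temperature at a station is modelled with a linear mixed
model:

```
soilT ~ mT + rad + sfd + dg + tc + pf + d
        + sfd:mT + sfd:rad + sfd:dg + sfd:d + tc:rad + (1 | gl)
```

where `mT` is macroclimate (midpoint of gridded monthly min/max temperature,
downscaled with a fixed lapse rate of −0.0065 °C/m), `rad` the monthly-averaged
daily cumulative shortwave radiation absorbed by the tilted, possibly shaded
surface (MJ m⁻² d⁻¹, with clearness-index-based direct/diffuse separation),
`sfd` the monthly frequency of snow-free days (%), `dg` the distance from the
glacier forefront (entered as √dg; a katabatic-wind proxy), `tc` tree cover
(0/1), `pf` permafrost occurrence (0/1, probability ≥ 0.9), `d` the burying
depth (5/10/15 cm) and `gl` a glacier random intercept. Continuous predictors
are standardized on the training table; months under snowpack decoupling
(`sfd` ≤ 20%) are discarded. Fit quality is reported as marginal/conditional
R² (R²m/R²c), term contributions as semi-partial R² and permutation importance
(1 − r), and transferability via leave-one-glacier-out mean coefficients
scored with weighted statistics (wR², wMAE, wRMSE) under hierarchical
downweighting (regions → glaciers → sfd deciles).

Snow-free days come from two routes that are calibrated against each other:
the diurnal temperature range of the buried logger (a sensor under snow
barely varies; range thresholds 0.5–3 °C) and satellite fractional snow cover
(snow when cover ≥ 40%, months with too few cloud-free images discarded).

For microclimate change, the transferable coefficients are projected over two
periods; per sampled point the pipeline reports ΔT (annual and seasonal),
the change in snow-free season duration, the local spatial variability
T_var (80% inter-percentile range within 250 m) and the buffering potential
T_bp = T_var / ΔT — |T_bp| > 1 means a warming-sized temperature offset is
available within walking distance.

## Worked example

`examples/05_projection_buffering.py` builds a small synthetic world
(6 forelands, 4 loggers each, one year of hourly records, macroclimate trend
0.5 °C/decade), fits the model, projects two periods 15 years apart and
summarizes the buffering analysis:

```
60 points from 6 grid cells
mean annual ΔT 0.776 °C (imposed trend: +0.75 °C)
mean snow-free season change 15.4 days
mean T_var (250 m) 5.43 °C

per-band summary:
          band  n  delta_T_annual_mean  delta_T_annual_sd  season_change_mean  pct_(1,10]  pct_>10
Inter-tropical 20                 0.78                0.0               21.72        90.0     10.0
      Northern 20                 0.78                0.0               17.08       100.0      0.0
      Southern 20                 0.78                0.0                7.32        80.0     20.0
```

The projected warming (+0.78 °C) recovers the trend imposed by the generator;
the snow-free season lengthens most where winters hover near 0 °C; and at
80–100% of points the 250 m spatial variability is one-to-ten times the
temporal change (|T_bp| ∈ (1, 10]) — the microclimate-buffering signature.

The other examples cover world simulation (`01`), snow calibration (`02`),
model fitting, variance partitioning and leave-one-out validation (`03`) and
topographic radiation (`04`). A thin CLI chains the stages:

```bash
proglacial pipeline --config examples/demo_config.yaml --artifacts artifacts/
```

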