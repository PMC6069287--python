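# Default conditions for the synthetic multitemporal campaign generator.
#
# Index-space targets are synthetic: chosen so that canopy chlorophyll
# (hence CI_red-edge) declines with stress severity and over the season
# after flowering, while senescence (hence PSRI) rises with both. They are
# not measured values from any field campaign. Adjacent stress classes are
# separated by a factor of ~1.25-1.3 in each component index, compounding
# to ~1.65 in their ratio (HMSSI).
#
# Noise: `shared_sigma` is the log-scale sd of a per-pixel, per-date
# multiplicative factor common to CI and PSRI (illumination / residual
# atmosphere); it cancels in HMSSI. `cv_ci` / `cv_psri` are coefficients of
# variation of independent per-index lognormal factors, which do not cancel.
version: 1
grid:
  rows: 120
  cols: 360
  resolution_m: 10.0
  x0: 600000.0
  y0: 3080000.0
  crs: "EPSG:32649"
# 1 km x 1 km study areas on the 10 m grid: [row0, col0, height, width]
areas:
  high: [10, 10, 100, 100]
  medium: [10, 130, 100, 100]
  low: [10, 250, 100, 100]
acquisitions:
  - {date: 2017-07-12, stage: booting}
  - {date: 2017-07-24, stage: booting}
  - {date: 2017-08-06, stage: flowering}
  - {date: 2017-08-21, stage: flowering}
  - {date: 2017-09-17, stage: mature}
  - {date: 2017-09-30, stage: mature}
plots_per_area: 100
base_bands:
  r705: 0.04
  r500: 0.04
  r750: 0.42
noise:
  shared_sigma: 0.15
  cv_ci: 0.10
  cv_psri: 0.10
targets:
  booting:
    ci: {high: 2.6, medium: 3.3, low: 4.2}
    psri: {high: 0.145, medium: 0.110, low: 0.085}
  flowering:
    ci: {high: 2.9, medium: 3.7, low: 4.7}
    psri: {high: 0.165, medium: 0.125, low: 0.095}
  mature:
    ci: {high: 1.8, medium: 2.35, low: 3.0}
    psri: {high: 0.230, medium: 0.175, low: 0.135}
# Soil heavy-metal concentrations (mg/kg) used to label the three study
# areas, attached to generated bundles as metadata.
soil_concentrations:
  high: {area: A, cd: 3.54, hg: 0.81, pb: 120.75, as: 21.35}
  medium: {area: B, cd: 2.31, hg: 0.24, pb: 91.05, as: 17.34}
  low: {area: C, cd: 0.84, hg: 0.35, pb: 78.33, as: 10.23}
  level_ii_standard: {cd: 0.3, hg: 0.5, pb: 300.0, as: 25.0}
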