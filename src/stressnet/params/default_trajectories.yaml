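# Default class-conditioned reflectance trajectories (version 1).
#
# Canopy reflectance of each channel starts at channel_base and changes
# linearly per acquisition date (slopes, reflectance units/date).  Stressed
# canopies lose NIR reflectance, gain red reflectance, shrink in area, and
# deform; the unaffected class stays flat.  noise_sd is additive sensor
# noise (reflectance units), illumination_jitter_sd a per-date multiplicative
# factor sd.  canopy_shrink_rate is the proportion of blob radius lost per
# date; deform_amplitude is the elastic-warp amplitude in pixels per date.
version: 1
channel_base:
  blue: 0.05
  green: 0.10
  red: 0.08
  rededge: 0.30
  nir: 0.55
soil_background:
  blue: 0.10
  green: 0.12
  red: 0.15
  rededge: 0.20
  nir: 0.25
classes:
  I1N2:   # high water stress
    nir_slope: -0.030
    red_slope: 0.010
    canopy_shrink_rate: 0.030
    deform_amplitude: 0.40
    noise_sd: 0.010
    illumination_jitter_sd: 0.020
  I2N2:   # moderate water stress
    nir_slope: -0.015
    red_slope: 0.005
    canopy_shrink_rate: 0.015
    deform_amplitude: 0.20
    noise_sd: 0.010
    illumination_jitter_sd: 0.020
  I3N2:   # no water stress
    nir_slope: 0.000
    red_slope: 0.000
    canopy_shrink_rate: 0.000
    deform_amplitude: 0.05
    noise_sd: 0.010
    illumination_jitter_sd: 0.020
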