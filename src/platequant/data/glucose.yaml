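name: glucose
units: mg/dL
wavelength_nm: 560
# Raspberry Pi (Sony IMX219) channel sensitivities at 560 nm.
sensitivities:
  red: 0.13
  green: 0.83
  blue: 0.11
# beta-D-glucose calibrator series spanning the kit's 0-32 mg/dL range.
standards: [0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0]
detection_range: [0.0, 32.0]
# Synthetic forward colour model (rendering only).  The pink oxidase/HRP
# product absorbs green light most strongly.
dye:
  response: log_linear
  slope: -4.0
  intercept: -0.7
  absorptivities: [0.12, 1.0, 0.30]
  blank_rgb: [250.0, 250.0, 250.0]
incubation: "30 min at room temperature (informational; not modelled)"
diluent: glucose buffer
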