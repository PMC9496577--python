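name: creatinine
units: mmol/L
wavelength_nm: 490
# Raspberry Pi (Sony IMX219) channel sensitivities at 490 nm.
sensitivities:
  red: 0.07
  green: 0.82
  blue: 0.66
# Jaffe kit calibrator series, 0 to 1.77 mmol/L (20 mg/dL).
standards: [0.0, 0.221, 0.442, 0.663, 0.884, 1.326, 1.77]
detection_range: [0.0, 1.77]
# Synthetic forward colour model (rendering only).  The red Jaffe complex
# absorbs most strongly in the blue-green, so the green channel carries
# unit absorptivity and red barely attenuates.
dye:
  response: log_linear
  slope: -2.5
  intercept: -2.0
  absorptivities: [0.08, 1.0, 0.80]
  blank_rgb: [250.0, 250.0, 250.0]
incubation: "30 min at room temperature (informational; not modelled)"
diluent: distilled water
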