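# End-to-end demo: simulate the layered rhizosphere O2 scenario, invert
# its zone rates, upscale the measured ROL with the field root census, and
# calibrate a synthetic AOB qPCR assay.
seed: 11
scenario:
  preset: fig5_o2
  sigma: 0.001          # umol/cm3 (1 uM sensor noise)
inversion:
  window: 3
  k_max: 4
  alpha: 0.05
  threshold_uM: 1.0
budget:
  census:
    roots_per_100cm2: 309
    mean_diameter_mm: 0.5
    active_tip_length_mm: 40
  rol: 0.21             # umol O2 cm-2 root surface h-1
  nh4_rate: 0.023       # areal rates at the root surface, umol cm-2 h-1
  o2_rate: 0.42
  no3_production: 0.016
  stoich: 1.5
qpcr:
  # noise-free dilution series generated at slope -3.68 (87% efficiency)
  standards:
    - [1.0e+1, 34.32]
    - [1.0e+2, 30.64]
    - [1.0e+3, 26.96]
    - [1.0e+4, 23.28]
    - [1.0e+5, 19.60]
    - [1.0e+6, 15.92]
    - [1.0e+7, 12.24]
    - [1.0e+8, 8.56]
  samples:
    - {assay: AOB, cq: 20.5}
    - {assay: Nitrospira, cq: 26.0}
  per_cm3_factor: 2.5e+3
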