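{
  "niti_superelastic": {
    "model": "superelastic",
    "name": "NiTi",
    "E_A": 37.0,
    "E_M": 42.0,
    "nu": 0.33,
    "Ms": 263.0,
    "Mf": 243.0,
    "As": 270.0,
    "Af": 280.0,
    "C_M": 7.0,
    "C_A": 7.0,
    "H": 0.04,
    "sigma_y": 1011.0,
    "T_op": 310.0
  },
  "niti_linear": {
    "model": "linear",
    "name": "NiTi (austenite, linearized)",
    "E": 37000.0,
    "nu": 0.33,
    "sigma_y": 1011.0
  },
  "niti_linear_martensite": {
    "model": "linear",
    "name": "NiTi (martensite, linearized)",
    "E": 42000.0,
    "nu": 0.33,
    "sigma_y": 1011.0
  },
  "ti6al4v": {
    "model": "linear",
    "name": "Ti-6Al-4V",
    "E": 112000.0,
    "nu": 0.3,
    "sigma_y": 970.0
  },
  "cortical_host": {
    "model": "linear",
    "name": "host mandible cortical bone (isotropic approximation)",
    "E": 17000.0,
    "nu": 0.315
  },
  "cancellous_host": {
    "model": "linear",
    "name": "host mandible cancellous bone (isotropic approximation)",
    "E": 960.0,
    "nu": 0.3
  },
  "cortical_graft": {
    "model": "linear",
    "name": "fibular graft cortical bone",
    "E": 26800.0,
    "nu": 0.3
  },
  "cancellous_graft": {
    "model": "linear",
    "name": "fibular graft cancellous bone",
    "E": 1650.0,
    "nu": 0.3
  },
  "teeth": {
    "model": "linear",
    "name": "teeth",
    "E": 17600.0,
    "nu": 0.25
  },
  "ligament": {
    "model": "linear",
    "name": "periodontal ligament",
    "E": 2.7,
    "nu": 0.45
  }
}
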