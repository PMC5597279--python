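{
  "comment": "Measured compression properties of the dense SLM-fabricated alloys: Young's modulus (GPa) and yield strength (MPa; Ti-6Al-4V yield is a band).",
  "NiTi": {"E_GPa": 37, "yield_MPa": 1011},
  "Ti-6Al-4V": {"E_GPa": 112, "yield_MPa": [970, 1030]}
}
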